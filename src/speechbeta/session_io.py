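"""Session recordings: container, HDF5 fixture I/O, channel selection, CAR.

A session is a channels x samples matrix of cortical surface electrical
potentials (CSEPs) with speech annotations (start, consonant-vowel
transition, end, syllable label per utterance), invalid time intervals,
and two channel index sets: the sensorimotor-cortex (SMC) channels and
the per-session bad channels.

Fixture files are plain HDF5 with the layout::

    /csep                 float  (n_channels, n_samples)
    /annotations/start_s  float  (n_utterances,)
    /annotations/cv_s     float  (n_utterances,)
    /annotations/end_s    float  (n_utterances,)
    /annotations/label    bytes  (n_utterances,)
    /invalid_intervals    float  (n_invalid, 2)     [start_s, end_s]
    /channels/smc         int    (n_smc,)
    /channels/bad         int    (n_bad,)
    attrs: sample_rate_hz, subject_id, session_id

plus an optional /ground_truth group written by the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "Annotation",
    "SessionRecording",
    "ChannelSet",
    "SchemaError",
    "read_session",
    "write_session",
    "select_channels",
    "common_average_reference",
]


class SchemaError(ValueError):
    """A fixture file is missing mandatory fields or is inconsistent."""


@dataclass(frozen=True)
class Annotation:
    """One utterance: speech start, consonant-vowel transition, speech end."""

    start_s: float
    cv_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not (self.start_s < self.cv_s < self.end_s):
            raise ValueError(
                f"annotation times must be strictly ordered, got "
                f"({self.start_s}, {self.cv_s}, {self.end_s})"
            )


@dataclass
class SessionRecording:
    subject_id: str
    session_id: str
    sample_rate_hz: float
    csep: np.ndarray  # (n_channels, n_samples)
    annotations: list[Annotation]
    invalid_intervals: list[tuple[float, float]] = field(default_factory=list)
    smc_indices: list[int] = field(default_factory=list)
    bad_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.csep = np.asarray(self.csep, dtype=float)
        if self.csep.ndim != 2:
            raise ValueError("csep must be a channels x samples matrix")
        dur = self.n_samples / self.sample_rate_hz
        prev_end = -np.inf
        for ann in self.annotations:
            if ann.start_s < prev_end:
                raise ValueError("annotations overlap or are out of order")
            if ann.end_s > dur + 1e-9:
                raise ValueError("annotation extends beyond the recording")
            prev_end = ann.end_s
        n_ch = self.csep.shape[0]
        if any(i < 0 or i >= n_ch for i in self.smc_indices):
            raise ValueError("smc_indices outside channel range")

    @property
    def n_channels(self) -> int:
        return self.csep.shape[0]

    @property
    def n_samples(self) -> int:
        return self.csep.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass(frozen=True)
class ChannelSet:
    """Ordered valid-channel indices; len() is N_channels, the channel-power divisor."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError("channel set is empty")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("channel indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def n_channels(self) -> int:
        return len(self.indices)


def write_session(session: SessionRecording, path, ground_truth=None) -> None:
    """Write a session (and optional ground truth) to the HDF5 fixture layout."""
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate_hz"] = session.sample_rate_hz
        f.attrs["subject_id"] = session.subject_id
        f.attrs["session_id"] = session.session_id
        f.create_dataset("csep", data=session.csep)
        g = f.create_group("annotations")
        g.create_dataset("start_s", data=[a.start_s for a in session.annotations])
        g.create_dataset("cv_s", data=[a.cv_s for a in session.annotations])
        g.create_dataset("end_s", data=[a.end_s for a in session.annotations])
        g.create_dataset(
            "label",
            data=np.array([a.label.encode() for a in session.annotations]),
        )
        f.create_dataset(
            "invalid_intervals",
            data=np.asarray(session.invalid_intervals, dtype=float).reshape(-1, 2),
        )
        ch = f.create_group("channels")
        ch.create_dataset("smc", data=np.asarray(session.smc_indices, dtype=int))
        ch.create_dataset("bad", data=np.asarray(session.bad_indices, dtype=int))
        if ground_truth is not None:
            ground_truth.to_hdf5(f.create_group("ground_truth"))


def read_session(path) -> SessionRecording:
    """Read a fixture file, validating the schema.

    Raises :class:`SchemaError` if mandatory groups/attributes are absent
    or inconsistent with the data matrix.
    """
    with h5py.File(path, "r") as f:
        for attr in ("sample_rate_hz", "subject_id", "session_id"):
            if attr not in f.attrs:
                raise SchemaError(f"missing attribute {attr!r}")
        if "csep" not in f:
            raise SchemaError("missing dataset /csep")
        if "annotations" not in f:
            raise SchemaError("missing group /annotations")
        g = f["annotations"]
        for ds in ("start_s", "cv_s", "end_s", "label"):
            if ds not in g:
                raise SchemaError(f"missing dataset /annotations/{ds}")
        starts = np.asarray(g["start_s"], dtype=float)
        cvs = np.asarray(g["cv_s"], dtype=float)
        ends = np.asarray(g["end_s"], dtype=float)
        labels = [s.decode() for s in g["label"]]
        if not (len(starts) == len(cvs) == len(ends) == len(labels)):
            raise SchemaError("annotation arrays have mismatched lengths")
        if "channels" not in f or "smc" not in f["channels"] or "bad" not in f["channels"]:
            raise SchemaError("missing /channels/{smc,bad}")
        anns = [
            Annotation(float(s), float(c), float(e), lab)
            for s, c, e, lab in zip(starts, cvs, ends, labels)
        ]
        inv = np.asarray(f["invalid_intervals"], dtype=float).reshape(-1, 2)
        return SessionRecording(
            subject_id=str(f.attrs["subject_id"]),
            session_id=str(f.attrs["session_id"]),
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            csep=np.asarray(f["csep"], dtype=float),
            annotations=anns,
            invalid_intervals=[(float(a), float(b)) for a, b in inv],
            smc_indices=[int(i) for i in f["channels"]["smc"]],
            bad_indices=[int(i) for i in f["channels"]["bad"]],
        )


def select_channels(session: SessionRecording) -> ChannelSet:
    """Valid SMC channels: session SMC indices minus bad indices, order kept."""
    if not session.smc_indices:
        raise ValueError("session has no SMC channels")
    bad = set(session.bad_indices)
    kept = tuple(i for i in session.smc_indices if i not in bad)
    if not kept:
        raise ValueError(
            f"session {session.session_id}: every SMC channel is marked bad"
        )
    return ChannelSet(kept)


def common_average_reference(x: np.ndarray) -> np.ndarray:
    """Subtract the cross-channel mean signal from each channel.

    Operates on an already-selected channels x samples matrix; the mean is
    taken over exactly the rows given (valid SMC channels), matching the
    exclude-then-rereference order of operations.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("CAR needs a matrix with at least 2 channels")
    return x - x.mean(axis=0, keepdims=True)
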