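"""Synthetic ECoG sessions with known ERD/ERS envelope structure.

Each generated channel is a sum over the six analysis sub-bands of an
amplitude-modulated band-limited Gaussian-noise carrier, plus 1/f
broadband noise and 60/120/180 Hz line interference.  The per-band
amplitude envelopes follow the qualitative event sequence seen in
sensorimotor recordings of consonant-vowel speech:

* beta sub-bands sit at their trial maximum during inter-utterance
  speech posture (ISP), start to decline a configurable lead time
  (default 400 ms) before consonant movement onset, reach their minimum
  early in the vowel, peak briefly before vowel termination, dip at
  termination, and rebound to maximum during ISP2;
* gamma / high-gamma sub-bands do roughly the opposite: minimum during
  ISP, rise starting a (default 300 ms) lead before consonant onset,
  peak around vowel onset (mid-vowel for low gamma), and decay back to
  minimum after vowel termination.

Envelopes are piecewise linear between named event nodes.  Per-session
envelopes are composed from per-utterance templates by an elementwise
minimum (beta: dips below a high baseline) or maximum (gamma: bumps
above a low baseline) so that closely spaced utterances overlap
gracefully.  Everything is driven by one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .bands import SUB_BANDS, SUB_BAND_NAMES, SubBand
from .session_io import Annotation, SessionRecording, read_session, write_session
from .spectral import bandpass_subband

__all__ = [
    "BandEnvelopeParams",
    "SimConfig",
    "GroundTruth",
    "default_envelope_params",
    "make_envelope_template",
    "template_nodes",
    "band_limited_carrier",
    "generate_session",
    "generate_collection",
    "write_fixture",
    "read_fixture",
]

#: Default lead (s) by which beta decline precedes consonant movement onset.
BETA_DECLINE_LEAD_S = 0.400
#: Default lead (s) by which gamma/high-gamma rise precedes consonant onset.
GAMMA_RISE_LEAD_S = 0.300


@dataclass(frozen=True)
class BandEnvelopeParams:
    """Piecewise-linear envelope description for one sub-band.

    ``nodes`` are (anchor, offset, level) triples.  Anchors:

    - ``"lead"``: consonant onset minus ``lead_s``; offset in seconds
    - ``"c0"`` / ``"cv"`` / ``"v1"``: consonant onset, consonant-vowel
      transition, vowel termination; offset in seconds
    - ``"cfrac"`` / ``"vfrac"``: fractional position inside the consonant
      or vowel interval; offset in [0, 1]

    ``baseline`` is the level far from any utterance and ``combine``
    ("min" or "max") controls how per-utterance templates merge into one
    session envelope.
    """

    baseline: float
    lead_s: float
    nodes: tuple[tuple[str, float, float], ...]
    combine: str = "min"

    def __post_init__(self) -> None:
        if self.combine not in ("min", "max"):
            raise ValueError("combine must be 'min' or 'max'")
        if self.baseline < 0 or any(level < 0 for _, _, level in self.nodes):
            raise ValueError("envelope levels must be nonnegative")


def default_envelope_params() -> dict[str, BandEnvelopeParams]:
    """Default per-band envelope event tables (levels in arbitrary units)."""
    beta_l = BandEnvelopeParams(
        baseline=1.0,
        lead_s=BETA_DECLINE_LEAD_S,
        combine="min",
        nodes=(
            ("lead", 0.0, 1.0),  # decline onset, 400 ms before movement
            ("c0", -0.35, 0.62),
            ("cv", 0.0, 0.38),
            ("vfrac", 0.20, 0.30),  # trial minimum early in the vowel
            ("vfrac", 0.85, 0.80),  # brief peak before vowel termination
            ("v1", 0.0, 0.65),
            ("v1", 0.08, 0.58),  # brief post-termination dip
            ("v1", 0.30, 1.00),  # rebound to trial maximum during ISP2
        ),
    )
    beta_h = BandEnvelopeParams(
        baseline=1.0,
        lead_s=BETA_DECLINE_LEAD_S,
        combine="min",
        nodes=(
            ("lead", 0.0, 1.0),
            ("lead", 0.025, 0.48),  # rapid early decline (faster than beta_l)
            ("cfrac", 0.30, 0.48),
            ("cfrac", 0.60, 0.56),  # brief inhibition transient during the consonant
            ("cv", 0.0, 0.46),
            ("vfrac", 0.20, 0.30),
            ("vfrac", 0.85, 0.85),
            ("v1", 0.0, 0.62),
            ("v1", 0.08, 0.55),
            ("v1", 0.30, 1.00),
        ),
    )
    gamma_fast = BandEnvelopeParams(
        baseline=0.30,
        lead_s=GAMMA_RISE_LEAD_S,
        combine="max",
        nodes=(
            ("lead", 0.0, 0.30),  # rise onset, 300 ms before movement
            ("c0", 0.0, 0.80),  # steady rise through the lead
            ("cfrac", 0.85, 1.00),  # trial maximum late in the consonant
            ("vfrac", 0.50, 0.60),
            ("v1", 0.0, 0.45),
            ("v1", 0.45, 0.30),  # slow decay to trial minimum during ISP2
        ),
    )
    gamma_l = BandEnvelopeParams(
        baseline=0.30,
        lead_s=GAMMA_RISE_LEAD_S,
        combine="max",
        nodes=(
            ("lead", 0.0, 0.30),
            ("cv", 0.0, 0.60),
            ("vfrac", 0.45, 1.00),  # trial maximum mid-vowel
            ("v1", 0.0, 0.55),
            ("v1", 0.10, 0.65),  # transient bump at return to posture
            ("v1", 0.35, 0.30),
        ),
    )
    return {
        "beta_l": beta_l,
        "beta_h": beta_h,
        "gamma_l": gamma_l,
        "gamma_h": gamma_fast,
        "hgamma_l": gamma_fast,
        "hgamma_h": gamma_fast,
    }


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic session.

    Defaults mirror the deposited recordings this generator emulates:
    3052 Hz sampling, consonant lengths averaging ~107 ms, vowel lengths
    averaging ~388 ms, inter-speech gaps with ~800 ms median, and a
    majority of syllables ending in the vowel /i/.
    """

    n_channels: int = 16
    sample_rate_hz: float = 3052.0
    n_utterances: int = 80
    syllables: tuple[str, ...] = (
        "bi", "di", "gi", "pi", "ti", "ki", "si", "mi", "ba", "da",
    )
    consonant_ms: tuple[float, float] = (50.0, 165.0)
    vowel_ms: tuple[float, float] = (250.0, 525.0)
    isp_ms: tuple[float, float] = (400.0, 1200.0)
    band_envelope_params: dict[str, BandEnvelopeParams] = field(
        default_factory=default_envelope_params
    )
    carrier_amp: float = 1.0
    line_noise_amp: float = 0.5
    broadband_noise_amp: float = 0.5
    broadband_noise_exponent: float = 1.0
    bad_channel_fraction: float = 0.1
    n_invalid_intervals: int = 2
    lead_in_s: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("consonant_ms", "vowel_ms", "isp_ms"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered")
        if not 0 <= self.bad_channel_fraction < 1:
            raise ValueError("bad_channel_fraction must be in [0, 1)")
        f_max = max(b.f_hi for b in SUB_BANDS.values())
        if self.sample_rate_hz <= 2 * f_max:
            raise ValueError(
                f"sample rate {self.sample_rate_hz} Hz violates Nyquist for the "
                f"{f_max} Hz upper band edge"
            )
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        missing = set(SUB_BAND_NAMES) - set(self.band_envelope_params)
        if missing:
            raise ValueError(f"missing envelope params for bands: {missing}")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    sample_rate_hz: float
    band_envelopes: dict[str, np.ndarray]  # per band, session-length
    beta_decline_lead_s: float
    gamma_rise_lead_s: float
    decline_node_s: np.ndarray  # per utterance: consonant onset - beta lead
    rise_node_s: np.ndarray  # per utterance: consonant onset - gamma lead
    bad_indices: list[int]
    annotations: list[Annotation]

    def to_hdf5(self, group) -> None:
        group.attrs["sample_rate_hz"] = self.sample_rate_hz
        group.attrs["beta_decline_lead_s"] = self.beta_decline_lead_s
        group.attrs["gamma_rise_lead_s"] = self.gamma_rise_lead_s
        env = group.create_group("band_envelopes")
        for band, arr in self.band_envelopes.items():
            env.create_dataset(band, data=arr)
        group.create_dataset("decline_node_s", data=self.decline_node_s)
        group.create_dataset("rise_node_s", data=self.rise_node_s)
        group.create_dataset("bad_indices", data=np.asarray(self.bad_indices, int))

    @classmethod
    def from_hdf5(cls, group, annotations: list[Annotation]) -> "GroundTruth":
        return cls(
            sample_rate_hz=float(group.attrs["sample_rate_hz"]),
            band_envelopes={
                band: np.asarray(ds) for band, ds in group["band_envelopes"].items()
            },
            beta_decline_lead_s=float(group.attrs["beta_decline_lead_s"]),
            gamma_rise_lead_s=float(group.attrs["gamma_rise_lead_s"]),
            decline_node_s=np.asarray(group["decline_node_s"], dtype=float),
            rise_node_s=np.asarray(group["rise_node_s"], dtype=float),
            bad_indices=[int(i) for i in group["bad_indices"]],
            annotations=annotations,
        )


def template_nodes(
    timing: tuple[float, float, float], params: BandEnvelopeParams
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve one utterance's envelope nodes to absolute (times, levels).

    ``timing`` is (consonant onset, CV transition, vowel termination) in
    seconds.  Nodes whose resolved time does not strictly increase are
    dropped (earlier nodes win), preserving the strictly-increasing node
    invariant for degenerate timings.
    """
    c0, cv, v1 = timing
    if not (c0 < cv < v1):
        raise ValueError(f"utterance timing must be ordered, got {timing}")
    times, levels = [], []
    for anchor, offset, level in params.nodes:
        if anchor == "lead":
            t = c0 - params.lead_s + offset
        elif anchor == "c0":
            t = c0 + offset
        elif anchor == "cv":
            t = cv + offset
        elif anchor == "v1":
            t = v1 + offset
        elif anchor == "cfrac":
            t = c0 + offset * (cv - c0)
        elif anchor == "vfrac":
            t = cv + offset * (v1 - cv)
        else:
            raise ValueError(f"unknown envelope anchor {anchor!r}")
        if times and t <= times[-1]:
            continue
        times.append(t)
        levels.append(level)
    return np.asarray(times), np.asarray(levels)


def make_envelope_template(
    band: str,
    timing: tuple[float, float, float, float, float],
    params: BandEnvelopeParams,
    fs: float,
) -> np.ndarray:
    """Sample one trial's piecewise-linear envelope at rate ``fs``.

    ``timing`` is (isp1_start, consonant onset, CV transition, vowel
    termination, isp2_end); the envelope is returned over
    [isp1_start, isp2_end) and equals ``params.baseline`` outside the
    node support.
    """
    isp1_start, c0, cv, v1, isp2_end = timing
    if not (isp1_start <= c0 < cv < v1 <= isp2_end):
        raise ValueError(f"trial timing must be ordered, got {timing}")
    if band not in SUB_BANDS:
        raise ValueError(f"unknown band {band!r}")
    times, levels = template_nodes((c0, cv, v1), params)
    n = int(round((isp2_end - isp1_start) * fs))
    tt = isp1_start + np.arange(n) / fs
    return np.interp(tt, times, levels, left=params.baseline, right=params.baseline)


def band_limited_carrier(
    band: SubBand, n_samples: int, fs: float, rng: np.random.Generator, shape=None
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed into ``band``.

    With ``shape=(n_channels,)`` returns independent carriers per row.
    """
    size = (n_samples,) if shape is None else (*shape, n_samples)
    w = rng.standard_normal(size)
    x = bandpass_subband(w, fs, band, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / rms


def _one_over_f_noise(
    n_samples: int, fs: float, exponent: float, rng: np.random.Generator, shape
) -> np.ndarray:
    """Unit-RMS broadband noise with power spectrum ~ 1/f**exponent."""
    w = rng.standard_normal((*shape, n_samples))
    spec = np.fft.rfft(w, axis=-1)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = np.ones_like(f)
    above = f >= 1.0  # flat below 1 Hz to avoid a DC blow-up
    scale[above] = f[above] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / rms


def _session_envelope(
    band: str,
    params: BandEnvelopeParams,
    annotations: list[Annotation],
    n_samples: int,
    fs: float,
) -> np.ndarray:
    env = np.full(n_samples, params.baseline)
    combine = np.minimum if params.combine == "min" else np.maximum
    for ann in annotations:
        times, levels = template_nodes((ann.start_s, ann.cv_s, ann.end_s), params)
        i0 = max(0, int(np.floor((times[0] - 0.02) * fs)))
        i1 = min(n_samples, int(np.ceil((times[-1] + 0.02) * fs)) + 1)
        tt = np.arange(i0, i1) / fs
        tmpl = np.interp(tt, times, levels, left=params.baseline, right=params.baseline)
        env[i0:i1] = combine(env[i0:i1], tmpl)
    return env


def generate_session(
    config: SimConfig,
    session_index: int = 0,
    subject_id: str = "synth",
) -> tuple[SessionRecording, GroundTruth]:
    """Generate one fully seeded synthetic session plus its ground truth.

    The channel matrix is sum-of-bands envelope-modulated carriers plus
    1/f broadband noise plus common-phase line interference; channels
    drawn as bad are replaced by large low-frequency drift that common
    average referencing cannot remove (only exclusion can).
    """
    config.validate()
    fs = config.sample_rate_hz
    rng = np.random.default_rng([config.seed, session_index])

    # --- utterance timing ---------------------------------------------------
    t = config.lead_in_s
    anns: list[Annotation] = []
    for _ in range(config.n_utterances):
        c_dur = rng.uniform(*config.consonant_ms) / 1000.0
        v_dur = rng.uniform(*config.vowel_ms) / 1000.0
        label = str(rng.choice(config.syllables))
        anns.append(Annotation(t, t + c_dur, t + c_dur + v_dur, label))
        t += c_dur + v_dur + rng.uniform(*config.isp_ms) / 1000.0
    duration = anns[-1].end_s + config.lead_in_s
    n = int(np.ceil(duration * fs))

    # --- envelopes and carriers --------------------------------------------
    envelopes = {
        band: _session_envelope(band, config.band_envelope_params[band], anns, n, fs)
        for band in SUB_BAND_NAMES
    }
    data = np.zeros((config.n_channels, n))
    for band in SUB_BAND_NAMES:
        carriers = band_limited_carrier(
            SUB_BANDS[band], n, fs, rng, shape=(config.n_channels,)
        )
        data += config.carrier_amp * envelopes[band][None, :] * carriers

    if config.broadband_noise_amp > 0:
        data += config.broadband_noise_amp * _one_over_f_noise(
            n, fs, config.broadband_noise_exponent, rng, (config.n_channels,)
        )

    if config.line_noise_amp > 0:
        tt = np.arange(n) / fs
        for f0, rel in ((60.0, 1.0), (120.0, 0.4), (180.0, 0.25)):
            phase = rng.uniform(0, 2 * np.pi)
            data += config.line_noise_amp * rel * np.sin(2 * np.pi * f0 * tt + phase)

    # --- bad channels: huge low-frequency drift, per channel ---------------
    n_bad = int(round(config.bad_channel_fraction * config.n_channels))
    bad = sorted(rng.choice(config.n_channels, size=n_bad, replace=False).tolist())
    if n_bad:
        drift = rng.standard_normal((n_bad, n))
        sos = _signal.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
        drift = _signal.sosfiltfilt(sos, drift, axis=-1)
        drift /= np.sqrt(np.mean(drift**2, axis=-1, keepdims=True))
        data[bad, :] = 50.0 * drift

    # --- invalid intervals outside the lead-in/lead-out --------------------
    invalid = []
    for _ in range(config.n_invalid_intervals):
        start = rng.uniform(config.lead_in_s, duration - config.lead_in_s - 1.0)
        invalid.append((start, start + 1.0))
    invalid.sort()

    session = SessionRecording(
        subject_id=subject_id,
        session_id=f"{subject_id}-{session_index:02d}",
        sample_rate_hz=fs,
        csep=data,
        annotations=anns,
        invalid_intervals=invalid,
        smc_indices=list(range(config.n_channels)),
        bad_indices=bad,
    )
    c0s = np.array([a.start_s for a in anns])
    beta_lead = config.band_envelope_params["beta_h"].lead_s
    gamma_lead = config.band_envelope_params["hgamma_l"].lead_s
    truth = GroundTruth(
        sample_rate_hz=fs,
        band_envelopes=envelopes,
        beta_decline_lead_s=beta_lead,
        gamma_rise_lead_s=gamma_lead,
        decline_node_s=c0s - beta_lead,
        rise_node_s=c0s - gamma_lead,
        bad_indices=bad,
        annotations=anns,
    )
    return session, truth


def generate_collection(
    config: SimConfig, n_sessions: int = 10
) -> list[tuple[SessionRecording, GroundTruth]]:
    """Generate a multi-session collection; session i uses seed (seed, i)."""
    return [generate_session(config, session_index=i) for i in range(n_sessions)]


def default_test_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-condition collection config used by the test suite.

    1000 Hz sampling keeps runtime low; every analysis band lies well
    below the 500 Hz Nyquist frequency.
    """
    overrides.setdefault("sample_rate_hz", 1000.0)
    return replace(SimConfig(seed=seed), **overrides)


def canonical_truth_timecourse(
    session: SessionRecording,
    truth: GroundTruth,
    band: str,
    min_isp_ms: float = 500.0,
    vowel: str = "i",
    pad_ms: float = 500.0,
) -> np.ndarray:
    """Ground-truth z-scored canonical timecourse for one band.

    Runs the squared envelope (the expected bandpower, up to scale)
    through the same epoching, resampling, and z-scoring stages as the
    measured power, yielding the series the pipeline should recover.
    """
    from . import epochs as ep

    fs = session.sample_rate_hz
    env2 = truth.band_envelopes[band] ** 2
    trial_set = ep.build_trials(session, min_isp_ms=min_isp_ms, vowel=vowel, pad_ms=pad_ms)
    pad_n = int(round(pad_ms / 1000.0 * fs))
    isp_n = ep.canonical_grid(fs)[0][0]
    rows = []
    for trial in trial_set.included:
        c0 = int(round(trial.start_s * fs))
        cv = int(round(trial.cv_s * fs))
        v1 = int(round(trial.end_s * fs))
        window = env2[c0 - isp_n - pad_n : v1 + isp_n + pad_n]
        tc = ep.assemble_timecourse(window, fs, cv - c0, v1 - cv, pad_n, band=band)
        rows.append(tc.values)
    z, _, _ = ep.zscore_session(np.vstack(rows))
    return z.mean(axis=0)


def write_fixture(session: SessionRecording, truth: GroundTruth, path) -> None:
    """Persist a session and its ground truth to the HDF5 fixture layout."""
    write_session(session, path, ground_truth=truth)


def read_fixture(path) -> tuple[SessionRecording, GroundTruth]:
    """Read back a fixture written by :func:`write_fixture`."""
    import h5py

    session = read_session(path)
    with h5py.File(path, "r") as f:
        if "ground_truth" not in f:
            raise ValueError(f"{path} holds no ground_truth group")
        truth = GroundTruth.from_hdf5(f["ground_truth"], session.annotations)
    return session, truth
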