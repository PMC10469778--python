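"""ISP1-CV-ISP2 trial epochs and canonical fixed-length timecourses.

A trial is one utterance together with the 500 ms of inter-speech
interval nearest the consonant-vowel (CV) movement on each side, plus an
extra 500 ms pad per side that absorbs filter/Hilbert edge effects and
is discarded before analysis.  Inclusion rules, applied in order:

1. boundary   — first and last utterance of a session (ISP undefined);
2. invalid    — any trial interval overlaps a marked invalid interval;
3. vowel      — syllable does not end in the target vowel (default /i/);
4. short_isp  — either flanking inter-speech interval shorter than 500 ms.

Variable-length consonant and vowel intervals are sinc-resampled to the
across-trial average lengths (~107 ms and ~388 ms), producing one
canonical grid on which trials, sessions, and subjects align.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .session_io import Annotation, SessionRecording

__all__ = [
    "TrialEpoch",
    "TrialSet",
    "BandPowerTimecourse",
    "EXCLUSION_REASONS",
    "derive_isp_intervals",
    "build_trials",
    "resample_interval",
    "canonical_grid",
    "assemble_timecourse",
    "zscore_session",
    "grand_average",
]

EXCLUSION_REASONS = ("boundary", "invalid", "vowel", "short_isp")

#: Canonical segment durations (s): kept ISP, average consonant, average vowel.
ISP_KEEP_S = 0.5
CONSONANT_TARGET_S = 0.107
VOWEL_TARGET_S = 0.388


def _round_even(x: float) -> int:
    """Round to nearest integer, ties to even (deterministic grid)."""
    return int(np.rint(x))


@dataclass
class TrialEpoch:
    """One candidate ISP1-CV-ISP2 trial (times in seconds)."""

    trial_id: int
    start_s: float  # consonant movement onset
    cv_s: float  # consonant-vowel transition
    end_s: float  # vowel movement termination
    label: str
    isp1_len_s: float
    isp2_len_s: float
    included: bool
    exclusion_reason: str | None = None

    @property
    def isp1_clip_start_s(self) -> float:
        return self.start_s - ISP_KEEP_S

    @property
    def isp2_clip_end_s(self) -> float:
        return self.end_s + ISP_KEEP_S

    def window_bounds_s(self, pad_s: float) -> tuple[float, float]:
        """Padded extraction window [start, end) in seconds."""
        return self.isp1_clip_start_s - pad_s, self.isp2_clip_end_s + pad_s


@dataclass
class TrialSet:
    """All candidate trials of one session plus the exclusion tally."""

    session_id: str
    trials: list[TrialEpoch]
    tally: Counter = field(default_factory=Counter)

    @property
    def included(self) -> list[TrialEpoch]:
        return [t for t in self.trials if t.included]

    @property
    def n_candidates(self) -> int:
        return len(self.trials)

    def check_conservation(self) -> bool:
        return len(self.included) + sum(self.tally.values()) == self.n_candidates


@dataclass
class BandPowerTimecourse:
    """Fixed-length z-scored power series on the canonical trial grid."""

    band: str
    values: np.ndarray
    boundaries: tuple[int, int, int]  # ISP1 end, CV transition, vowel end
    sample_rate_hz: float
    n_units: int = 1
    se: np.ndarray | None = None

    def interval_slices(self) -> dict[str, slice]:
        b1, b2, b3 = self.boundaries
        return {
            "ISP1": slice(0, b1),
            "consonant": slice(b1, b2),
            "vowel": slice(b2, b3),
            "ISP2": slice(b3, len(self.values)),
        }


def derive_isp_intervals(
    annotations: list[Annotation],
) -> list[tuple[float, float]]:
    """Inter-speech intervals: (end of utterance i, start of utterance i+1)."""
    out = []
    for a, b in zip(annotations[:-1], annotations[1:]):
        if a.end_s > b.start_s:
            raise ValueError(
                f"utterances overlap: end {a.end_s} s > next start {b.start_s} s"
            )
        out.append((a.end_s, b.start_s))
    return out


def build_trials(
    session: SessionRecording,
    min_isp_ms: float = 500.0,
    vowel: str = "i",
    pad_ms: float = 500.0,
) -> TrialSet:
    """Apply the trial inclusion rules to one session.

    Exclusions are tallied against the first failing rule in the order
    boundary, invalid, vowel, short_isp; candidate count is conserved.
    """
    anns = session.annotations
    n = len(anns)
    min_isp_s = min_isp_ms / 1000.0
    pad_s = pad_ms / 1000.0
    trials: list[TrialEpoch] = []
    tally: Counter = Counter()
    for i, ann in enumerate(anns):
        isp1 = ann.start_s - anns[i - 1].end_s if i > 0 else np.nan
        isp2 = anns[i + 1].start_s - ann.end_s if i < n - 1 else np.nan
        reason = None
        if i == 0 or i == n - 1:
            reason = "boundary"
        else:
            core = (ann.start_s - ISP_KEEP_S, ann.end_s + ISP_KEEP_S)
            window = (core[0] - pad_s, core[1] + pad_s)
            if window[0] < 0 or window[1] > session.duration_s:
                reason = "boundary"
            elif any(
                iv_start < core[1] and iv_end > core[0]
                for iv_start, iv_end in session.invalid_intervals
            ):
                reason = "invalid"
            elif not ann.label.endswith(vowel):
                reason = "vowel"
            elif isp1 < min_isp_s or isp2 < min_isp_s:
                reason = "short_isp"
        if reason is not None:
            tally[reason] += 1
        trials.append(
            TrialEpoch(
                trial_id=i,
                start_s=ann.start_s,
                cv_s=ann.cv_s,
                end_s=ann.end_s,
                label=ann.label,
                isp1_len_s=isp1,
                isp2_len_s=isp2,
                included=reason is None,
                exclusion_reason=reason,
            )
        )
    return TrialSet(session_id=session.session_id, trials=trials, tally=tally)


def resample_interval(series: np.ndarray, target_len: int) -> np.ndarray:
    """Band-limited (periodic sinc / Fourier) resampling to ``target_len``.

    Constant inputs are preserved exactly; equal lengths return a copy.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2 or target_len < 2:
        raise ValueError("resample_interval needs 1-D input and lengths >= 2")
    if target_len == len(series):
        return series.copy()
    return signal.resample(series, target_len)


def canonical_grid(fs: float) -> tuple[tuple[int, int, int, int], tuple[int, int, int]]:
    """Canonical segment lengths and boundary indices at sample rate ``fs``.

    Returns ((isp1, consonant, vowel, isp2) lengths, cumulative boundaries).
    At 3052 Hz this is (1526, 327, 1184, 1526) with boundaries
    (1526, 1853, 3037) and total length 4563.
    """
    isp_n = _round_even(ISP_KEEP_S * fs)
    c_n = _round_even(CONSONANT_TARGET_S * fs)
    v_n = _round_even(VOWEL_TARGET_S * fs)
    return (isp_n, c_n, v_n, isp_n), (isp_n, isp_n + c_n, isp_n + c_n + v_n)


def assemble_timecourse(
    power: np.ndarray,
    fs: float,
    c_len: int,
    v_len: int,
    pad_len: int,
    band: str = "",
) -> BandPowerTimecourse:
    """Truncate pads, resample C and V segments, and concatenate.

    ``power`` covers [pad | ISP1 | consonant | vowel | ISP2 | pad] in
    samples, with ``c_len``/``v_len`` the trial's consonant and vowel
    lengths and ``pad_len`` the pad length.  The result lies on the
    canonical grid of :func:`canonical_grid`.
    """
    power = np.asarray(power, dtype=float)
    (isp_n, c_t, v_t, _), boundaries = canonical_grid(fs)
    expected = 2 * pad_len + 2 * isp_n + c_len + v_len
    if len(power) != expected:
        raise ValueError(
            f"window has {len(power)} samples, expected {expected} "
            f"(pad {pad_len}, isp {isp_n}, consonant {c_len}, vowel {v_len})"
        )
    core = power[pad_len : len(power) - pad_len]
    isp1 = core[:isp_n]
    cons = core[isp_n : isp_n + c_len]
    vow = core[isp_n + c_len : isp_n + c_len + v_len]
    isp2 = core[isp_n + c_len + v_len :]
    values = np.concatenate(
        [isp1, resample_interval(cons, c_t), resample_interval(vow, v_t), isp2]
    )
    return BandPowerTimecourse(
        band=band, values=values, boundaries=boundaries, sample_rate_hz=fs
    )


def zscore_session(
    trial_timecourses: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Z-score trials of one session/band by pooled-sample moments.

    The mean and SD pool every time sample of every included trial, so the
    concatenated session samples come out with mean 0 and SD 1.  Returns
    (z-scored array, mu, sigma).
    """
    x = np.asarray(trial_timecourses, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("zscore_session needs >= 2 trials (2-D array)")
    mu = float(x.mean())
    sigma = float(x.std())
    if sigma == 0:
        raise ValueError("session has zero power variance; cannot z-score")
    return (x - mu) / sigma, mu, sigma


def grand_average(
    session_means: np.ndarray,
    fs: float,
    band: str = "",
    se_mode: str = "sd_over_sqrt_n",
) -> BandPowerTimecourse:
    """Pointwise mean across sessions with a dispersion band.

    ``se_mode`` is ``"sd_over_sqrt_n"`` (standard error, default) or
    ``"sd_over_n"`` (sigma/N).
    """
    x = np.asarray(session_means, dtype=float)
    if x.ndim != 2:
        raise ValueError("grand_average needs a sessions x samples array")
    lengths, _ = canonical_grid(fs)
    if x.shape[1] != sum(lengths):
        raise ValueError(
            f"session means have length {x.shape[1]}, canonical grid at "
            f"{fs} Hz has {sum(lengths)}"
        )
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if n > 1 else np.zeros(x.shape[1])
    if se_mode == "sd_over_sqrt_n":
        se = sd / np.sqrt(n)
    elif se_mode == "sd_over_n":
        se = sd / n
    else:
        raise ValueError(f"unknown se_mode {se_mode!r}")
    _, boundaries = canonical_grid(fs)
    return BandPowerTimecourse(
        band=band,
        values=mean,
        boundaries=boundaries,
        sample_rate_hz=fs,
        n_units=n,
        se=se,
    )
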