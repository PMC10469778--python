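"""Interval statistics: correlation structure, extrema, wavelet maps,
change-point segmentation, and mixed-effects inference.

Correlations between z-scored sub-band power timecourses are computed
per speech interval (ISP1, consonant, vowel, ISP2) as Pearson r with
two-tailed p-values, compared against a Bonferroni-corrected threshold
alpha/m with m = C(6,2) = 15 unique pairs per interval.

For each sub-band, PELT/MBIC change points split the canonical trial
timecourse into intervals of relatively unchanging mean power; a linear
mixed-effects model (fixed effect: interval; random intercept: session)
is compared to its intercept-only null by a chi-squared likelihood-ratio
test (ML fits on both sides), and interval means are contrasted pairwise
with Tukey HSD adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .bands import SUB_BAND_NAMES
from .changepoint import pelt_mean_shift
from .epochs import BandPowerTimecourse

__all__ = [
    "bonferroni_threshold",
    "CorrelationGrid",
    "interval_correlations",
    "cv_centered_correlations",
    "ExtremaSet",
    "local_extrema",
    "WaveletMap",
    "gaussian_wavelet_map",
    "detect_change_points",
    "last_pre_onset_change_point",
    "LmeSummary",
    "interval_lme_lrt",
    "tukey_pairwise",
    "ChangePointResult",
]

INTERVAL_NAMES = ("ISP1", "consonant", "vowel", "ISP2")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1 or int(m) != m:
        raise ValueError(f"m must be a positive integer, got {m}")
    return alpha / m


@dataclass
class CorrelationGrid:
    """Symmetric r/p matrices over band pairs for one interval."""

    interval: str
    bands: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    alpha: float = 0.05

    @property
    def m(self) -> int:
        k = len(self.bands)
        return k * (k - 1) // 2

    @property
    def alpha_critical(self) -> float:
        return bonferroni_threshold(self.alpha, self.m)

    @property
    def significant(self) -> np.ndarray:
        mask = self.p < self.alpha_critical
        np.fill_diagonal(mask, False)
        return mask

    def pair(self, band_a: str, band_b: str) -> tuple[float, float]:
        i, j = self.bands.index(band_a), self.bands.index(band_b)
        return float(self.r[i, j]), float(self.p[i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.bands)), 2):
            rows.append(
                {
                    "interval": self.interval,
                    "band_a": self.bands[i],
                    "band_b": self.bands[j],
                    "r": self.r[i, j],
                    "p": self.p[i, j],
                    "significant": bool(self.significant[i, j]),
                }
            )
        return pd.DataFrame(rows)


def _correlation_grid(
    series: dict[str, np.ndarray], label: str, alpha: float
) -> CorrelationGrid:
    bands = tuple(series)
    k = len(bands)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        xi, xj = series[bands[i]], series[bands[j]]
        if np.std(xi) == 0 or np.std(xj) == 0:
            raise ValueError(
                f"zero-variance series for pair ({bands[i]}, {bands[j]}) in "
                f"{label}: correlation undefined"
            )
        res = stats.pearsonr(xi, xj)
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    return CorrelationGrid(interval=label, bands=bands, r=r, p=p, alpha=alpha)


def interval_correlations(
    timecourses: dict[str, BandPowerTimecourse],
    interval: str,
    alpha: float = 0.05,
) -> CorrelationGrid:
    """Pearson r/p over one interval's samples of the grand timecourses."""
    if interval not in INTERVAL_NAMES:
        raise ValueError(f"interval must be one of {INTERVAL_NAMES}")
    first = next(iter(timecourses.values()))
    sl = first.interval_slices()[interval]
    if sl.stop - sl.start < 3:
        raise ValueError(f"interval {interval} has fewer than 3 samples")
    series = {b: tc.values[sl] for b, tc in timecourses.items()}
    return _correlation_grid(series, interval, alpha)


def cv_centered_correlations(
    timecourses: dict[str, BandPowerTimecourse],
    width: int,
    alpha: float = 0.05,
) -> CorrelationGrid:
    """Correlations over a window of consonant movement centered at the
    CV transition (the analysis that reproduces reported positive
    high-gamma-beta coupling near the transition)."""
    first = next(iter(timecourses.values()))
    cv_idx = first.boundaries[1]
    lo, hi = cv_idx - width // 2, cv_idx - width // 2 + width
    if lo < 0 or hi > len(first.values):
        raise ValueError(
            f"CV-centered window [{lo}, {hi}) falls outside the canonical series"
        )
    series = {b: tc.values[lo:hi] for b, tc in timecourses.items()}
    return _correlation_grid(series, "cv_centered", alpha)


@dataclass
class ExtremaSet:
    """Strict interior local extrema per interval (global sample indices)."""

    band: str
    maxima: dict[str, np.ndarray]
    minima: dict[str, np.ndarray]


def local_extrema(tc: BandPowerTimecourse) -> ExtremaSet:
    """Local maxima/minima of a timecourse within each speech interval.

    Extrema are strict (greater/less than both neighbours) and interval
    endpoints are excluded, so monotone segments yield none.
    """
    x = tc.values
    maxima: dict[str, np.ndarray] = {}
    minima: dict[str, np.ndarray] = {}
    for name, sl in tc.interval_slices().items():
        seg = x[sl]
        if len(seg) < 3:
            maxima[name] = np.array([], dtype=int)
            minima[name] = np.array([], dtype=int)
            continue
        interior = np.arange(1, len(seg) - 1)
        is_max = (seg[interior] > seg[interior - 1]) & (seg[interior] > seg[interior + 1])
        is_min = (seg[interior] < seg[interior - 1]) & (seg[interior] < seg[interior + 1])
        maxima[name] = interior[is_max] + sl.start
        minima[name] = interior[is_min] + sl.start
    return ExtremaSet(band=tc.band, maxima=maxima, minima=minima)


@dataclass
class WaveletMap:
    """Normalized correlations of zero-mean Gaussian templates with a series.

    Positive coefficients mark peak-like features, negative ones troughs.
    """

    band: str
    sigmas: np.ndarray  # template widths, in canonical samples
    coefficients: np.ndarray  # (n_sigmas, n_samples)


def _gaussian_template(sigma: float) -> np.ndarray:
    half = int(np.ceil(4 * sigma))
    u = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (u / sigma) ** 2)
    g -= g.mean()  # zero mean: constant input maps to ~0
    return g / np.linalg.norm(g)


def gaussian_wavelet_map(
    tc: BandPowerTimecourse, sigma_range: tuple[int, int] = (1, 42)
) -> WaveletMap:
    """Continuous wavelet-style map with unit-energy zero-mean Gaussians.

    Template support is truncated at +/-4 sigma; widths are in canonical
    samples.  coefficient(sigma, t) is the inner product of the template
    centered at t with the series.
    """
    x = np.asarray(tc.values, dtype=float)
    sigmas = np.arange(sigma_range[0], sigma_range[1] + 1)
    max_support = 2 * int(np.ceil(4 * sigmas[-1])) + 1
    if len(x) <= max_support:
        raise ValueError(
            f"series of length {len(x)} is shorter than the largest wavelet "
            f"support ({max_support} samples)"
        )
    coef = np.empty((len(sigmas), len(x)))
    for i, s in enumerate(sigmas):
        g = _gaussian_template(s)
        half = len(g) // 2
        padded = np.pad(x, half, mode="reflect")  # keeps zero-mean at edges
        coef[i] = np.correlate(padded, g, mode="valid")
    return WaveletMap(band=tc.band, sigmas=sigmas, coefficients=coef)


def detect_change_points(
    series: np.ndarray, min_size: int = 10, noise_scale: float | str = 1.0
) -> np.ndarray:
    """PELT mean-shift change points under the MBIC penalty."""
    return pelt_mean_shift(np.asarray(series, float), min_size=min_size,
                           noise_scale=noise_scale)


def last_pre_onset_change_point(
    change_points: np.ndarray, onset_idx: int
) -> int | None:
    """The change point marking pre-movement power decline/rise onset.

    Returns the last detected change point at or before consonant
    movement onset, or None if there is none.
    """
    before = [int(c) for c in change_points if c <= onset_idx]
    return before[-1] if before else None


@dataclass
class LmeSummary:
    """Likelihood-ratio test of interval structure in a mixed model."""

    chi2: float
    df: int
    p_value: float
    interval_means: np.ndarray  # fixed-effect estimate per interval
    n_sessions: int
    n_intervals: int
    converged: bool
    warnings_: list[str] = field(default_factory=list)
    _fit: object | None = None  # fitted full MixedLM result

    @property
    def n_obs(self) -> int:
        return self.n_sessions * self.n_intervals


def _fit_ml(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """ML MixedLM fit with optimizer fallbacks for boundary fits.

    When the random-intercept variance collapses to ~0 the default
    optimizer's Hessian can be singular; gradient-free optimizers still
    deliver a valid maximized likelihood for the LRT.
    """
    model = sm.MixedLM(y, x, groups=groups)
    last_err: Exception | None = None
    for kwargs in ({}, {"method": "powell"}, {"method": "nm", "maxiter": 2000}):
        try:
            return model.fit(reml=False, **kwargs)
        except np.linalg.LinAlgError as err:
            last_err = err
    raise last_err


def interval_lme_lrt(interval_means: np.ndarray) -> LmeSummary:
    """Fit interval-mean power with random session intercepts and test it.

    ``interval_means`` is a sessions x intervals array of average power
    per change-point interval.  The full model has a fixed effect of
    interval and a random intercept per session; the null drops the
    interval effect.  Both are fitted by maximum likelihood and compared
    with chi2 = 2(l_full - l_null) on K-1 degrees of freedom.
    """
    y2d = np.asarray(interval_means, dtype=float)
    if y2d.ndim != 2:
        raise ValueError("interval_means must be sessions x intervals")
    n_ses, k = y2d.shape
    if n_ses < 2 or k < 2:
        raise ValueError("need >= 2 sessions and >= 2 intervals")
    y = y2d.ravel()
    groups = np.repeat(np.arange(n_ses), k)
    interval = np.tile(np.arange(k), n_ses)
    x_full = np.column_stack(
        [np.ones_like(y)] + [(interval == j).astype(float) for j in range(1, k)]
    )
    x_null = np.ones((len(y), 1))
    msgs: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        full = _fit_ml(y, x_full, groups)
        null = _fit_ml(y, x_null, groups)
        msgs = sorted({str(w.message) for w in caught})
    chi2 = 2.0 * (full.llf - null.llf)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    fe = np.asarray(full.fe_params)
    means = fe[0] + np.concatenate([[0.0], fe[1:k]])
    converged = bool(full.converged and null.converged)
    if float(np.asarray(full.cov_re).ravel()[0]) <= 1e-10:
        msgs.append("random-intercept variance estimated at the boundary (~0)")
    return LmeSummary(
        chi2=float(chi2),
        df=df,
        p_value=p,
        interval_means=means,
        n_sessions=n_ses,
        n_intervals=k,
        converged=converged,
        warnings_=msgs,
        _fit=full,
    )


def tukey_pairwise(summary: LmeSummary) -> pd.DataFrame:
    """All-pairs interval contrasts with Tukey HSD adjusted p-values.

    Contrast estimates and standard errors come from the fitted mixed
    model's fixed-effects covariance; adjusted p-values use the
    studentized range distribution with k groups and residual degrees of
    freedom n_obs - k - (n_sessions - 1).
    """
    if summary._fit is None:
        raise ValueError("summary carries no fitted model")
    k = summary.n_intervals
    if k < 2:
        raise ValueError("need >= 2 intervals for pairwise comparisons")
    fit = summary._fit
    cov = np.asarray(fit.cov_params())[: k, : k]  # fixed-effects block
    means = summary.interval_means
    ddf = max(summary.n_obs - k - (summary.n_sessions - 1), 1)
    rows = []
    for i, j in combinations(range(k), 2):
        c = np.zeros(k)
        # means differ by dummy coefficients: mean_j - mean_i
        if i == 0:
            c[j] = 1.0
        else:
            c[i], c[j] = -1.0, 1.0
        est = means[j] - means[i]
        se = float(np.sqrt(c @ cov @ c))
        q = np.abs(est) / se * np.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k, ddf))
        rows.append(
            {
                "interval_a": i + 1,
                "interval_b": j + 1,
                "estimate": est,
                "se": se,
                "q": q,
                "p_tukey": min(p_adj, 1.0),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ChangePointResult:
    """Segmentation plus mixed-effects inference for one sub-band."""

    band: str
    change_points: np.ndarray
    session_interval_means: np.ndarray  # sessions x intervals
    lme: LmeSummary
    tukey: pd.DataFrame

    @property
    def n_intervals(self) -> int:
        return len(self.change_points) + 1
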