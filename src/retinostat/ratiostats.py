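"""Paired-ratio estimation and the hypothesis tests used alongside it.

Staining intensities from WT/KO littermate pairs are compared as a ratio.
The naive ratio-of-sums estimator ``r = Σy / Σx`` is biased at order
``1/n``; the jackknife bias correction

    r_c = n r - (n-1)/n * Σ r_i,     r_i = Σ_{j≠i} y_j / Σ_{j≠i} x_j

reduces the bias to order ``1/n²``, with the leave-one-out spread giving
the standard-deviation estimates ``s`` (of r) and ``s_c`` (of r_c).
:class:`PairedRatioModel` packages this chain statsmodels-style.

Hypothesis tests: paired Student's t on within-pair differences; Welch's
unequal-variance t from summary statistics, with the Satterthwaite
degrees of freedom and the two-sided p computed from the regularized
incomplete beta function ``I_{v/(v+t²)}(v/2, 1/2)``; a double-difference
Welch variant for comparing two ratios in log space; and Pearson/Spearman
correlations with p from the t-transform with n−2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import rankdata

__all__ = [
    "PairedSample",
    "RatioEstimate",
    "PairedRatioModel",
    "jackknife_ratio",
    "normalize_paired_batches",
    "paired_t",
    "WelchResult",
    "welch_t",
    "welch_double_diff",
    "CorrelationResult",
    "correlations",
    "t_sf_two_sided",
    "normalized_pool_level",
    "DegenerateSampleError",
]


class DegenerateSampleError(ValueError):
    """Raised when an estimator is undefined on the given sample."""


# ---------------------------------------------------------------------------
# p-values via the regularized incomplete beta function
# ---------------------------------------------------------------------------

def t_sf_two_sided(t: float, v: float) -> float:
    """Two-sided p of a t statistic with ``v`` degrees of freedom.

    Computed as ``I_{v/(v+t²)}(v/2, 1/2)`` — the regularized incomplete
    beta function — which equals ``2 P(T_v > |t|)``.
    """
    if v <= 0:
        raise ValueError("degrees of freedom must be positive")
    t = float(t)
    if not np.isfinite(t):
        return 0.0
    return float(betainc(v / 2.0, 0.5, v / (v + t * t)))


# ---------------------------------------------------------------------------
# Paired samples and batch normalization
# ---------------------------------------------------------------------------

@dataclass
class PairedSample:
    """Paired WT (x) and KO (y) intensities, one entry per littermate pair."""

    x: np.ndarray
    y: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.n < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def n(self) -> int:
        return self.x.size


def normalize_paired_batches(df: pd.DataFrame) -> PairedSample:
    """Two-step normalization of paired staining intensities.

    ``df`` has columns ``batch`` (blot or slide), ``pair``, ``genotype``
    ('WT'/'KO') and ``intensity``.  First the mean intensity of all
    samples on each batch is normalized to 1, then the mean of each
    WT/KO pair is normalized to 1, so every pair satisfies
    ``(x_i + y_i)/2 = 1`` and any per-batch scale factor cancels.
    """
    required = {"batch", "pair", "genotype", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if (df["intensity"] <= 0).any():
        raise ValueError("intensities must be positive")
    work = df.copy()
    batch_mean = work.groupby("batch")["intensity"].transform("mean")
    if (batch_mean == 0).any():
        raise ZeroDivisionError("zero batch mean")
    work["intensity"] = work["intensity"] / batch_mean
    pair_mean = work.groupby("pair")["intensity"].transform("mean")
    work["intensity"] = work["intensity"] / pair_mean

    wide = work.pivot_table(index="pair", columns="genotype", values="intensity")
    if not {"WT", "KO"}.issubset(wide.columns):
        raise ValueError("each pair must have a WT and a KO sample")
    wide = wide.dropna()
    return PairedSample(wide["WT"].to_numpy(), wide["KO"].to_numpy(),
                        labels=list(wide.index))


# ---------------------------------------------------------------------------
# Jackknife bias-corrected ratio
# ---------------------------------------------------------------------------

@dataclass
class RatioEstimate:
    """Naive and jackknife bias-corrected KO/WT ratio with uncertainties."""

    r: float
    r_i: np.ndarray
    s: float
    r_c: float
    s_c: float
    n: int

    def summary(self) -> str:
        return "\n".join([
            "Jackknife paired-ratio estimate (KO/WT)",
            "-" * 44,
            f"n pairs                {self.n}",
            f"naive ratio r          {self.r:#.6g}",
            f"jackknife SD s         {self.s:#.4g}",
            f"bias-corrected r_c     {self.r_c:#.6g}",
            f"corrected SD s_c       {self.s_c:#.4g}",
        ])


class PairedRatioModel:
    """Jackknife bias-corrected ratio-of-sums estimator for paired data."""

    def __init__(self, sample: PairedSample):
        self.sample = sample
        if np.any(sample.x <= 0):
            raise DegenerateSampleError("all WT intensities must be positive")

    def fit(self) -> RatioEstimate:
        x, y, n = self.sample.x, self.sample.y, self.sample.n
        sx, sy = x.sum(), y.sum()
        loo_x, loo_y = sx - x, sy - y
        if np.any(loo_x <= 0):
            raise DegenerateSampleError("a leave-one-out WT sum is not positive")
        r = sy / sx
        r_i = loo_y / loo_x
        s = float(np.sqrt(np.mean((r_i - r) ** 2)))
        r_c = n * r - (n - 1) / n * r_i.sum()
        s_c = float(np.sqrt(np.sum((r_i - r_c) ** 2) / (n - 1)))
        return RatioEstimate(float(r), r_i, s, float(r_c), s_c, n)


def jackknife_ratio(sample: PairedSample) -> RatioEstimate:
    """Functional wrapper around :class:`PairedRatioModel`."""
    return PairedRatioModel(sample).fit()


def jackknife_ratio_batch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (r, r_c) over replicate rows of paired data.

    ``x`` and ``y`` are (replicates, n) arrays; used for Monte-Carlo bias
    studies where building per-replicate objects would dominate runtime.
    """
    sx = x.sum(axis=1, keepdims=True)
    sy = y.sum(axis=1, keepdims=True)
    n = x.shape[1]
    r = (sy / sx).ravel()
    r_i = (sy - y) / (sx - x)
    r_c = n * r - (n - 1) / n * r_i.sum(axis=1)
    return r, r_c


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def paired_t(sample: PairedSample) -> float:
    """Two-sided paired Student's t p-value on within-pair differences."""
    d = sample.y - sample.x
    n = sample.n
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        # identical differences: p=1 if no shift, else arbitrarily strong
        return 1.0 if mean == 0 else 0.0
    t = mean / (sd / np.sqrt(n))
    return t_sf_two_sided(t, n - 1)


@dataclass
class WelchResult:
    """Welch's t statistic, Satterthwaite degrees of freedom, two-sided p."""

    t: float
    v: float
    p: float

    def summary(self) -> str:
        return (f"Welch's t-test: t = {self.t:#.4g}, "
                f"v = {self.v:#.4g} (Satterthwaite), p = {self.p:#.4g}")


def welch_t(a1: float, s1: float, v1: float,
            a2: float, s2: float, v2: float) -> WelchResult:
    """Welch's unequal-variance t-test from summary statistics.

    ``a`` is a sample mean, ``s`` its standard error (SEM), ``v`` the
    sample size.  ``t = (a1-a2)/sqrt(s1²+s2²)``; the degrees of freedom
    are ``(s1²+s2²)² / (s1⁴/(v1-1) + s2⁴/(v2-1))``.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("SEMs must be >= 0")
    if v1 < 2 or v2 < 2:
        raise ValueError("each sample must have size >= 2")
    denom2 = s1**2 + s2**2
    if denom2 == 0:
        raise DegenerateSampleError("both SEMs are zero: t undefined")
    t = (a1 - a2) / np.sqrt(denom2)
    v = denom2**2 / (s1**4 / (v1 - 1) + s2**4 / (v2 - 1))
    return WelchResult(float(t), float(v), t_sf_two_sided(t, v))


def welch_double_diff(a1, s1, v1, a2, s2, v2, a3, s3, v3, a4, s4, v4) -> WelchResult:
    """Welch's t for a difference of differences, on log-transformed data.

    Compares ``(a1-a2)`` against ``(a3-a4)`` — e.g. log-ratios of two
    proteins in WT vs KO — with
    ``t = ((a1-a2)-(a3-a4)) / sqrt(s1²+s2²+s3²+s4²)`` and the four-term
    Satterthwaite degrees of freedom.
    """
    s = np.array([s1, s2, s3, s4], dtype=float)
    v = np.array([v1, v2, v3, v4], dtype=float)
    if np.any(s < 0):
        raise ValueError("SEMs must be >= 0")
    if np.any(v < 2):
        raise ValueError("each sample must have size >= 2")
    denom2 = float(np.sum(s**2))
    if denom2 == 0:
        raise DegenerateSampleError("all four SEMs are zero: t undefined")
    t = ((a1 - a2) - (a3 - a4)) / np.sqrt(denom2)
    dof = denom2**2 / float(np.sum(s**4 / (v - 1)))
    return WelchResult(float(t), float(dof), t_sf_two_sided(t, dof))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Pearson and Spearman correlations with t-transform p-values."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int

    def summary(self) -> str:
        return (f"Pearson r = {self.pearson_r:#.3g} (p = {self.pearson_p:#.3g}); "
                f"Spearman rho = {self.spearman_rho:#.3g} "
                f"(p = {self.spearman_p:#.3g}); n = {self.n}")


def _corr_p(r: float, n: int) -> float:
    """p from t = r sqrt((n-2)/(1-r²)) with n-2 degrees of freedom."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return t_sf_two_sided(t, n - 2)


def correlations(a, b) -> CorrelationResult:
    """Pearson (on values) and Spearman (on average ranks) correlation.

    p-values come from the t-transform with n−2 degrees of freedom, the
    same route for both coefficients.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    n = a.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateSampleError("zero variance: correlation undefined")

    def _pearson(u, w):
        uc, wc = u - u.mean(), w - w.mean()
        return float(uc @ wc / np.sqrt((uc @ uc) * (wc @ wc)))

    r = _pearson(a, b)
    rho = _pearson(rankdata(a), rankdata(b))
    return CorrelationResult(r, _corr_p(r, n), rho, _corr_p(rho, n), n)


# ---------------------------------------------------------------------------
# Pooled-level arithmetic
# ---------------------------------------------------------------------------

def normalized_pool_level(level: float | list, reference_pool: float | list) -> float:
    """Level of a protein pool relative to a reference pool.

    Both arguments are a scalar or a list of component amounts (summed);
    e.g. RGS7 remaining in an Rgs11 knockout relative to the combined
    RGS7 + RGS11 pool of the wild type.
    """
    num = float(np.sum(level))
    den = float(np.sum(reference_pool))
    if den <= 0:
        raise ValueError("reference pool must be positive")
    return num / den
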