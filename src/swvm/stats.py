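"""Reliability and validation statistics.

Covers the agreement/reliability toolbox for test-retest SWE designs:
ICC(2,1) — two-way random effects, absolute agreement, single measures —
with its exact-F 95% confidence interval, the standard error of measurement
SEm = SD * sqrt(1 - ICC), a qualitative ICC banding, the isotropic
linear-elastic modulus-to-velocity conversion v = sqrt(E / (3 rho)), percent
deviation against phantom reference values, and paired t-tests (from raw
vectors or from printed summary statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsError",
    "RatingsMatrix",
    "ReliabilityResult",
    "anova_mean_squares",
    "icc_2_1",
    "sem",
    "classify_icc",
    "reliability",
    "modulus_to_velocity",
    "percent_deviation",
    "paired_t",
    "paired_t_from_summary",
]


class StatsError(ValueError):
    pass


@dataclass
class RatingsMatrix:
    """n_subjects x k_measurements matrix of SWV ratings (no missing cells)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise StatsError("ratings must be a 2D (subjects x measurements) array")
        n, k = v.shape
        if n < 2 or k < 2:
            raise StatsError("need at least 2 subjects and 2 measurements")
        if not np.all(np.isfinite(v)):
            raise StatsError("ratings must not contain missing/non-finite cells")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    sem: float
    label: str
    n: int
    k: int


def anova_mean_squares(m: RatingsMatrix) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (MSR rows/subjects, MSC columns, MSE)."""
    v = m.values
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((v - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_2_1(m: RatingsMatrix, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1) point estimate with its exact-F confidence interval.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)); the interval is
    the McGraw & Wong absolute-agreement single-measures procedure built on a
    Satterthwaite-approximated F distribution (the same computation SPSS
    performs).  Returns (icc, ci_low, ci_high).
    """
    msr, msc, mse = anova_mean_squares(m)
    n, k = m.n, m.k
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr == 0 and msc == 0 and mse == 0):
        raise StatsError("ratings have zero total variance; ICC undefined")
    icc = (msr - mse) / denom

    # Satterthwaite df for the rater+error combination
    a = (k * icc) / (n * (1.0 - icc)) if icc != 1.0 else np.inf
    if not np.isfinite(a):
        return float(icc), float(icc), float(icc)
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    ci_low = n * (msr - f_u * mse) / (
        f_u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_l * msr
    )
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return float(icc), float(ci_low), float(ci_high)


def sem(m: RatingsMatrix, icc: float) -> float:
    """Standard error of measurement, SD * sqrt(1 - ICC).

    SD is the standard deviation of all n*k pooled values.  ICC = 1 gives 0;
    ICC = 0 returns the pooled SD itself.
    """
    if not (0.0 <= icc <= 1.0):
        raise StatsError("SEm requires ICC in [0, 1]")
    sd = float(np.std(m.values, ddof=1))
    return sd * float(np.sqrt(1.0 - icc))


_ICC_BANDS = [
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "good"),
]


def classify_icc(icc: float) -> str:
    """Qualitative band: poor (<=0.2), fair, moderate, good, very good (>0.8)."""
    if icc > 1.0:
        raise StatsError("ICC cannot exceed 1")
    for upper, label in _ICC_BANDS:
        if icc <= upper:
            return label
    return "very good"


def reliability(m: RatingsMatrix, alpha: float = 0.05) -> ReliabilityResult:
    """Full reliability summary: ICC(2,1), 95% CI, SEm and qualitative band."""
    icc, lo, hi = icc_2_1(m, alpha=alpha)
    s = sem(m, min(max(icc, 0.0), 1.0))
    return ReliabilityResult(
        icc=icc, ci_low=lo, ci_high=hi, sem=s, label=classify_icc(icc), n=m.n, k=m.k
    )


def modulus_to_velocity(e_pa: float, rho_kg_m3: float) -> float:
    """Shear wave velocity (m/s) from Young's modulus, v = sqrt(E / (3 rho)).

    Assumes an isotropic, incompressible, linear-elastic material — the
    convention used to convert manufacturer-certified phantom moduli.
    """
    e = np.asarray(e_pa, dtype=float)
    rho = np.asarray(rho_kg_m3, dtype=float)
    if np.any(rho <= 0):
        raise StatsError("density must be positive")
    if np.any(e < 0):
        raise StatsError("Young's modulus must be non-negative")
    v = np.sqrt(e / (3.0 * rho))
    return float(v) if v.ndim == 0 else v


def percent_deviation(measured: float, reference: float) -> float:
    """Signed percent deviation 100 * (measured - reference) / reference."""
    if reference <= 0:
        raise StatsError("reference value must be positive")
    return 100.0 * (measured - reference) / reference


def _t_to_p(t: float, df: int) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def paired_t(pre, post) -> tuple[float, float, float, float]:
    """Two-sided paired t-test; returns (mean_diff, sd_diff, t, p).

    Zero-variance differences are handled as limiting cases: all-zero
    differences give t = 0, p = 1; a constant nonzero difference gives
    t = +/-inf, p = 0.
    """
    a = np.asarray(pre, dtype=float).ravel()
    b = np.asarray(post, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise StatsError("paired_t needs two equal-length vectors, n >= 2")
    d = b - a
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return 0.0, 0.0, 0.0, 1.0
        return md, 0.0, float(np.sign(md) * np.inf), 0.0
    t, p = sps.ttest_rel(b, a)
    return md, sd, float(t), float(p)


def paired_t_from_summary(
    mean_diff: float, sd_diff: float, n: int
) -> tuple[float, float]:
    """Paired t-test from printed summary statistics; returns (t, p)."""
    if n < 2:
        raise StatsError("need n >= 2")
    if sd_diff < 0:
        raise StatsError("sd must be non-negative")
    if sd_diff == 0.0:
        return (0.0, 1.0) if mean_diff == 0.0 else (float(np.inf), 0.0)
    t = mean_diff / (sd_diff / np.sqrt(n))
    return float(t), _t_to_p(t, n - 1)
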