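"""Group comparison statistics.

The workflow mirrors a fixed two-step protocol: per-animal metric values are
first checked for normality with a Shapiro-Wilk test (reported as a gate,
never used to switch tests), then genotype groups are compared with a
two-sample Kolmogorov-Smirnov test, which makes no distributional
assumptions. Effect sizes are expressed as percent change of the mutant
mean relative to the wild-type mean, and values can be normalized to the
wild-type mean for plotting (wild type then has mean 1 exactly).

Tests run on per-animal values, not pooled per-punctum values, so animals —
not puncta — are the statistical units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from punctakit.metrics import AnimalRecord

__all__ = [
    "GroupComparison",
    "ks_two_sample",
    "shapiro_wilk",
    "normalize_to_wt",
    "percent_change",
    "compare_groups",
    "ks_null_rejection_rate",
]

logger = logging.getLogger(__name__)

METRICS = ("mean_peak_to_bead", "mean_fwhm_um", "density_per_10um")

# product of sample sizes at or below which the exact KS distribution is used
EXACT_KS_MAX_PRODUCT = 10_000


@dataclass(frozen=True)
class GroupComparison:
    """Result of comparing one metric between wild-type and mutant groups."""

    metric_name: str
    n_wt: int
    n_mut: int
    shapiro_p_wt: float
    shapiro_p_mut: float
    ks_D: float
    ks_p: float
    ks_mode: str
    percent_change: float
    wt_mean: float
    mut_mean: float


def _check_sample(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError(f"insufficient sample: {name} needs >= 2 finite values")
    return x


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    D is the supremum absolute difference of the empirical CDFs. The p-value
    uses the exact small-sample distribution when ``n_a * n_b <= 10^4``
    (which covers typical per-animal group sizes), else the asymptotic
    Kolmogorov distribution.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    method = "exact" if a.size * b.size <= EXACT_KS_MAX_PRODUCT else "asymp"
    res = sps.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_mode(n_a: int, n_b: int) -> str:
    """Which p-value mode ks_two_sample will use for these sizes."""
    return "exact" if n_a * n_b <= EXACT_KS_MAX_PRODUCT else "asymptotic"


def shapiro_wilk(sample) -> float:
    """Shapiro-Wilk normality p-value.

    Reported as a gate only; a degenerate (zero-variance) sample yields NaN.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if not np.all(np.isfinite(x)):
        raise ValueError("Shapiro-Wilk requires finite values")
    if np.ptp(x) == 0:
        return math.nan
    return float(sps.shapiro(x).pvalue)


def normalize_to_wt(values, wt_values) -> np.ndarray:
    """Divide values by the wild-type mean (wild type then has mean 1)."""
    wt = np.asarray(wt_values, dtype=float)
    wt_mean = float(np.mean(wt))
    if wt_mean == 0 or not np.isfinite(wt_mean):
        raise ValueError("cannot normalize: wild-type mean is zero or undefined")
    return np.asarray(values, dtype=float) / wt_mean


def percent_change(mut_mean: float, wt_mean: float) -> float:
    """Percent change of the mutant mean relative to the wild-type mean."""
    if wt_mean == 0:
        raise ValueError("percent change undefined: wild-type mean is zero")
    return 100.0 * (mut_mean - wt_mean) / wt_mean


def compare_groups(
    records: list[AnimalRecord],
    metric_name: str,
    wt_genotype: str = "wt",
    mut_genotype: str = "mut",
) -> GroupComparison:
    """Compare one per-animal metric between two genotypes.

    Missing (NaN) values — e.g. width means of zero-puncta animals — are
    dropped with a logged count before testing.
    """
    if metric_name not in METRICS:
        raise ValueError(f"unknown metric {metric_name!r}; expected one of {METRICS}")

    def _values(genotype: str) -> np.ndarray:
        group = [r for r in records if r.genotype == genotype]
        if not group:
            raise ValueError(f"genotype {genotype!r} absent from records")
        vals = np.array([getattr(r, metric_name) for r in group], dtype=float)
        n_missing = int(np.sum(~np.isfinite(vals)))
        if n_missing:
            logger.warning(
                "%s: dropping %d animal(s) with missing %s from genotype %s",
                metric_name, n_missing, metric_name, genotype,
            )
        return vals[np.isfinite(vals)]

    wt = _values(wt_genotype)
    mut = _values(mut_genotype)
    if wt.size < 2 or mut.size < 2:
        raise ValueError(
            f"insufficient sample for {metric_name}: need >= 2 animals with a "
            f"defined value per genotype (got {wt.size} wt, {mut.size} mut)"
        )
    D, p = ks_two_sample(wt, mut)
    wt_mean = float(np.mean(wt))
    mut_mean = float(np.mean(mut))
    return GroupComparison(
        metric_name=metric_name,
        n_wt=int(wt.size),
        n_mut=int(mut.size),
        shapiro_p_wt=shapiro_wilk(wt) if wt.size >= 3 else math.nan,
        shapiro_p_mut=shapiro_wilk(mut) if mut.size >= 3 else math.nan,
        ks_D=D,
        ks_p=p,
        ks_mode=ks_mode(wt.size, mut.size),
        percent_change=percent_change(mut_mean, wt_mean),
        wt_mean=wt_mean,
        mut_mean=mut_mean,
    )


def ks_null_rejection_rate(
    n_a: int,
    n_b: int,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error rate of the KS test under the null, by simulation.

    Draws both samples from a standard normal in each replicate and reports
    the fraction of replicates with p < alpha. A well-calibrated (if
    slightly conservative, due to the discreteness of the exact statistic)
    test should land near alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.standard_normal(n_a)
        b = rng.standard_normal(n_b)
        _, p = ks_two_sample(a, b)
        rejections += p < alpha
    return rejections / n_replicates
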