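"""Method-comparison statistics for paired dietary measurements.

The battery used to judge relative validity of an FFQ against repeated
24-h recalls: Lin's concordance correlation coefficient, Bland–Altman mean
difference / limits of agreement with a proportional-bias regression,
quartile cross-classification with weighted Cohen's kappa, paired t and
Wilcoxon signed-rank tests, percent agreement and Fisher's exact test for
binary items, and an age-band direction analysis.

Conventions: differences are FFQ minus recall, so a positive mean
difference means the FFQ over-estimates relative to the reference method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa

__all__ = [
    "PairedScores", "DegenerateInputError", "lin_ccc", "bland_altman",
    "quartile_assign", "weighted_kappa", "percent_agreement",
    "paired_location_test", "fisher_exact", "subgroup_direction_analysis",
    "compare_methods", "AgreementReport", "BlandAltmanResult",
    "LocationTestResult", "SubgroupDirectionResult",
]


class DegenerateInputError(ValueError):
    """Statistic undefined for the given data (constant input, n too small)."""


@dataclass
class PairedScores:
    """Paired per-child values from the two instruments (x = FFQ-derived,
    y = recall-derived), aligned by child."""

    child_ids: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if len(self.child_ids) != len(self.x):
            raise ValueError("child_ids must match the value arrays")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("paired scores may not contain missing values")

    def __len__(self) -> int:
        return len(self.x)


# ---------------------------------------------------------------------------
# Lin's concordance correlation coefficient
# ---------------------------------------------------------------------------

def lin_ccc(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Concordance correlation coefficient with a Fisher-z confidence
    interval.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (x̄ − ȳ)^2) on sample moments
    (divisor n).  Unlike Pearson's r it penalises location and scale shifts,
    so it measures agreement, not just linearity.  The CI back-transforms a
    normal interval on atanh(rho_c) using the large-sample standard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise DegenerateInputError("lin_ccc requires n >= 3 paired values")
    sx2 = np.var(x)
    sy2 = np.var(y)
    if sx2 == 0 and sy2 == 0:
        raise DegenerateInputError("both inputs are constant")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    ccc = 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)

    if sx2 == 0 or sy2 == 0 or abs(ccc) >= 1 - 1e-12:
        # CI collapses when a marginal is constant or agreement is perfect
        return float(ccc), float(ccc), float(ccc)
    r = sxy / math.sqrt(sx2 * sy2)
    u = (x.mean() - y.mean()) / (sx2 * sy2) ** 0.25
    se_ccc = math.sqrt(
        (
            (1 - r**2) * ccc**2 * (1 - ccc**2) / r**2
            + 2 * ccc**3 * (1 - ccc) * u**2 / r
            - 0.5 * ccc**4 * u**4 / r**2
        )
        / (n - 2)
    )
    z = math.atanh(ccc)
    se_z = se_ccc / (1 - ccc**2)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo = math.tanh(z - zcrit * se_z)
    hi = math.tanh(z + zcrit * se_z)
    return float(ccc), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    n: int
    mean_diff: float
    ci_low: float
    ci_high: float
    sd_diff: float
    upper_loa: float
    lower_loa: float
    slope: float
    slope_p: float
    k: float = 1.96


def bland_altman(
    x: np.ndarray, y: np.ndarray, k: float = 1.96
) -> BlandAltmanResult:
    """Mean difference, limits of agreement (mean ± k·SD of differences)
    and proportional-bias regression of differences on pair means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise DegenerateInputError("bland_altman requires n >= 3 pairs")
    d = x - y
    m = (x + y) / 2.0
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = stats.t.ppf(0.975, n - 1)
    half = tcrit * sd / math.sqrt(n)
    if np.ptp(m) == 0 or np.ptp(d) == 0:
        slope, slope_p = 0.0, 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            reg = stats.linregress(m, d)
        slope, slope_p = float(reg.slope), float(reg.pvalue)
        if not np.isfinite(slope_p):
            slope_p = 1.0
    return BlandAltmanResult(
        n=n,
        mean_diff=mean_diff,
        ci_low=mean_diff - half,
        ci_high=mean_diff + half,
        sd_diff=sd,
        upper_loa=mean_diff + k * sd,
        lower_loa=mean_diff - k * sd,
        slope=slope,
        slope_p=slope_p,
        k=k,
    )


# ---------------------------------------------------------------------------
# Quartile ranking agreement
# ---------------------------------------------------------------------------

def quartile_assign(values: np.ndarray) -> np.ndarray:
    """Quartile labels 1..4 against the sample's own 25/50/75 percentiles
    (linear interpolation); a value exactly at a cut-point takes the lower
    quartile."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise DegenerateInputError("quartile_assign requires n >= 4")
    cuts = np.percentile(values, [25, 50, 75])
    return (1 + (values[:, None] > cuts[None, :]).sum(axis=1)).astype(int)


def weighted_kappa(
    labels_x: np.ndarray,
    labels_y: np.ndarray,
    weights: str = "linear",
    n_categories: int | None = None,
) -> tuple[float, float]:
    """Weighted Cohen's kappa on ordinal labels 1..K with its two-sided
    large-sample p-value (H0: kappa = 0).

    Disagreement weights |i−j|/(K−1) (linear, default) or squared
    (quadratic).  With K = 2 both reduce to unweighted kappa.
    """
    lx = np.asarray(labels_x, dtype=int)
    ly = np.asarray(labels_y, dtype=int)
    if lx.shape != ly.shape or lx.ndim != 1:
        raise ValueError("label vectors must be 1-d and equal length")
    if len(lx) == 0:
        raise ValueError("empty label vectors")
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    k = n_categories or int(max(lx.max(), ly.max()))
    if lx.min() < 1 or ly.min() < 1 or max(lx.max(), ly.max()) > k:
        raise ValueError(f"labels must lie in 1..{k}")
    table = np.zeros((k, k), dtype=float)
    np.add.at(table, (lx - 1, ly - 1), 1.0)
    if k == 1:
        return 1.0, 1.0  # single category: trivially perfect agreement
    res = cohens_kappa(table, wt=weights)
    return float(res.kappa), float(res.pvalue_two_sided)


def percent_agreement(table: np.ndarray) -> float:
    """Percent of observations on the diagonal of a square contingency
    table (e.g. 2×2 yes/no cross-classification of the two instruments)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("percent_agreement expects a square table")
    total = table.sum()
    if total <= 0:
        raise ValueError("table total must be positive")
    return float(100.0 * np.trace(table) / total)


# ---------------------------------------------------------------------------
# Paired location tests
# ---------------------------------------------------------------------------

@dataclass
class LocationTestResult:
    method: str  # "t" or "wilcoxon"
    statistic: float  # t statistic, or normal-approximation Z
    p: float
    mean_diff: float
    ci_low: float | None = None
    ci_high: float | None = None
    median_diff: float | None = None


def paired_location_test(
    x: np.ndarray, y: np.ndarray, method: str = "t"
) -> LocationTestResult:
    """Paired t-test (mean difference with 95% CI) or Wilcoxon signed-rank
    test (normal-approximation Z with continuity and tie correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    d = x - y
    if method == "t":
        if n < 3:
            raise DegenerateInputError("paired t-test requires n >= 3")
        if np.ptp(d) == 0:
            # constant differences: zero-variance limit of the t statistic
            c = float(d[0])
            stat = 0.0 if c == 0 else math.copysign(math.inf, c)
            return LocationTestResult(
                method="t", statistic=stat, p=1.0 if c == 0 else 0.0,
                mean_diff=c, ci_low=c, ci_high=c,
            )
        res = stats.ttest_rel(x, y)
        ci = res.confidence_interval(0.95)
        return LocationTestResult(
            method="t",
            statistic=float(res.statistic),
            p=float(res.pvalue),
            mean_diff=float(d.mean()),
            ci_low=float(ci.low),
            ci_high=float(ci.high),
        )
    if method == "wilcoxon":
        nz = np.count_nonzero(d)
        if nz == 0:
            warnings.warn(
                "all paired differences are zero; Wilcoxon signed-rank "
                "is undefined, reporting Z = 0, p = 1",
                stacklevel=2,
            )
            return LocationTestResult(
                method="wilcoxon", statistic=0.0, p=1.0,
                mean_diff=0.0, median_diff=0.0,
            )
        if nz < 5:
            raise DegenerateInputError(
                "wilcoxon requires >= 5 non-zero differences"
            )
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=True, method="approx"
        )
        return LocationTestResult(
            method="wilcoxon",
            statistic=float(res.zstatistic),
            p=float(res.pvalue),
            mean_diff=float(d.mean()),
            median_diff=float(np.median(d)),
        )
    raise ValueError("method must be 't' or 'wilcoxon'")


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2×2 table: the summed hypergeometric
    probability of all tables (given the margins) no more probable than the
    observed one."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if (table < 0).any() or (table != np.round(table)).any():
            raise ValueError("counts must be non-negative integers")
        table = table.astype(int)
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Age-band direction analysis
# ---------------------------------------------------------------------------

@dataclass
class SubgroupDirectionResult:
    counts: dict[str, dict[str, int]]  # band -> {"higher": .., "not_higher": ..}
    table: np.ndarray  # 2x2: (<12mo, older) x (higher, not higher)
    fisher_p: float
    bland_altman_excluding_infants: BlandAltmanResult | None


def subgroup_direction_analysis(
    pairs: PairedScores, age_bands: list[str]
) -> SubgroupDirectionResult:
    """Per age band, count children whose FFQ-derived score exceeds the
    recall-derived one; test infants (<12 months) against older children
    with Fisher's exact test, and re-run Bland–Altman without infants."""
    if len(age_bands) != len(pairs):
        raise ValueError("age_bands must align with the paired scores")
    bands_present = [b for b in dict.fromkeys(age_bands)]
    counts: dict[str, dict[str, int]] = {}
    for band in bands_present:
        mask = np.array([b == band for b in age_bands])
        if not mask.any():
            warnings.warn(f"age band {band} has no children; excluded",
                          stacklevel=2)
            continue
        higher = int((pairs.x[mask] > pairs.y[mask]).sum())
        counts[band] = {
            "higher": higher,
            "not_higher": int(mask.sum()) - higher,
        }
    infants = np.array([b == "<12mo" for b in age_bands])
    inf_higher = int((pairs.x[infants] > pairs.y[infants]).sum())
    old_higher = int((pairs.x[~infants] > pairs.y[~infants]).sum())
    table = np.array([
        [inf_higher, int(infants.sum()) - inf_higher],
        [old_higher, int((~infants).sum()) - old_higher],
    ])
    p = fisher_exact(table)
    ba_excl = None
    if (~infants).sum() >= 3:
        ba_excl = bland_altman(pairs.x[~infants], pairs.y[~infants])
    return SubgroupDirectionResult(
        counts=counts, table=table, fisher_p=p,
        bland_altman_excluding_infants=ba_excl,
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """All method-comparison statistics for one paired score set."""

    n: int
    ccc: float
    ccc_ci: tuple[float, float]
    bland_altman: BlandAltmanResult
    t_test: LocationTestResult
    wilcoxon: LocationTestResult | None
    kappa: float
    kappa_p: float
    percent_same_quartile: float
    quartiles_x: np.ndarray = field(repr=False, default=None)
    quartiles_y: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        ba = self.bland_altman
        out = {
            "n": self.n,
            "ccc": self.ccc,
            "ccc_ci": list(self.ccc_ci),
            "mean_difference": ba.mean_diff,
            "mean_difference_ci": [ba.ci_low, ba.ci_high],
            "sd_difference": ba.sd_diff,
            "upper_loa": ba.upper_loa,
            "lower_loa": ba.lower_loa,
            "proportional_bias_slope": ba.slope,
            "proportional_bias_p": ba.slope_p,
            "t_statistic": self.t_test.statistic,
            "t_p": self.t_test.p,
            "weighted_kappa": self.kappa,
            "weighted_kappa_p": self.kappa_p,
            "percent_same_quartile": self.percent_same_quartile,
        }
        if self.wilcoxon is not None:
            out["wilcoxon_z"] = self.wilcoxon.statistic
            out["wilcoxon_p"] = self.wilcoxon.p
        return out


def compare_methods(
    pairs: PairedScores,
    kappa_weights: str = "linear",
    loa_k: float = 1.96,
) -> AgreementReport:
    """Run the full agreement battery on one paired score set."""
    x, y = pairs.x, pairs.y
    ccc, lo, hi = lin_ccc(x, y)
    ba = bland_altman(x, y, k=loa_k)
    t_res = paired_location_test(x, y, method="t")
    try:
        w_res = paired_location_test(x, y, method="wilcoxon")
    except DegenerateInputError:
        w_res = None
    qx = quartile_assign(x)
    qy = quartile_assign(y)
    if np.array_equal(qx, qy):
        kappa, kappa_p = 1.0, 0.0 if len(set(qx)) > 1 else 1.0
    else:
        kappa, kappa_p = weighted_kappa(
            qx, qy, weights=kappa_weights, n_categories=4
        )
    same = float(100.0 * np.mean(qx == qy))
    return AgreementReport(
        n=len(pairs),
        ccc=ccc,
        ccc_ci=(lo, hi),
        bland_altman=ba,
        t_test=t_res,
        wilcoxon=w_res,
        kappa=kappa,
        kappa_p=kappa_p,
        percent_same_quartile=same,
        quartiles_x=qx,
        quartiles_y=qy,
    )
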