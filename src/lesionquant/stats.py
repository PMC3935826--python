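"""Group comparison statistics for the pediatric-vs-adult lesion analysis.

The battery mirrors the source study design: Fisher's exact test on 2x2
lesion-incidence tables, Student's t-tests on log-transformed lesion volumes
(log(variable + constant), applied because raw lesion volumes are skewed),
and the Mann-Whitney U-test for non-normalized continuous variables, with a
pre-specified significance threshold of 0.05 and no multiplicity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05


class StatsError(Exception):
    pass


def log_shift_transform(values, constant: float = 1.0) -> np.ndarray:
    """Elementwise natural log of (value + constant); strictly monotone."""
    x = np.asarray(values, dtype=np.float64)
    if np.any(x + constant <= 0):
        raise StatsError("log_shift_transform requires value + constant > 0")
    return np.log(x + constant)


def two_sample_t(a, b, equal_variance: bool = True) -> tuple:
    """Two-sample t-test (pooled variance by default, Welch otherwise);
    two-sided p.  Zero variance in both groups: equal means give the p = 1
    convention, unequal means are a degenerate-input error."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise StatsError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_variance)
    return float(t), float(p)


def mann_whitney_u(a, b, exact_max_n: int = 12) -> tuple:
    """Mann-Whitney U from rank sums (midranks for ties); exact enumeration when
    the combined sample size is at most ``exact_max_n`` and there are no ties,
    otherwise the normal approximation with tie and continuity corrections.
    All values identical across both groups: p = 1 convention."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 1 or len(b) < 1:
        raise StatsError("each group needs n >= 1")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) + len(b) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows are groups, columns with/without lesion: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatsError("contingency entries must be nonnegative")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(table, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher's exact test by the point-probability rule.

    Conditional on the margins, the first cell is hypergeometric; the
    two-sided p sums the probabilities of every same-margin table whose point
    probability does not exceed the observed table's (within a relative
    tolerance absorbing floating-point ties).  Returns p in (0, 1].
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.array
    else:
        arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or arr.min() < 0:
        raise StatsError("fisher_exact_2x2 needs a nonnegative 2x2 table")
    a, b = arr[0]
    c, d = arr[1]
    n1, K, N = a + b, a + c, a + b + c + d
    if N == 0:
        raise StatsError("all margins are zero")
    lo, hi = max(0, K - (c + d)), min(n1, K)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, N, K, n1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    return min(p, 1.0)


def incidence_table(inventories_g1: list, inventories_g2: list, region: str,
                    modality: str) -> ContingencyTable2x2:
    """Patients with vs without any lesion in (region, modality), per group."""

    def with_lesion(invs):
        try:
            return sum(1 for inv in invs if inv.count(region, modality) > 0)
        except KeyError as e:
            raise StatsError(f"region/modality missing from inventory: {e}") from e

    a = with_lesion(inventories_g1)
    c = with_lesion(inventories_g2)
    return ContingencyTable2x2(a=a, b=len(inventories_g1) - a,
                               c=c, d=len(inventories_g2) - c)


@dataclass
class GroupComparison:
    variable: str
    statistic_kind: str  # "N (%)" or "Mean (SD)"
    group1_summary: str
    group2_summary: str
    test: str
    statistic: float
    p_value: float
    significant: bool
    transform: str = "none"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError(f"p-value {self.p_value} outside [0,1]")


@dataclass
class GroupReport:
    group1_name: str
    group2_name: str
    n1: int
    n2: int
    rows: list = field(default_factory=list)
    alpha: float = ALPHA

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "variable": r.variable, "statistic": r.statistic_kind,
                self.group1_name: r.group1_summary, self.group2_name: r.group2_summary,
                "test": r.test, "test_statistic": r.statistic,
                "p_value": r.p_value, "significant": r.significant,
                "transform": r.transform,
            })
        return pd.DataFrame(recs)

    def row(self, variable: str) -> GroupComparison:
        for r in self.rows:
            if r.variable == variable:
                return r
        raise KeyError(variable)


@dataclass(frozen=True)
class ReportConfig:
    """Row schema and test choices for the group report.

    ``volume_test`` applies to whole-brain and supratentorial volume rows;
    infratentorial volume rows, the periventricular rows and any other
    non-normalized continuous variable use the Mann-Whitney U-test.
    """

    log_constant_cm3: float = 1.0
    equal_variance: bool = True
    alpha: float = ALPHA
    volume_test: str = "t"  # "t" (on log-shifted volumes) or "mannwhitney"
    incidence_rows: tuple = (
        ("supratentorial", "T2w"), ("supratentorial", "T1w"),
        ("infratentorial", "T2w"), ("infratentorial", "T1w"),
        ("brainstem", "T2w"), ("pons", "T2w"),
    )
    volume_rows: tuple = (
        ("whole_brain", "T2w"), ("whole_brain", "T1w"),
        ("supratentorial", "T2w"), ("supratentorial", "T1w"),
        ("infratentorial", "T2w"), ("infratentorial", "T1w"),
    )
    mannwhitney_volume_rows: tuple = (
        ("infratentorial", "T2w"), ("infratentorial", "T1w"),
        ("periventricular", "T2w"), ("non_periventricular", "T2w"),
    )
    ratio_regions: tuple = ("supratentorial", "infratentorial")
    count_rows: tuple = (
        ("supratentorial", "T2w"), ("infratentorial", "T2w"), ("whole_brain", "T2w"),
    )

    def n_rows(self) -> int:
        extra_mw = tuple(r for r in self.mannwhitney_volume_rows
                         if r not in self.volume_rows)
        return (len(self.incidence_rows) + len(self.volume_rows) + len(extra_mw)
                + len(self.ratio_regions) + len(self.count_rows))


def _mean_sd(x) -> str:
    return f"{np.mean(x):.2f} ({np.std(x, ddof=1):.2f})"


def _n_pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f}%)"


def group_report(inventories_g1: list, inventories_g2: list,
                 config: ReportConfig = ReportConfig(),
                 group1_name: str = "pediatric", group2_name: str = "adult") -> GroupReport:
    """Build the full incidence/volume/ratio/count comparison between two cohorts."""
    if not inventories_g1 or not inventories_g2:
        raise StatsError("both cohorts must be nonempty")
    n1, n2 = len(inventories_g1), len(inventories_g2)
    report = GroupReport(group1_name=group1_name, group2_name=group2_name,
                         n1=n1, n2=n2, alpha=config.alpha)

    def volumes(invs, region, modality):
        try:
            return np.array([inv.volume(region, modality) for inv in invs])
        except KeyError as e:
            raise StatsError(f"inventory missing region/modality: {e}") from e

    def counts(invs, region, modality):
        return np.array([inv.count(region, modality) for inv in invs], dtype=float)

    for region, modality in config.incidence_rows:
        tab = incidence_table(inventories_g1, inventories_g2, region, modality)
        p = fisher_exact_2x2(tab)
        report.rows.append(GroupComparison(
            variable=f"patients with {region} {modality} lesions",
            statistic_kind="N (%)",
            group1_summary=_n_pct(tab.a, n1), group2_summary=_n_pct(tab.c, n2),
            test="fisher_exact", statistic=float(tab.a), p_value=p,
            significant=p < config.alpha))

    mw_rows = tuple(config.mannwhitney_volume_rows)
    for region, modality in config.volume_rows + tuple(
            r for r in mw_rows if r not in config.volume_rows):
        v1 = volumes(inventories_g1, region, modality)
        v2 = volumes(inventories_g2, region, modality)
        use_mw = (region, modality) in mw_rows or config.volume_test == "mannwhitney"
        if use_mw:
            stat, p = mann_whitney_u(v1, v2)
            test, transform = "mann_whitney_u", "none"
        else:
            t1 = log_shift_transform(v1, config.log_constant_cm3)
            t2 = log_shift_transform(v2, config.log_constant_cm3)
            stat, p = two_sample_t(t1, t2, equal_variance=config.equal_variance)
            test, transform = "t", f"log(v+{config.log_constant_cm3:g})"
        report.rows.append(GroupComparison(
            variable=f"{region} {modality} lesion volume (cm3)",
            statistic_kind="Mean (SD)",
            group1_summary=_mean_sd(v1), group2_summary=_mean_sd(v2),
            test=test, statistic=stat, p_value=p,
            significant=p < config.alpha, transform=transform))

    for region in config.ratio_regions:
        r1 = _t1_t2_ratios(inventories_g1, region)
        r2 = _t1_t2_ratios(inventories_g2, region)
        if len(r1) >= 2 and len(r2) >= 2:
            stat, p = two_sample_t(r1, r2, equal_variance=config.equal_variance)
            report.rows.append(GroupComparison(
                variable=f"{region} T1w:T2w lesion volume ratio",
                statistic_kind="Mean (SD)",
                group1_summary=_mean_sd(r1), group2_summary=_mean_sd(r2),
                test="t", statistic=stat, p_value=p, significant=p < config.alpha))

    for region, modality in config.count_rows:
        c1 = counts(inventories_g1, region, modality)
        c2 = counts(inventories_g2, region, modality)
        stat, p = two_sample_t(c1, c2, equal_variance=config.equal_variance)
        report.rows.append(GroupComparison(
            variable=f"{region} {modality} lesion count",
            statistic_kind="Mean (SD)",
            group1_summary=_mean_sd(c1), group2_summary=_mean_sd(c2),
            test="t", statistic=stat, p_value=p, significant=p < config.alpha))

    return report


def _t1_t2_ratios(inventories, region) -> np.ndarray:
    """Per-subject T1LV:T2LV ratio; subjects without T2 lesions in the region are
    dropped (the ratio is undefined for them)."""
    out = []
    for inv in inventories:
        t2 = inv.volume(region, "T2w")
        if t2 > 0:
            out.append(inv.volume(region, "T1w") / t2)
    return np.array(out)
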