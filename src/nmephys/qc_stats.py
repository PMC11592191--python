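"""Inclusion/exclusion rules and the group-statistics battery.

QC: neurons enter the dataset only with a sufficiently hyperpolarized resting
membrane potential (below −50 mV at E13, below −55 mV at E20–21) and a series
resistance of at most 10 MΩ.  Within each analysis group, datapoints more
than two standard deviations from the group mean are excluded as outliers
(single pass).

Statistics: Welch's unpaired t-test for two-condition contrasts; one-way
ANOVA with Bonferroni-adjusted all-pairs comparisons for three or more; and a
heteroscedasticity-robust battery (Welch ANOVA and Brown–Forsythe F*) for the
Boltzmann read-out comparisons at fixed voltages.  Welch and Brown–Forsythe
ANOVA statistics are computed from group summary statistics (vectorized over
replicates), which also makes large null-calibration simulations cheap;
classical tests go through scipy.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RMP_CUTOFF",
    "SERIES_RESISTANCE_MAX",
    "NeuronRecord",
    "TestResult",
    "OutlierResult",
    "inclusion_flag",
    "apply_inclusion",
    "exclude_outliers",
    "welch_t",
    "anova_bonferroni",
    "welch_anova_arrays",
    "brown_forsythe_arrays",
    "bf_welch_anova",
    "shapiro_wilk",
    "p_stars",
    "run_condition_battery",
]

RMP_CUTOFF = {"E13": -50.0, "E20_21": -55.0}  # include iff rmp < cutoff
SERIES_RESISTANCE_MAX = 10.0  # MΩ; discard above this
ALPHA = 0.05


@dataclass
class NeuronRecord:
    """One cell's QC metadata plus extracted features — the unit of statistics."""

    neuron_id: str
    embryo_id: str
    age: str
    region: str
    condition: str
    rmp: float
    series_resistance: float
    features: Dict[str, float] = field(default_factory=dict)
    included: Optional[bool] = None
    exclusion_reason: str = ""


def inclusion_flag(age: str, rmp: float, series_resistance: float) -> Tuple[bool, str]:
    """Apply the resting-potential and series-resistance inclusion rules."""
    if age not in RMP_CUTOFF:
        raise ValueError(f"unknown age group {age!r}")
    if not (np.isfinite(rmp) and np.isfinite(series_resistance)):
        raise ValueError("rmp and series resistance must be present and finite")
    reasons = []
    if not rmp < RMP_CUTOFF[age]:
        reasons.append(f"rmp {rmp:.1f} mV not below {RMP_CUTOFF[age]:.0f} mV")
    if series_resistance > SERIES_RESISTANCE_MAX:
        reasons.append(f"series resistance {series_resistance:.1f} MΩ > 10 MΩ")
    return (len(reasons) == 0, "; ".join(reasons))


def apply_inclusion(rec: NeuronRecord) -> NeuronRecord:
    """Set the inclusion flag (and reason when excluded) on a record. Idempotent."""
    rec.included, rec.exclusion_reason = inclusion_flag(
        rec.age, rec.rmp, rec.series_resistance
    )
    return rec


@dataclass
class OutlierResult:
    kept: np.ndarray
    excluded: np.ndarray
    mask: np.ndarray  # True where kept; order preserved


def exclude_outliers(values: Sequence[float], k: float = 2.0) -> OutlierResult:
    """Single-pass ±k·SD outlier rule.

    Mean and sample SD are computed once on the full set; points with
    |x − mean| > k·SD are excluded.  Not iterated.  An all-equal list (SD = 0)
    excludes nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("outlier rule needs at least 3 values")
    sd = float(np.std(x, ddof=1))
    mask = np.abs(x - np.mean(x)) <= k * sd
    return OutlierResult(x[mask], x[~mask], mask)


@dataclass
class TestResult:
    """One statistical comparison, with optional pairwise follow-ups."""

    test: str
    statistic: float
    df: Tuple[float, ...]
    p_value: float
    group_n: Tuple[int, ...]
    group_means: Tuple[float, ...]
    group_sds: Tuple[float, ...]
    comparisons: List[Dict[str, object]] = field(default_factory=list)
    extra: Dict[str, float] = field(default_factory=dict)
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def stars(self) -> str:
        return p_stars(self.p_value)

    @property
    def group_sems(self) -> Tuple[float, ...]:
        return tuple(s / np.sqrt(n) for s, n in zip(self.group_sds, self.group_n))


def p_stars(p: float) -> str:
    """Figure-legend star coding: ns / * / ** / *** / **** at 0.05/0.01/0.001/0.0001."""
    for thresh, sym in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thresh:
            return sym
    return "ns"


def _summaries(groups: Sequence[Sequence[float]]):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    n = np.array([a.size for a in arrs])
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    m = np.array([a.mean() for a in arrs])
    v = np.array([a.var(ddof=1) for a in arrs])
    return arrs, n, m, v


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Unpaired two-sided t-test with Welch's correction."""
    _, n, m, v = _summaries([a, b])
    if v.sum() == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return TestResult(
        test="welch_t",
        statistic=float(res.statistic),
        df=(float(res.df),),
        p_value=float(res.pvalue),
        group_n=tuple(int(x) for x in n),
        group_means=tuple(m),
        group_sds=tuple(np.sqrt(v)),
    )


def _bonferroni_pairs(
    arrs: Sequence[np.ndarray],
    labels: Sequence[str],
    pairs: Sequence[Tuple[int, int]],
    equal_var: bool,
) -> List[Dict[str, object]]:
    m = len(pairs)
    out = []
    for i, j in pairs:
        res = sps.ttest_ind(arrs[i], arrs[j], equal_var=equal_var)
        raw = float(res.pvalue)
        out.append(
            {
                "a": labels[i],
                "b": labels[j],
                "statistic": float(res.statistic),
                "p_raw": raw,
                "p_adjusted": min(1.0, raw * m),
                "stars": p_stars(min(1.0, raw * m)),
            }
        )
    return out


def _pair_indices(k: int, labels: Sequence[str], reference: Optional[str]) -> List[Tuple[int, int]]:
    if reference is None:
        return list(itertools.combinations(range(k), 2))
    ref = list(labels).index(reference)
    return [(ref, j) for j in range(k) if j != ref]


def anova_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    reference: Optional[str] = None,
) -> TestResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise comparisons.

    Pairwise follow-ups are pooled-variance t-tests with raw p multiplied by
    the number of comparisons (capped at 1); all pairs by default, or
    control-referenced when `reference` names a group.
    """
    arrs, n, m, v = _summaries(groups)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrs))]
    f, p = sps.f_oneway(*arrs)
    pairs = _pair_indices(len(arrs), labels, reference)
    return TestResult(
        test="anova_bonferroni",
        statistic=float(f),
        df=(float(len(arrs) - 1), float(n.sum() - len(arrs))),
        p_value=float(p),
        group_n=tuple(int(x) for x in n),
        group_means=tuple(m),
        group_sds=tuple(np.sqrt(v)),
        comparisons=_bonferroni_pairs(arrs, labels, pairs, equal_var=True),
    )


def welch_anova_arrays(n: np.ndarray, mean: np.ndarray, var: np.ndarray):
    """Welch's heteroscedastic one-way ANOVA from group summaries.

    Accepts 1-D summaries (k groups) or 2-D (reps × k) for vectorized
    simulation.  Returns (W statistic, df1, df2, p).
    """
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    k = n.shape[-1]
    w = n / var
    w_sum = w.sum(axis=-1, keepdims=True)
    x_w = (w * mean).sum(axis=-1, keepdims=True) / w_sum
    a = (w * (mean - x_w) ** 2).sum(axis=-1) / (k - 1)
    lam = ((1.0 - w / w_sum) ** 2 / (n - 1.0)).sum(axis=-1)
    b = 2.0 * (k - 2.0) / (k**2 - 1.0) * lam
    stat = a / (1.0 + b)
    df1 = float(k - 1)
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = sps.f.sf(stat, df1, df2)
    return stat, df1, df2, p


def brown_forsythe_arrays(n: np.ndarray, mean: np.ndarray, var: np.ndarray):
    """Brown–Forsythe F* ANOVA for means from group summaries.

    F* = Σ n_i (x̄_i − x̄)² / Σ (1 − n_i/N) s_i², with Satterthwaite
    denominator degrees of freedom.  Returns (F*, df1, df2, p).
    """
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    k = n.shape[-1]
    N = n.sum(axis=-1, keepdims=True)
    grand = (n * mean).sum(axis=-1, keepdims=True) / N
    num = (n * (mean - grand) ** 2).sum(axis=-1)
    c = (1.0 - n / N) * var
    den = c.sum(axis=-1)
    stat = num / den
    df1 = float(k - 1)
    df2 = den**2 / (c**2 / (n - 1.0)).sum(axis=-1)
    p = sps.f.sf(stat, df1, df2)
    return stat, df1, df2, p


def bf_welch_anova(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    reference: Optional[str] = None,
) -> TestResult:
    """Brown–Forsythe and Welch ANOVAs with Bonferroni-adjusted Welch pairs.

    The Welch W statistic and p-value headline the result; the Brown–Forsythe
    F* with its approximate degrees of freedom rides along in ``extra``.
    """
    arrs, n, m, v = _summaries(groups)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrs))]
    w, df1, df2, p_w = welch_anova_arrays(n, m, v)
    f_bf, bdf1, bdf2, p_bf = brown_forsythe_arrays(n, m, v)
    pairs = _pair_indices(len(arrs), labels, reference)
    return TestResult(
        test="bf_welch_anova",
        statistic=float(w),
        df=(df1, float(df2)),
        p_value=float(p_w),
        group_n=tuple(int(x) for x in n),
        group_means=tuple(m),
        group_sds=tuple(np.sqrt(v)),
        comparisons=_bonferroni_pairs(arrs, labels, pairs, equal_var=False),
        extra={
            "bf_statistic": float(f_bf),
            "bf_df1": bdf1,
            "bf_df2": float(bdf2),
            "bf_p_value": float(p_bf),
        },
    )


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro–Wilk normality test (reported; does not gate test selection)."""
    x = np.asarray(values, dtype=float)
    res = sps.shapiro(x)
    return TestResult(
        test="shapiro_wilk",
        statistic=float(res.statistic),
        df=(float(x.size),),
        p_value=float(res.pvalue),
        group_n=(int(x.size),),
        group_means=(float(x.mean()),),
        group_sds=(float(x.std(ddof=1)),),
    )


def run_condition_battery(
    table: pd.DataFrame,
    metrics: Sequence[str],
    condition_col: str = "condition",
    strata: Sequence[str] = ("age", "region"),
    reference: str = "control",
    outlier_k: Optional[float] = 2.0,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run the per-stratum comparison battery over a tidy per-neuron table.

    For each (age × region) stratum and metric: two conditions route to
    Welch's t-test; three or more route to the ANOVA battery (classical
    one-way ANOVA with Bonferroni pairs plus Welch/Brown–Forsythe).  The
    ±2 SD outlier rule is applied per metric within each condition group
    before testing.  Rows excluded by QC (``included == False``) are dropped
    first.  Returns a tidy results table; deterministic given the inputs.
    """
    df = table
    if "included" in df.columns:
        df = df[df["included"].astype(bool)]
    rows: List[Dict[str, object]] = []
    for stratum_key, sub in df.groupby(list(strata)):
        if not isinstance(stratum_key, tuple):
            stratum_key = (stratum_key,)
        conds = sorted(
            sub[condition_col].unique(), key=lambda c: (c != reference, str(c))
        )
        if len(conds) < 2:
            raise ValueError(f"stratum {stratum_key} has fewer than 2 conditions")
        for metric in metrics:
            if metric not in sub.columns:
                raise KeyError(
                    f"metric {metric!r} not in table; available: "
                    f"{sorted(c for c in sub.columns if sub[c].dtype.kind == 'f')}"
                )
            groups, labels = [], []
            for c in conds:
                vals = sub.loc[sub[condition_col] == c, metric].dropna().to_numpy()
                if outlier_k is not None and vals.size >= 3:
                    vals = exclude_outliers(vals, outlier_k).kept
                if vals.size >= 2:
                    groups.append(vals)
                    labels.append(str(c))
            if len(groups) < 2:
                continue
            if len(groups) == 2:
                res = welch_t(groups[0], groups[1])
                results = [res]
            else:
                results = [
                    anova_bonferroni(groups, labels, reference=reference),
                    bf_welch_anova(groups, labels, reference=reference),
                ]
            for res in results:
                row: Dict[str, object] = dict(zip(strata, stratum_key))
                row.update(
                    metric=metric,
                    test=res.test,
                    statistic=res.statistic,
                    df1=res.df[0],
                    df2=res.df[1] if len(res.df) > 1 else np.nan,
                    p_value=res.p_value,
                    stars=res.stars,
                    significant=res.p_value < alpha,
                    groups=",".join(labels),
                    group_n=",".join(str(x) for x in res.group_n),
                    group_means=",".join(f"{x:.6g}" for x in res.group_means),
                    group_sds=",".join(f"{x:.6g}" for x in res.group_sds),
                    group_sems=",".join(f"{x:.6g}" for x in res.group_sems),
                )
                for comp in res.comparisons:
                    rows.append(
                        {
                            **row,
                            "comparison": f"{comp['a']} vs {comp['b']}",
                            "p_raw": comp["p_raw"],
                            "p_adjusted": comp["p_adjusted"],
                        }
                    )
                rows.append(row)
    return pd.DataFrame(rows)
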