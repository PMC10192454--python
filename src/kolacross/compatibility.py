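"""Sexual-compatibility statistics for controlled-pollination trials.

Pod set is the percentage of hand-pollinated flowers that develop into true
pods; pseudo-pod set the percentage producing fruit-like structures without
viable fertilization. Crosses are graded on the field's 0-5 compatibility
scale (0 incompatible ... 5 very highly compatible) and cross types (self vs
hybrid, single vs double) are contrasted with a binomial GLM on the
success/failure counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .crossdata import CrossDataset, CrossSpec, CrossType, PollinationRecord

__all__ = [
    "CompatibilityResult",
    "CrossTypeContrast",
    "ClassDistributionResult",
    "CLASS_NAMES",
    "pod_set_percent",
    "pseudo_pod_set_percent",
    "compatibility_class",
    "summarize_compatibility",
    "cross_type_podset_test",
    "class_distribution_test",
]

#: names of the 0-5 compatibility classes, in scale order
CLASS_NAMES = ("incompatible", "very low", "low", "moderate", "high", "very high")


class ContrastError(ValueError):
    """Cross-type contrast is not computable (wrong group structure)."""


def pod_set_percent(n_pod: int, n_pollinated: int) -> Optional[float]:
    """Pod set %: 100 x pods / flowers pollinated; ``None`` when no flowers
    were pollinated (undefined, never coerced to 0)."""
    if n_pollinated == 0:
        return None
    if not 0 <= n_pod <= n_pollinated:
        raise ValueError(f"n_pod={n_pod} outside [0, {n_pollinated}]")
    return 100.0 * n_pod / n_pollinated


def pseudo_pod_set_percent(n_pseudo: int, n_pollinated: int) -> Optional[float]:
    """Pseudo-pod set %: 100 x pseudo-pods / flowers pollinated."""
    return pod_set_percent(n_pseudo, n_pollinated)


def compatibility_class(pod_set_pct: float) -> int:
    """Grade a pod-set percentage on the 0-5 compatibility scale.

    0 is reserved for exactly zero pod set; class k covers the half-open
    interval (20(k-1), 20k], so 20% -> 1, 20.5% -> 2 and 100% -> 5 (the top
    class includes its upper bound, matching the printed "81-100%" range).
    """
    if not 0.0 <= pod_set_pct <= 100.0:
        raise ValueError(f"pod set {pod_set_pct} outside [0, 100]")
    if pod_set_pct == 0.0:
        return 0
    return min(5, max(1, math.ceil(pod_set_pct / 20.0)))


@dataclass(frozen=True)
class CompatibilityResult:
    """Per-cross compatibility summary: percentages plus 0-5 class."""

    cross: CrossSpec
    pod_set_pct: float
    pseudo_pod_set_pct: float
    n_pollinated_total: Optional[int]
    compat_class: int
    class_name: str


def _per_cross_percentages(
    records: Sequence[PollinationRecord], mode: str
) -> Dict[str, Tuple[float, float, int]]:
    """(pod %, pseudo %, total flowers) per cross under an aggregation mode.

    ``"pooled"`` sums counts over replicates before forming percentages (the
    default); ``"mean"`` averages the replicate percentages.
    """
    by_cross: Dict[str, List[PollinationRecord]] = {}
    for r in records:
        by_cross.setdefault(r.cross.canonical_label, []).append(r)
    out = {}
    for label, recs in by_cross.items():
        total = sum(r.n_pollinated for r in recs)
        if mode == "pooled":
            ps = pod_set_percent(sum(r.n_pod for r in recs), total)
            psp = pseudo_pod_set_percent(sum(r.n_pseudo for r in recs), total)
        elif mode == "mean":
            per_ps = [
                pod_set_percent(r.n_pod, r.n_pollinated)
                for r in recs
                if r.n_pollinated > 0
            ]
            per_psp = [
                pseudo_pod_set_percent(r.n_pseudo, r.n_pollinated)
                for r in recs
                if r.n_pollinated > 0
            ]
            ps = float(np.mean(per_ps)) if per_ps else None
            psp = float(np.mean(per_psp)) if per_psp else None
        else:
            raise ValueError(f"unknown aggregation mode {mode!r}")
        out[label] = (ps, psp, total)
    return out


def summarize_compatibility(dataset: CrossDataset) -> List[CompatibilityResult]:
    """Per-cross pod-set / pseudo-pod-set percentages and compatibility class.

    Uses pollination counts when present (aggregated per the dataset's
    declared mode), otherwise the dataset's printed percentages.
    """
    results: List[CompatibilityResult] = []
    specs = dataset.cross_specs()
    if dataset.pollinations:
        table = _per_cross_percentages(dataset.pollinations, dataset.aggregation)
        for label, (ps, psp, total) in table.items():
            if ps is None:
                continue
            k = compatibility_class(ps)
            results.append(
                CompatibilityResult(specs[label], ps, psp, total, k, CLASS_NAMES[k])
            )
    elif dataset.percentages is not None:
        for label, row in dataset.percentages.iterrows():
            ps = float(row["pod_set_pct"])
            psp = float(row["pseudo_pod_set_pct"])
            k = compatibility_class(ps)
            results.append(
                CompatibilityResult(specs[label], ps, psp, None, k, CLASS_NAMES[k])
            )
    return results


@dataclass(frozen=True)
class CrossTypeContrast:
    """Likelihood-ratio contrast of two cross types on success/failure counts."""

    groups: Tuple[CrossType, CrossType]
    statistic: float  # LR deviance vs intercept-only model, 1 df
    p_value: float
    group_means: Dict[str, float]  # pooled % per group
    separation: bool = False  # a group was all-success or all-failure
    method: str = "binomial GLM (logit), LRT vs intercept-only"


def _pooled_g_statistic(s1: int, f1: int, s2: int, f2: int) -> float:
    """Likelihood-ratio G on the pooled 2x2 success/failure table.

    This equals the binomial-GLM deviance drop for a two-level factor (the
    group MLEs are the pooled proportions), and stays finite under complete
    separation with the 0*log(0)=0 convention.
    """
    cells = np.array([[s1, f1], [s2, f2]], dtype=float)
    total = cells.sum()
    if total == 0:
        return 0.0
    rows = cells.sum(axis=1, keepdims=True)
    cols = cells.sum(axis=0, keepdims=True)
    expect = rows * cols / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(cells > 0, cells * np.log(cells / expect), 0.0)
    return float(2.0 * terms.sum())


def cross_type_podset_test(
    records: Sequence[PollinationRecord],
    types: Dict[str, CrossType],
    outcome: str = "pod",
) -> CrossTypeContrast:
    """Contrast two cross types (e.g. DCC vs DCS) on pod or pseudo-pod set.

    Fits logit(success probability) ~ cross-type on per-record success/failure
    counts by IRLS and reports the likelihood-ratio deviance against the
    intercept-only model (1 df) with its chi-square p-value, plus pooled
    percentages per type. Under complete separation (a type entirely
    successful or unsuccessful) the Wald output is degenerate, so the LRT is
    taken from the pooled 2x2 table and the result flagged.
    """
    if outcome not in ("pod", "pseudo"):
        raise ValueError(f"unknown outcome {outcome!r}")
    by_type: Dict[CrossType, List[PollinationRecord]] = {}
    for r in records:
        t = types[r.cross.canonical_label]
        by_type.setdefault(t, []).append(r)
    if len(by_type) != 2:
        raise ContrastError(
            f"need exactly two cross types, got {sorted(t.value for t in by_type)}"
        )
    (t1, recs1), (t2, recs2) = sorted(by_type.items(), key=lambda kv: kv[0].value)
    for t, recs in ((t1, recs1), (t2, recs2)):
        if sum(r.n_pollinated for r in recs) == 0:
            raise ContrastError(f"cross type {t.value} has zero total pollinations")

    def _counts(r: PollinationRecord) -> Tuple[int, int]:
        s = r.n_pod if outcome == "pod" else r.n_pseudo
        return s, r.n_pollinated - s

    s1 = sum(_counts(r)[0] for r in recs1)
    n1 = sum(r.n_pollinated for r in recs1)
    s2 = sum(_counts(r)[0] for r in recs2)
    n2 = sum(r.n_pollinated for r in recs2)
    group_means = {t1.value: 100.0 * s1 / n1, t2.value: 100.0 * s2 / n2}
    separation = s1 in (0, n1) or s2 in (0, n2)

    if separation:
        stat = _pooled_g_statistic(s1, n1 - s1, s2, n2 - s2)
    else:
        import warnings as _warnings

        import statsmodels.api as sm

        endog = np.array([_counts(r) for r in recs1 + recs2], dtype=float)
        exog = sm.add_constant(
            np.array([0.0] * len(recs1) + [1.0] * len(recs2))
        )
        with _warnings.catch_warnings():
            # saturated fits (one cross per type) warn but the deviance is valid
            _warnings.simplefilter("ignore")
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        stat = float(fit.null_deviance - fit.deviance)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return CrossTypeContrast(
        groups=(t1, t2),
        statistic=stat,
        p_value=p,
        group_means=group_means,
        separation=separation,
        method=(
            "LRT from pooled 2x2 table (complete separation)"
            if separation
            else "binomial GLM (logit), LRT vs intercept-only"
        ),
    )


@dataclass(frozen=True)
class ClassDistributionResult:
    """Chi-square test of the 0-5 class distribution plus pairwise
    class-proportion comparisons (Holm-adjusted)."""

    counts: Tuple[int, ...]  # occupancy of classes 0..5
    statistic: float
    df: int
    p_value: float
    pairwise: pd.DataFrame  # class_a, class_b, statistic, p_raw, p_holm


def class_distribution_test(
    classes: Iterable[int], by: Optional[CrossType] = None
) -> ClassDistributionResult:
    """Test whether crosses spread uniformly over the six compatibility
    classes (goodness-of-fit, df=5) and compare class proportions pairwise.

    The pairwise comparison of classes i and j is the binomial score test of
    an even split among the crosses falling in either class
    (z = (c_i - c_j) / sqrt(c_i + c_j)); p-values are Holm-adjusted. ``by``
    only annotates which cross type the classes belong to.
    """
    ks = list(classes)
    if not ks:
        raise ValueError("empty class list")
    if any(not 0 <= k <= 5 for k in ks):
        raise ValueError("classes must be integers in 0..5")
    counts = np.bincount(ks, minlength=6)
    if (counts > 0).sum() < 2:
        # degenerate single-class data still has a valid GOF statistic
        pass
    n = counts.sum()
    stat, p = stats.chisquare(counts, f_exp=np.full(6, n / 6.0))
    rows = []
    from statsmodels.stats.multitest import multipletests

    for i in range(6):
        for j in range(i + 1, 6):
            ci, cj = int(counts[i]), int(counts[j])
            if ci + cj == 0:
                z, praw = 0.0, 1.0
            else:
                z = (ci - cj) / math.sqrt(ci + cj)
                praw = 2.0 * stats.norm.sf(abs(z))
            rows.append((i, j, z, praw))
    df = pd.DataFrame(rows, columns=["class_a", "class_b", "statistic", "p_raw"])
    df["p_holm"] = multipletests(df["p_raw"], method="holm")[1]
    return ClassDistributionResult(
        counts=tuple(int(c) for c in counts),
        statistic=float(stat),
        df=5,
        p_value=float(p),
        pairwise=df,
    )


def results_frame(results: Sequence[CompatibilityResult]) -> pd.DataFrame:
    """Flat per-cross table (CSV-ready) of compatibility results."""
    return pd.DataFrame(
        [
            {
                "cross_label": r.cross.canonical_label,
                "pod_set_pct": r.pod_set_pct,
                "pseudo_pod_set_pct": r.pseudo_pod_set_pct,
                "n_pollinated_total": r.n_pollinated_total,
                "compat_class": r.compat_class,
                "class_name": r.class_name,
            }
            for r in results
        ]
    )
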