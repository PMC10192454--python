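"""Yield and nut-quality summaries and group tests.

Outturn (%) is the peeled-nut weight as a percentage of unpeeled-nut weight.
Per-cross trait means come with standard errors; differences among crosses
are tested with one-way ANOVA when its residuals look normal
(Shapiro-Wilk gate) and with Kruskal-Wallis otherwise, followed by LSD-style
pairwise comparisons at P < 0.05 rendered as compact letter displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .crossdata import CrossSpec, TraitRecord

__all__ = [
    "TraitSummary",
    "GroupTestResult",
    "outturn_percent",
    "summarize_traits",
    "trait_group_test",
    "compact_letters",
]


def outturn_percent(
    weight_peeled: float, weight_unpeeled: float
) -> Optional[float]:
    """Outturn %: 100 x peeled / unpeeled nut weight.

    ``None`` (undefined) when the unpeeled weight is zero; peeled weight
    exceeding unpeeled weight is a measurement error, not an outturn > 100%.
    """
    if weight_unpeeled == 0:
        return None
    if weight_peeled < 0 or weight_unpeeled < 0:
        raise ValueError("nut weights must be non-negative")
    if weight_peeled > weight_unpeeled:
        raise ValueError(
            f"peeled weight {weight_peeled} exceeds unpeeled {weight_unpeeled}"
        )
    return 100.0 * weight_peeled / weight_unpeeled


@dataclass(frozen=True)
class TraitSummary:
    """Mean, standard error of the mean and n for one cross x trait.

    With a single observation the se is undefined and reported as ``None``
    (never 0); an all-missing trait yields n=0 and a missing mean.
    """

    cross: CrossSpec
    trait: str
    mean: Optional[float]
    se: Optional[float]
    n: int


def summarize_traits(
    records: Sequence[TraitRecord], traits: Optional[Sequence[str]] = None
) -> List[TraitSummary]:
    """Per cross x trait mean, sem (s/sqrt(n), ddof=1) and n; missing values
    are excluded pairwise."""
    from .crossdata import TRAIT_FIELDS

    traits = list(traits) if traits is not None else list(TRAIT_FIELDS)
    by_cross: Dict[str, List[TraitRecord]] = {}
    specs: Dict[str, CrossSpec] = {}
    for r in records:
        label = r.cross.canonical_label
        by_cross.setdefault(label, []).append(r)
        specs.setdefault(label, r.cross)
    out: List[TraitSummary] = []
    for label, recs in by_cross.items():
        for trait in traits:
            vals = [r.value(trait) for r in recs if r.value(trait) is not None]
            n = len(vals)
            if n == 0:
                out.append(TraitSummary(specs[label], trait, None, None, 0))
            elif n == 1:
                out.append(TraitSummary(specs[label], trait, float(vals[0]), None, 1))
            else:
                arr = np.asarray(vals, dtype=float)
                se = float(arr.std(ddof=1) / math.sqrt(n))
                out.append(TraitSummary(specs[label], trait, float(arr.mean()), se, n))
    return out


def summaries_frame(summaries: Sequence[TraitSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cross_label": s.cross.canonical_label,
                "trait": s.trait,
                "mean": s.mean,
                "se": s.se,
                "n": s.n,
            }
            for s in summaries
        ]
    )


@dataclass(frozen=True)
class GroupTestResult:
    """One-way group test for a trait across crosses.

    ``method`` records which test actually ran ("anova" or
    "kruskal-wallis"); ``letters`` is the compact letter display — crosses
    sharing a letter are not significantly different at ``alpha``.
    """

    trait: str
    method: str
    statistic: float
    df: Tuple[float, float]
    p_value: float
    letters: Dict[str, str]
    alpha: float
    normality_p: Optional[float] = None
    degenerate: bool = False
    group_means: Dict[str, float] = field(default_factory=dict)


def compact_letters(
    groups: Sequence[str], significant_pairs: Sequence[Tuple[str, str]]
) -> Dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Guarantees letter-sharing is exactly equivalent to the pairwise decision:
    two groups share a letter iff their pair was NOT declared significant.
    """
    sets: List[set] = [set(groups)]
    for a, b in significant_pairs:
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            for candidate in (s - {a}, s - {b}):
                if candidate and not any(candidate <= other for other in sets):
                    sets = [t for t in sets if not t < candidate]
                    sets.append(candidate)
    # stable ordering: letters sorted by their first group in input order
    index = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(index[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: Dict[str, str] = {g: "" for g in groups}
    for rank, s in enumerate(sets):
        ch = alphabet[rank % len(alphabet)] * (1 + rank // len(alphabet))
        for g in s:
            letters[g] += ch
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def _lsd_pairs(
    means: Dict[str, float],
    ns: Dict[str, int],
    mse: float,
    df_error: float,
    alpha: float,
) -> List[Tuple[str, str]]:
    """Pairs significantly different by Fisher's LSD with pooled MSE."""
    tcrit = stats.t.ppf(1 - alpha / 2, df_error)
    sig = []
    labels = list(means)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            lsd = tcrit * math.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
            if abs(means[a] - means[b]) > lsd:
                sig.append((a, b))
    return sig


def _dunn_pairs(
    values: Dict[str, np.ndarray], alpha: float
) -> List[Tuple[str, str]]:
    """Rank-based pairwise comparisons after Kruskal-Wallis (Dunn's z with
    tie correction, unadjusted — protected by the global test)."""
    all_vals = np.concatenate(list(values.values()))
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks: Dict[str, float] = {}
    pos = 0
    for g, v in values.items():
        mean_ranks[g] = float(ranks[pos : pos + len(v)].mean())
        pos += len(v)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    zcrit = stats.norm.ppf(1 - alpha / 2)
    sig = []
    labels = list(values)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            sd = math.sqrt(base_var * (1 / len(values[a]) + 1 / len(values[b])))
            if sd > 0 and abs(mean_ranks[a] - mean_ranks[b]) / sd > zcrit:
                sig.append((a, b))
    return sig


def trait_group_test(
    records: Sequence[TraitRecord], trait: str, alpha: float = 0.05
) -> GroupTestResult:
    """Test trait differences among crosses (one-way layout).

    Runs ANOVA; if the residuals fail Shapiro-Wilk at 0.05 the test switches
    to Kruskal-Wallis (and the pairwise rule to Dunn's rank comparisons).
    When the global test is significant at ``alpha``, pairwise comparisons
    produce compact letter groupings; otherwise all groups share one letter.
    """
    by_cross: Dict[str, List[float]] = {}
    for r in records:
        v = r.value(trait)
        if v is not None:
            by_cross.setdefault(r.cross.canonical_label, []).append(float(v))
    groups = {g: np.asarray(v, dtype=float) for g, v in by_cross.items()}
    if len(groups) < 2:
        raise ValueError(f"need >= 2 crosses with data for trait {trait!r}")
    labels = list(groups)
    means = {g: float(v.mean()) for g, v in groups.items()}
    ns = {g: len(v) for g, v in groups.items()}
    n_total = sum(ns.values())
    k = len(groups)

    within_ss = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    if within_ss == 0.0:
        # every group constant: exact-tie degenerate result
        distinct = len(set(means.values()))
        if distinct == 1:
            return GroupTestResult(
                trait, "anova", 0.0, (k - 1, n_total - k), 1.0,
                {g: "a" for g in labels}, alpha, degenerate=True,
                group_means=means,
            )
        sig = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]
               if means[a] != means[b]]
        return GroupTestResult(
            trait, "anova", math.inf, (k - 1, n_total - k), 0.0,
            compact_letters(labels, sig), alpha, degenerate=True,
            group_means=means,
        )

    if any(n < 2 for n in ns.values()):
        use_anova = False  # ANOVA needs replication in every group
        normality_p = None
    else:
        resid = np.concatenate([v - v.mean() for v in groups.values()])
        normality_p = float(stats.shapiro(resid).pvalue) if len(resid) >= 3 else 1.0
        use_anova = normality_p >= 0.05

    if use_anova:
        f_stat, p = stats.f_oneway(*groups.values())
        df = (k - 1, n_total - k)
        mse = within_ss / (n_total - k)
        sig = (
            _lsd_pairs(means, ns, mse, df[1], alpha)
            if p < alpha
            else []
        )
        method = "anova"
        statistic = float(f_stat)
    else:
        h_stat, p = stats.kruskal(*groups.values())
        df = (k - 1, float("nan"))
        sig = _dunn_pairs(groups, alpha) if p < alpha else []
        method = "kruskal-wallis"
        statistic = float(h_stat)

    return GroupTestResult(
        trait=trait,
        method=method,
        statistic=statistic,
        df=df,
        p_value=float(p),
        letters=compact_letters(labels, sig),
        alpha=alpha,
        normality_p=normality_p,
        group_means=means,
    )
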