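"""Heterosis estimation for single and double hybrid crosses.

Three statistics per hybrid cross and trait, all in percent:

* mid-parent heterosis (MPH, *di*): deviation of the F1 from the mean of its
  two parents' self-cross values, ``100 (F1 - MP) / MP`` with
  ``MP = (P1 + P2) / 2``;
* heterobeltiosis (BPH, *dii*): deviation from the better (larger) parent,
  ``100 (F1 - BP) / BP`` with ``BP = max(P1, P2)``;
* economic heterosis (ECH): deviation from a recommended standard variety,
  ``100 (F1 - SV) / SV`` — here the released hybrids GX1/46 × GX1/16
  (standard 1) and JX1/5 × JX1/9 (standard 2).

Parental values are pedigree-aware: for a single cross A × B the parents'
values are the self-crosses A × A and B × B; for a double cross
(A × B) × (C × D) they are the double-selfs (A × B) × (A × B) and
(C × D) × (C × D). Whenever a denominator is zero or a parental record is
absent, the statistic is *undefined* (``None`` with provenance), never a
numeric sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .crossdata import CrossDataset, CrossSpec

__all__ = [
    "ReferenceSet",
    "HeterosisResult",
    "DEFAULT_TRAITS",
    "STANDARD1_LABEL",
    "STANDARD2_LABEL",
    "mid_parent_value",
    "mid_parent_heterosis",
    "heterobeltiosis",
    "economic_heterosis",
    "cross_value_table",
    "compute_heterosis_table",
    "results_frame",
]

#: traits scored by default (all larger-is-better)
DEFAULT_TRAITS = ("pod_set", "outturn", "brix")

STANDARD1_LABEL = "GX1/46 × GX1/16"
STANDARD2_LABEL = "JX1/5 × JX1/9"


class ConfigurationError(ValueError):
    """A named reference cross is absent from the dataset."""


def mid_parent_value(p1: Optional[float], p2: Optional[float]) -> Optional[float]:
    """Arithmetic mean of the two parental values; ``None`` if either is
    missing."""
    if p1 is None or p2 is None:
        return None
    return 0.5 * (p1 + p2)


def mid_parent_heterosis(
    f1: float, p1: float, p2: float
) -> Optional[float]:
    """MPH % = 100 (F1 - MP) / MP; undefined (``None``) when MP = 0."""
    mp = mid_parent_value(p1, p2)
    if mp is None or mp == 0:
        return None
    if mp < 0:
        raise ValueError("mid-parent value cannot be negative for these traits")
    return 100.0 * (f1 - mp) / mp


def heterobeltiosis(f1: float, p1: float, p2: float) -> Optional[float]:
    """BPH % = 100 (F1 - BP) / BP with BP the larger parent; undefined when
    BP = 0."""
    bp = max(p1, p2)
    if bp == 0:
        return None
    if bp < 0:
        raise ValueError("better-parent value cannot be negative for these traits")
    return 100.0 * (f1 - bp) / bp


def economic_heterosis(f1: float, standard: float) -> Optional[float]:
    """ECH % = 100 (F1 - SV) / SV against a standard variety; undefined when
    the standard value is not positive."""
    if standard <= 0:
        return None
    return 100.0 * (f1 - standard) / standard


@dataclass(frozen=True)
class ReferenceSet:
    """Trait values of the two standard varieties (for economic heterosis)."""

    standard1_label: str
    standard1_values: Dict[str, Optional[float]]
    standard2_label: str
    standard2_values: Dict[str, Optional[float]]

    @classmethod
    def from_dataset(
        cls,
        dataset: CrossDataset,
        traits: Sequence[str] = DEFAULT_TRAITS,
        standard1_label: str = STANDARD1_LABEL,
        standard2_label: str = STANDARD2_LABEL,
        overrides: Optional[Dict[str, Dict[str, float]]] = None,
    ) -> "ReferenceSet":
        """Look up the standards' observed per-cross means in the dataset.

        ``overrides`` may supply {label: {trait: value}} externally; any
        standard absent from both dataset and overrides raises
        :class:`ConfigurationError` listing the missing labels.
        """
        table = cross_value_table(dataset, traits)
        overrides = overrides or {}
        values = {}
        missing = []
        for label in (standard1_label, standard2_label):
            if label in overrides:
                values[label] = {t: overrides[label].get(t) for t in traits}
            elif label in table.index:
                values[label] = {
                    t: (None if pd.isna(table.at[label, t]) else float(table.at[label, t]))
                    for t in traits
                }
            else:
                missing.append(label)
        if missing:
            raise ConfigurationError(
                f"reference cross(es) absent from dataset: {', '.join(missing)}"
            )
        return cls(
            standard1_label,
            values[standard1_label],
            standard2_label,
            values[standard2_label],
        )


@dataclass(frozen=True)
class HeterosisResult:
    """Heterosis statistics for one hybrid cross x trait, with the labels of
    the parent / reference records used (provenance). Undefined statistics
    are ``None``."""

    cross: CrossSpec
    trait: str
    f1_value: Optional[float]
    p1_value: Optional[float]
    p2_value: Optional[float]
    mid_parent: Optional[float]
    mph_pct: Optional[float]
    bph_pct: Optional[float]
    ech1_pct: Optional[float]
    ech2_pct: Optional[float]
    provenance: Dict[str, Optional[str]] = field(default_factory=dict)


def cross_value_table(
    dataset: CrossDataset, traits: Sequence[str] = DEFAULT_TRAITS
) -> pd.DataFrame:
    """Per-cross trait values (rows = canonical labels, columns = traits).

    ``pod_set`` / ``pseudo_pod_set`` come from the pollination counts under
    the dataset's aggregation mode (or from printed percentages); other
    traits are per-cross means of the trait records — the trial scores
    heterosis on the overall mean of each cross over replications.
    """
    from .compatibility import summarize_compatibility

    labels = list(dataset.cross_specs())
    table = pd.DataFrame(index=labels, columns=list(traits), dtype=float)
    pct_traits = {"pod_set", "pseudo_pod_set"} & set(traits)
    if pct_traits:
        for r in summarize_compatibility(dataset):
            lab = r.cross.canonical_label
            if "pod_set" in pct_traits:
                table.at[lab, "pod_set"] = r.pod_set_pct
            if "pseudo_pod_set" in pct_traits:
                table.at[lab, "pseudo_pod_set"] = r.pseudo_pod_set_pct
    record_traits = [t for t in traits if t not in ("pod_set", "pseudo_pod_set")]
    if record_traits and dataset.traits:
        df = dataset.trait_frame()
        df[record_traits] = df[record_traits].astype(float)
        means = df.groupby("cross_label")[record_traits].mean()
        for t in record_traits:
            table.loc[means.index, t] = means[t]
    return table


def compute_heterosis_table(
    dataset: CrossDataset,
    refs: Optional[ReferenceSet] = None,
    traits: Sequence[str] = DEFAULT_TRAITS,
) -> List[HeterosisResult]:
    """Score every hybrid (non-self) cross in the dataset for MPH, BPH and
    (when ``refs`` is given) economic heterosis against both standards.

    Self crosses are the parental reference points and are not themselves
    scored. A hybrid whose parental self-cross is absent gets undefined
    statistics with the missing label recorded in provenance.
    """
    specs = dataset.cross_specs()
    table = cross_value_table(dataset, traits)

    def _get(label: str, trait: str) -> Optional[float]:
        if label not in table.index:
            return None
        v = table.at[label, trait]
        return None if pd.isna(v) else float(v)

    results: List[HeterosisResult] = []
    for label, spec in specs.items():
        if spec.is_self:
            continue
        p1_label = f"{spec.female.label} × {spec.female.label}"
        p2_label = f"{spec.male.label} × {spec.male.label}"
        p1_exists = p1_label in table.index
        p2_exists = p2_label in table.index
        for trait in traits:
            f1 = _get(label, trait)
            p1 = _get(p1_label, trait)
            p2 = _get(p2_label, trait)
            mp = mid_parent_value(p1, p2)
            mph = bph = None
            if f1 is not None and p1 is not None and p2 is not None:
                mph = mid_parent_heterosis(f1, p1, p2)
                bph = heterobeltiosis(f1, p1, p2)
            ech1 = ech2 = None
            if refs is not None and f1 is not None:
                sv1 = refs.standard1_values.get(trait)
                sv2 = refs.standard2_values.get(trait)
                ech1 = economic_heterosis(f1, sv1) if sv1 is not None else None
                ech2 = economic_heterosis(f1, sv2) if sv2 is not None else None
            results.append(
                HeterosisResult(
                    cross=spec,
                    trait=trait,
                    f1_value=f1,
                    p1_value=p1,
                    p2_value=p2,
                    mid_parent=mp,
                    mph_pct=mph,
                    bph_pct=bph,
                    ech1_pct=ech1,
                    ech2_pct=ech2,
                    provenance={
                        "p1_label": p1_label if p1_exists else None,
                        "p2_label": p2_label if p2_exists else None,
                        "p1_missing": None if p1_exists else p1_label,
                        "p2_missing": None if p2_exists else p2_label,
                        "standard1": refs.standard1_label if refs else None,
                        "standard2": refs.standard2_label if refs else None,
                    },
                )
            )
    return results


def results_frame(results: Sequence[HeterosisResult]) -> pd.DataFrame:
    """Flat CSV-ready table: cross, trait, f1, p1, p2, mp, mph_pct, bph_pct,
    ech1_pct, ech2_pct, provenance."""
    columns = [
        "cross_label", "trait", "f1", "p1", "p2", "mid_parent",
        "mph_pct", "bph_pct", "ech1_pct", "ech2_pct", "p1_label", "p2_label",
    ]
    return pd.DataFrame(
        [
            {
                "cross_label": r.cross.canonical_label,
                "trait": r.trait,
                "f1": r.f1_value,
                "p1": r.p1_value,
                "p2": r.p2_value,
                "mid_parent": r.mid_parent,
                "mph_pct": r.mph_pct,
                "bph_pct": r.bph_pct,
                "ech1_pct": r.ech1_pct,
                "ech2_pct": r.ech2_pct,
                "p1_label": r.provenance.get("p1_label"),
                "p2_label": r.provenance.get("p2_label"),
            }
            for r in results
        ],
        columns=columns,
    )
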