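"""Synthetic crossing-trial generator with sporophytic self-incompatibility.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline can be exercised (and its estimators verified
against known truth) without field data:

* a germplasm of genotypes carrying S-locus genotypes under a strict
  dominance hierarchy — pollen expresses the phenotype of the pollen-producing
  plant (sporophytic SI), so a cross fails whenever the two parents' expressed
  S-specificities overlap; every self-pollination is therefore incompatible;
* binomial pod set per pollination, with success probability ``p_compat`` for
  S-compatible crosses and a small leakage probability ``p_leak`` for
  incompatible ones (partial self-compatibility);
* pseudo-pods drawn from the flowers that did not set a pod, at a higher rate
  in incompatible crosses — reproducing the elevated pseudo-pod set observed
  in selfs;
* trait values with additive + dominance architecture: each genotype carries
  additive values per trait, an F1 expresses the mid-parent value inflated by
  ``1 + dominance_gain`` when the cross is compatible and non-self, so
  mid-parent heterosis is recoverable (it equals ``100 × dominance_gain``
  exactly when noise is off).

Trait measurements carry multiplicative environmental noise per measured pod
(coefficient of variation ``env_cv``); a replicate's trait record is the mean
over the pods it harvested, which is how the trial itself measures traits.

Randomness is keyed by ``(seed, cross label, replicate)``, so adding crosses
to a design never perturbs the records of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .crossdata import (
    CrossDataset,
    CrossEntity,
    CrossSpec,
    GenotypeID,
    PollinationRecord,
    TraitRecord,
    classify_cross_type,
)

__all__ = [
    "SAllele",
    "SGenotype",
    "SimGenotype",
    "SimParams",
    "SimulatedTrial",
    "TRAIT_BASELINES",
    "si_phenotype",
    "is_cross_compatible",
    "make_population",
    "make_design",
    "simulate_crossing_trial",
]


@dataclass(frozen=True, order=True)
class SAllele:
    """An S-locus allele; ``index`` is its rank in the dominance hierarchy
    (1 = most dominant)."""

    index: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("S-allele index must be >= 1")


@dataclass(frozen=True)
class SGenotype:
    """An unordered pair of S-alleles (possibly identical: homozygote)."""

    alleles: Tuple[SAllele, SAllele]

    def __post_init__(self) -> None:
        a, b = self.alleles
        object.__setattr__(self, "alleles", tuple(sorted((a, b))))


def si_phenotype(g: SGenotype, codominant: bool = False) -> frozenset:
    """S-specificities expressed by the (diploid) sporophyte.

    Under the default strict dominance hierarchy only the more dominant allele
    (smaller rank index) is expressed; with ``codominant=True`` both are.
    """
    a, b = g.alleles
    if codominant:
        return frozenset({a, b})
    return frozenset({min(a, b)})


def is_cross_compatible(
    stigma_parent: SGenotype, pollen_parent: SGenotype, codominant: bool = False
) -> bool:
    """Sporophytic SI rule: the cross succeeds iff the expressed phenotype
    sets of stigma parent and pollen parent are disjoint."""
    return not (
        si_phenotype(stigma_parent, codominant)
        & si_phenotype(pollen_parent, codominant)
    )


# Baseline (mean, between-genotype CV) per trait, in trait units. Magnitudes
# follow the printed self-cross tables of the trial; outturn is derived from
# the unpeeled weight and the outturn percentage rather than drawn separately.
TRAIT_BASELINES: Dict[str, Tuple[float, float]] = {
    "number_of_pods": (15.0, 0.35),
    "pod_weight": (150.0, 0.35),
    "pod_length": (15.0, 0.15),
    "pod_width": (7.0, 0.15),
    "nuts_per_pod": (6.0, 0.25),
    "nut_length": (4.0, 0.15),
    "nut_width": (2.5, 0.15),
    "weight_unpeeled": (60.0, 0.30),
    "outturn": (75.0, 0.08),
    "brix": (12.0, 0.25),
    "potential_alcohol": (7.0, 0.20),
    "firmness": (14.0, 0.15),
}

_DEFAULT_GAIN = {
    "pod_weight": 0.25,
    "weight_unpeeled": 0.20,
    "nuts_per_pod": 0.15,
    "outturn": 0.10,
    "brix": 0.15,
}


@dataclass(frozen=True)
class SimParams:
    """Parameters of the simulated crossing design.

    Defaults follow the trial protocol: 20 pollinations per cross, replicated
    by 3 pollinators. ``p_compat``/``p_leak`` are per-pollination pod-set
    probabilities for S-compatible and S-incompatible crosses;
    ``p_pseudo_*`` the pseudo-pod probabilities among remaining flowers;
    ``dominance_gain`` maps trait → proportional F1 dominance deviation;
    ``env_cv`` the coefficient of variation of per-pod measurement noise.
    """

    n_genotypes: int = 30
    n_s_alleles: int = 6
    p_compat: float = 0.75
    p_leak: float = 0.10
    p_pseudo_incompat: float = 0.35
    p_pseudo_compat: float = 0.05
    dominance_gain: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GAIN)
    )
    env_cv: float = 0.10
    n_pollinated: int = 20
    n_replicates: int = 3
    codominant: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_compat": self.p_compat,
            "p_leak": self.p_leak,
            "p_pseudo_incompat": self.p_pseudo_incompat,
            "p_pseudo_compat": self.p_pseudo_compat,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.p_compat <= self.p_leak:
            raise ValueError("p_compat must exceed p_leak")
        if self.p_pseudo_incompat < self.p_pseudo_compat:
            raise ValueError("p_pseudo_incompat must be >= p_pseudo_compat")
        if self.n_pollinated < 1 or self.n_replicates < 1:
            raise ValueError("n_pollinated and n_replicates must be >= 1")
        if self.env_cv < 0:
            raise ValueError("env_cv must be >= 0")


@dataclass(frozen=True)
class SimGenotype:
    id: GenotypeID
    s_genotype: SGenotype
    additive_values: Dict[str, float]


@dataclass
class SimulatedTrial:
    """A simulated dataset plus the ground truth used to generate it."""

    dataset: CrossDataset
    truth: dict
    params: SimParams


def _rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator keyed by (seed, *keys)."""
    tag = zlib.crc32("|".join(str(k) for k in keys).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


def make_population(params: SimParams) -> List[SimGenotype]:
    """Draw the germplasm: S-alleles uniform (homozygotes allowed), additive
    trait values from the trait baselines. Deterministic under the seed."""
    if params.n_s_alleles < 2:
        raise ValueError(
            "n_s_alleles must be >= 2: with a single S-allele no cross is compatible"
        )
    rng = _rng(params.seed, "population")
    pop: List[SimGenotype] = []
    for i in range(params.n_genotypes):
        a, b = rng.integers(1, params.n_s_alleles + 1, size=2)
        additive: Dict[str, float] = {}
        for trait, (mean, cv) in TRAIT_BASELINES.items():
            v = float(rng.normal(mean, cv * mean))
            additive[trait] = max(v, 0.05 * mean)  # weights/counts stay positive
        # keep F1 outturn (mid-parent x (1+gain)) strictly below 100%
        additive["outturn"] = min(additive["outturn"], 88.0)
        pop.append(
            SimGenotype(
                id=GenotypeID("SIM", str(i + 1)),
                s_genotype=SGenotype((SAllele(int(a)), SAllele(int(b)))),
                additive_values=additive,
            )
        )
    return pop


def make_design(
    pop: Sequence[SimGenotype],
    n_single: int = 40,
    n_double: int = 0,
    include_selfs: bool = True,
    seed: int = 0,
) -> List[CrossSpec]:
    """Build a crossing design: all selfs (parent references for heterosis),
    ``n_single`` random single hybrid crosses and ``n_double`` random double
    hybrid crosses (with the double-selfs of their component hybrids)."""
    rng = _rng(seed, "design")
    ids = [g.id for g in pop]
    design: List[CrossSpec] = []
    seen = set()

    def add(spec: CrossSpec) -> None:
        if spec.canonical_label not in seen:
            seen.add(spec.canonical_label)
            design.append(spec)

    if include_selfs:
        for g in ids:
            e = CrossEntity.genotype(g)
            add(CrossSpec(e, e, label=f"{g.label} × {g.label}"))
    max_tries = 50 * (n_single + n_double + 1)
    tries = 0
    n_pairs = 0
    while n_pairs < n_single:
        tries += 1
        if tries > max_tries:
            raise ValueError("design too large for the population size")
        i, j = rng.choice(len(ids), size=2, replace=False)
        e1, e2 = CrossEntity.genotype(ids[i]), CrossEntity.genotype(ids[j])
        spec = CrossSpec(e1, e2, label=f"{ids[i].label} × {ids[j].label}")
        if spec.canonical_label not in seen:
            add(spec)
            n_pairs += 1
    n_dbl = 0
    while n_dbl < n_double:
        tries += 1
        if tries > max_tries:
            raise ValueError("design too large for the population size")
        i, j, k, l = rng.choice(len(ids), size=4, replace=False)
        f = CrossEntity.hybrid(ids[i], ids[j])
        m = CrossEntity.hybrid(ids[k], ids[l])
        spec = CrossSpec(f, m, label=f"{f.label} × {m.label}")
        if spec.canonical_label not in seen:
            add(spec)
            add(CrossSpec(f, f, label=f"{f.label} × {f.label}"))
            add(CrossSpec(m, m, label=f"{m.label} × {m.label}"))
            n_dbl += 1
    return design


def _resolve_entity(
    entity: CrossEntity, by_id: Dict[GenotypeID, SimGenotype], params: SimParams
) -> Tuple[SGenotype, Dict[str, float]]:
    """S-genotype and additive values of a cross entity.

    A hybrid-pair entity is built as an F1 of its two members: one allele from
    each member (seeded draw keyed by the entity label) and additive values
    equal to the parental mean inflated by the dominance gain.
    """
    for m in entity.members:
        if m not in by_id:
            raise KeyError(f"genotype {m.label!r} not in population")
    if entity.kind == "genotype":
        g = by_id[entity.members[0]]
        return g.s_genotype, dict(g.additive_values)
    p1, p2 = (by_id[m] for m in entity.members)
    rng = _rng(params.seed, "entity", entity.label)
    a1 = p1.s_genotype.alleles[int(rng.integers(2))]
    a2 = p2.s_genotype.alleles[int(rng.integers(2))]
    additive = {}
    for trait in TRAIT_BASELINES:
        mid = 0.5 * (p1.additive_values[trait] + p2.additive_values[trait])
        gain = params.dominance_gain.get(trait, 0.0)
        additive[trait] = mid * (1.0 + gain)
    return SGenotype((a1, a2)), additive


def _noise_mean(rng: np.random.Generator, cv: float, n: int) -> float:
    """Mean of ``n`` multiplicative per-pod deviates with mean 1 and CV
    ``cv`` (gamma distributed, so strictly positive). Exactly 1 when cv=0."""
    if cv == 0.0:
        return 1.0
    shape = 1.0 / cv**2
    return float(np.mean(rng.gamma(shape, 1.0 / shape, size=n)))


def simulate_crossing_trial(
    pop: Sequence[SimGenotype],
    design: Sequence[CrossSpec],
    params: SimParams,
) -> SimulatedTrial:
    """Simulate the crossing trial for ``design`` over population ``pop``.

    Per cross × replicate: ``n_pod ~ Binomial(n_pollinated, p)`` with
    ``p = p_compat`` or ``p_leak`` by the SI rule; pseudo-pods are then drawn
    from the remaining flowers at ``p_pseudo_incompat`` / ``p_pseudo_compat``;
    the rest are dropped (counts always conserve). One trait record is emitted
    per replicate; its expectation is the entity mid-parent value times
    ``1 + dominance_gain`` for compatible non-self crosses.
    """
    by_id = {g.id: g for g in pop}
    ds = CrossDataset(
        metadata={"simulated": True, "seed": params.seed},
        aggregation="pooled",
    )
    truth_crosses: dict = {}
    for spec in design:
        label = spec.canonical_label
        s_f, add_f = _resolve_entity(spec.female, by_id, params)
        s_m, add_m = _resolve_entity(spec.male, by_id, params)
        compatible = is_cross_compatible(s_f, s_m, params.codominant)
        heterotic = compatible and not spec.is_self
        p_pod = params.p_compat if compatible else params.p_leak
        p_pseudo = params.p_pseudo_compat if compatible else params.p_pseudo_incompat

        expected: Dict[str, float] = {}
        for trait in TRAIT_BASELINES:
            mid = 0.5 * (add_f[trait] + add_m[trait])
            gain = params.dominance_gain.get(trait, 0.0) if heterotic else 0.0
            expected[trait] = mid * (1.0 + gain)
        expected["weight_peeled"] = (
            expected["weight_unpeeled"] * expected["outturn"] / 100.0
        )

        for rep in range(1, params.n_replicates + 1):
            rng = _rng(params.seed, label, rep)
            n_pod = int(rng.binomial(params.n_pollinated, p_pod))
            remaining = params.n_pollinated - n_pod
            n_pseudo = int(rng.binomial(remaining, p_pseudo))
            n_dropped = remaining - n_pseudo
            ds.pollinations.append(
                PollinationRecord(
                    cross=spec,
                    replicate=rep,
                    n_pollinated=params.n_pollinated,
                    n_pod=n_pod,
                    n_pseudo=n_pseudo,
                    n_dropped=n_dropped,
                )
            )
            n_measured = max(n_pod, 1)
            values = {}
            for trait in TRAIT_BASELINES:
                values[trait] = expected[trait] * _noise_mean(
                    rng, params.env_cv, n_measured
                )
            values["outturn"] = min(values["outturn"], 100.0)
            values["weight_peeled"] = min(
                values["weight_unpeeled"] * values["outturn"] / 100.0,
                values["weight_unpeeled"],  # guard 1-ulp overshoot at outturn=100
            )
            ds.traits.append(TraitRecord(cross=spec, **values))

        truth_crosses[label] = {
            "compatible": bool(compatible),
            "is_self": bool(spec.is_self),
            "cross_type": classify_cross_type(spec).value,
            "p_pod": p_pod,
            "p_pseudo": p_pseudo,
            "expected_pod_set_pct": 100.0 * p_pod,
            "expected_traits": expected,
        }

    truth = {
        "crosses": truth_crosses,
        "params": {
            "n_genotypes": params.n_genotypes,
            "n_s_alleles": params.n_s_alleles,
            "p_compat": params.p_compat,
            "p_leak": params.p_leak,
            "p_pseudo_incompat": params.p_pseudo_incompat,
            "p_pseudo_compat": params.p_pseudo_compat,
            "dominance_gain": dict(params.dominance_gain),
            "env_cv": params.env_cv,
            "n_pollinated": params.n_pollinated,
            "n_replicates": params.n_replicates,
            "codominant": params.codominant,
            "seed": params.seed,
        },
        "note": (
            "pseudo-pod leakage is a binomial modelling assumption of the "
            "generator, not an observed biological mechanism"
        ),
    }
    return SimulatedTrial(dataset=ds, truth=truth, params=params)
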