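"""Sporophytic-SI simulator: dominance rule, determinism, sampling laws."""

import itertools

import numpy as np
import pytest

import kolacross as kc
from kolacross.simulate import SAllele, SGenotype, _rng


def g(a, b):
    return SGenotype((SAllele(a), SAllele(b)))


class TestSIRule:
    def test_dominant_allele_expressed(self):
        assert kc.si_phenotype(g(1, 3)) == {SAllele(1)}
        assert kc.si_phenotype(g(2, 2)) == {SAllele(2)}

    def test_codominant_option_expresses_both(self):
        assert kc.si_phenotype(g(1, 3), codominant=True) == {SAllele(1), SAllele(3)}

    def test_every_self_is_incompatible(self):
        for a, b in itertools.combinations_with_replacement(range(1, 5), 2):
            assert not kc.is_cross_compatible(g(a, b), g(a, b))
            assert not kc.is_cross_compatible(g(a, b), g(a, b), codominant=True)

    def test_shared_dominant_blocks_disjoint_allows(self):
        assert not kc.is_cross_compatible(g(1, 2), g(1, 3))  # both express S1
        assert kc.is_cross_compatible(g(3, 4), g(1, 2))  # {S3} vs {S1}


class TestMakePopulation:
    def test_deterministic_and_sized(self):
        params = kc.SimParams(n_genotypes=10, seed=42)
        p1, p2 = kc.make_population(params), kc.make_population(params)
        assert len(p1) == 10
        assert all(len(a.s_genotype.alleles) == 2 for a in p1)
        assert p1 == p2

    def test_single_allele_pool_rejected(self):
        with pytest.raises(ValueError, match="n_s_alleles"):
            kc.make_population(kc.SimParams(n_s_alleles=1))

    def test_compatible_pair_fraction_matches_enumeration(self):
        """With 2 S-alleles under strict dominance the compatible fraction of
        ordered pairs follows from enumerating the 3 genotype classes."""
        # brute-force oracle: enumerate unordered genotypes over {S1,S2} with
        # Hardy-Weinberg-free uniform allele draws (each allele uniform)
        combos = [(a, b) for a in (1, 2) for b in (1, 2)]  # ordered draws
        compat = total = 0
        for ga in combos:
            for gb in combos:
                total += 1
                if kc.is_cross_compatible(g(*ga), g(*gb)):
                    compat += 1
        expected = compat / total  # = 2 * P(expr S1) * P(expr S2) = 0.375
        assert expected == pytest.approx(0.375)

        params = kc.SimParams(n_genotypes=400, n_s_alleles=2, seed=5)
        pop = kc.make_population(params)
        pairs = [
            (a, b) for a in pop for b in pop if a.id != b.id
        ]
        frac = np.mean(
            [kc.is_cross_compatible(a.s_genotype, b.s_genotype) for a, b in pairs]
        )
        # SE of the fraction at 400 genotypes is ~2.5e-2 on correlated pairs
        assert frac == pytest.approx(expected, abs=0.05)


class TestSimulateTrial:
    def test_counts_conserve(self, noisy_trial):
        for r in noisy_trial.dataset.pollinations:
            assert r.n_pod + r.n_pseudo + r.n_dropped == r.n_pollinated

    def test_degenerate_probabilities(self):
        params = kc.SimParams(
            n_genotypes=12, p_compat=1.0, p_leak=0.0,
            p_pseudo_incompat=0.0, p_pseudo_compat=0.0, env_cv=0.0, seed=1,
        )
        pop = kc.make_population(params)
        design = kc.make_design(pop, n_single=10, seed=1)
        trial = kc.simulate_crossing_trial(pop, design, params)
        truth = trial.truth["crosses"]
        for r in trial.dataset.pollinations:
            lab = r.cross.canonical_label
            expected = r.n_pollinated if truth[lab]["compatible"] else 0
            assert r.n_pod == expected

    def test_repeat_call_is_byte_identical(self, noisy_trial):
        params = noisy_trial.params
        pop = kc.make_population(params)
        design = kc.make_design(pop, n_single=30, n_double=10, seed=params.seed)
        again = kc.simulate_crossing_trial(pop, design, params)
        assert again.dataset.pollination_frame().equals(
            noisy_trial.dataset.pollination_frame()
        )
        assert again.dataset.trait_frame().equals(noisy_trial.dataset.trait_frame())

    def test_adding_crosses_preserves_existing_records(self):
        """The RNG is keyed per (seed, cross, replicate), so growing the
        design never rewrites history."""
        params = kc.SimParams(n_genotypes=15, seed=9)
        pop = kc.make_population(params)
        small = kc.make_design(pop, n_single=5, seed=9)
        large = small + kc.make_design(pop, n_single=12, seed=10)[-6:]
        t_small = kc.simulate_crossing_trial(pop, small, params)
        t_large = kc.simulate_crossing_trial(pop, large, params)
        small_labels = {s.canonical_label for s in small}
        recs_small = {
            (r.cross.canonical_label, r.replicate): (r.n_pod, r.n_pseudo)
            for r in t_small.dataset.pollinations
        }
        recs_large = {
            (r.cross.canonical_label, r.replicate): (r.n_pod, r.n_pseudo)
            for r in t_large.dataset.pollinations
            if r.cross.canonical_label in small_labels
        }
        assert recs_small == recs_large

    def test_mean_pod_set_within_binomial_band(self):
        """Compatible crosses at p=0.8 with 60 flowers each: the pooled mean
        stays inside the 99% band from binomial sampling theory."""
        params = kc.SimParams(n_genotypes=40, p_compat=0.8, seed=3)
        pop = kc.make_population(params)
        design = kc.make_design(pop, n_single=120, include_selfs=False, seed=3)
        trial = kc.simulate_crossing_trial(pop, design, params)
        truth = trial.truth["crosses"]
        compat_labels = [l for l, t in truth.items() if t["compatible"]]
        assert len(compat_labels) >= 50
        labels = set(compat_labels[:50])
        pods = flowers = 0
        for r in trial.dataset.pollinations:
            if r.cross.canonical_label in labels:
                pods += r.n_pod
                flowers += r.n_pollinated
        mean_pct = 100.0 * pods / flowers
        half_width = 2.576 * 100.0 * np.sqrt(0.8 * 0.2 / flowers)
        assert abs(mean_pct - 80.0) < half_width

    def test_more_compatible_success_does_not_lose_pods(self):
        """Raising p_compat (same seed discipline) does not decrease total
        pods among compatible crosses."""
        totals = {}
        for p in (0.6, 0.9):
            params = kc.SimParams(n_genotypes=30, p_compat=p, seed=17)
            pop = kc.make_population(params)
            design = kc.make_design(pop, n_single=40, include_selfs=False, seed=17)
            trial = kc.simulate_crossing_trial(pop, design, params)
            truth = trial.truth["crosses"]
            totals[p] = sum(
                r.n_pod
                for r in trial.dataset.pollinations
                if truth[r.cross.canonical_label]["compatible"]
            )
        assert totals[0.9] >= totals[0.6]

    def test_unknown_genotype_in_design_rejected(self):
        params = kc.SimParams(n_genotypes=5, seed=0)
        pop = kc.make_population(params)
        stranger = kc.parse_cross_label("SIM/1 × SIM/99")
        with pytest.raises(KeyError, match="SIM/99"):
            kc.simulate_crossing_trial(pop, [stranger], params)

    def test_truth_covers_every_cross(self, noisy_trial):
        labels = {r.cross.canonical_label for r in noisy_trial.dataset.pollinations}
        assert labels == set(noisy_trial.truth["crosses"])

    def test_hybrid_entity_takes_one_allele_per_parent(self):
        params = kc.SimParams(n_genotypes=6, seed=2)
        pop = kc.make_population(params)
        from kolacross.simulate import _resolve_entity

        by_id = {p.id: p for p in pop}
        ent = kc.CrossEntity.hybrid(pop[0].id, pop[1].id)
        s, additive = _resolve_entity(ent, by_id, params)
        a1, a2 = s.alleles
        assert {a1, a2} <= set(pop[0].s_genotype.alleles) | set(
            pop[1].s_genotype.alleles
        )
        # F1 additive value = mid-parent inflated by the dominance gain
        for trait, gain in params.dominance_gain.items():
            mid = 0.5 * (
                pop[0].additive_values[trait] + pop[1].additive_values[trait]
            )
            assert additive[trait] == pytest.approx(mid * (1 + gain))


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_compat": 1.2},
            {"p_compat": 0.1, "p_leak": 0.2},
            {"p_pseudo_incompat": 0.1, "p_pseudo_compat": 0.2},
            {"n_pollinated": 0},
            {"env_cv": -0.1},
        ],
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            kc.SimParams(**kwargs)

    def test_rng_keying_is_stable(self):
        a = _rng(1, "x", 2).integers(0, 1000, 5)
        b = _rng(1, "x", 2).integers(0, 1000, 5)
        c = _rng(1, "y", 2).integers(0, 1000, 5)
        assert (a == b).all() and not (a == c).all()
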