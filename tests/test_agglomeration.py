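import numpy as np
import pytest

from spikecad.agglomeration import (Assembly, AssemblyCatalog, DetectionConfig,
                                    agglomerate_at_scale, detect_assemblies,
                                    extend_assembly, pattern_series,
                                    prune_catalog, seed_pairs)
from spikecad.agglomeration import TestBudget as Budget
from spikecad.io import SpikeDataset
from spikecad.stats import SegmentScheme, pair_test


def bernoulli_counts(rng, T, p):
    return (rng.random(T) < p).astype(np.int64)


def make_assembly(units, lags, delta=0.1, p=1e-4, counts=None, T=50):
    z = counts if counts is not None else np.ones(T, dtype=np.int64)
    return Assembly(units=tuple(units), lags=tuple(lags), delta=delta,
                    p_value=p, joint_count=int(z.sum()), activation_counts=z)


class TestBudgetFormulas:
    def test_seed_budget_formula(self):
        b = Budget(alpha=0.05, l_max=10, n_units=3)
        assert b.seed_tests == 3 * 2 * 21 // 2 == 63
        assert b.seed_level() == pytest.approx(0.05 / 63)

    def test_extension_budget(self):
        b = Budget(alpha=0.05, l_max=5)
        assert b.extension_level(4, 3) == pytest.approx(0.05 / (4 * 3 * 11))


class TestSeedPairs:
    def test_embedded_lagged_pair_found(self):
        rng = np.random.default_rng(0)
        T = 4000
        base = bernoulli_counts(rng, T, 0.15)
        counts = {
            0: base + bernoulli_counts(rng, T, 0.02),
            1: np.roll(base, 2) + bernoulli_counts(rng, T, 0.02),
            2: bernoulli_counts(rng, T, 0.15),
        }
        budget = Budget(alpha=0.05, l_max=5)
        seeds, Z, results = seed_pairs(counts, 0.1, 5, budget)
        assert len(seeds) == 1
        assert seeds[0].units == (0, 1) and seeds[0].lags == (0, 2)
        assert Z[frozenset((0, 1))]
        assert len(results) == 3   # all pairs tested once

    def test_independent_units_rarely_seed(self):
        # Bonferroni keeps the family-wise error well below alpha = 0.05;
        # allow 4/40 (P < 1e-3 under a true rate of 0.05)
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            counts = {i: bernoulli_counts(rng, 1500, 0.1) for i in range(4)}
            seeds, _, _ = seed_pairs(counts, 0.1, 5,
                                     Budget(alpha=0.05, l_max=5))
            hits += bool(seeds)
        assert hits <= 4

    def test_fast_path_matches_pair_test(self):
        # the cached seed loop must agree with the reference implementation
        rng = np.random.default_rng(1)
        counts = {0: rng.binomial(10, 0.05, 950) + 1,   # nonzero floor
                  1: rng.binomial(10, 0.06, 950) + 2,
                  2: rng.binomial(3, 0.02, 950)}
        _, _, results = seed_pairs(counts, 0.1, 4,
                                   Budget(alpha=0.05, l_max=4))
        level = Budget(alpha=0.05, l_max=4, n_units=3).seed_level()
        for r in results:
            a, b = r.pair
            ref = pair_test(counts[a], counts[b], delta=0.1, l_max=4,
                            corrected_alpha=level, pair=(a, b))
            assert r.selected_lag == ref.selected_lag
            assert r.difference == ref.difference
            assert r.variance_estimate == pytest.approx(ref.variance_estimate)
            assert r.p_value == pytest.approx(ref.p_value)


class TestExtension:
    def test_coupled_third_unit_joins(self):
        rng = np.random.default_rng(2)
        T = 4000
        base = bernoulli_counts(rng, T, 0.15)
        counts = {
            0: base + bernoulli_counts(rng, T, 0.02),
            1: np.roll(base, 1) + bernoulli_counts(rng, T, 0.02),
            2: np.roll(base, 3) + bernoulli_counts(rng, T, 0.02),
        }
        pair = make_assembly((0, 1), (0, 1),
                             counts=pattern_series(counts, (0, 1), (0, 1)))
        ext = extend_assembly(pair, 2, counts, l_max=5, corrected_alpha=1e-4)
        assert ext is not None
        assert ext.units == (0, 1, 2) and ext.lags == (0, 1, 3)

    def test_independent_candidate_rejected(self):
        rng = np.random.default_rng(3)
        T = 4000
        base = bernoulli_counts(rng, T, 0.15)
        counts = {0: base, 1: np.roll(base, 1), 2: bernoulli_counts(rng, T, 0.1)}
        pair = make_assembly((0, 1), (0, 1),
                             counts=pattern_series(counts, (0, 1), (0, 1)))
        assert extend_assembly(pair, 2, counts, 5, 1e-4) is None

    def test_member_candidate_rejected(self):
        counts = {0: np.ones(300, dtype=np.int64), 1: np.ones(300, dtype=np.int64)}
        pair = make_assembly((0, 1), (0, 1), counts=counts[0])
        with pytest.raises(ValueError):
            extend_assembly(pair, 1, counts, 5, 0.05)

    def test_higher_order_structure_needs_formed_pair(self):
        # A and B independent; C fires iff A and B agree (XNOR): every pair
        # is independent, but C depends on the joint (A,B) occurrence, which
        # only the activation-series test can see.
        rng = np.random.default_rng(4)
        T = 6000
        a = bernoulli_counts(rng, T, 0.5)
        b = bernoulli_counts(rng, T, 0.5)
        c = np.roll((a == b).astype(np.int64), 1)
        counts = {0: a, 1: b, 2: c}
        seeds, _, results = seed_pairs(counts, 0.1, 3,
                                       Budget(alpha=0.05, l_max=3))
        assert not seeds   # no pairwise structure to seed from
        ab = make_assembly((0, 1), (0, 0),
                           counts=pattern_series(counts, (0, 1), (0, 0)))
        ext = extend_assembly(ab, 2, counts, l_max=3, corrected_alpha=1e-6)
        assert ext is not None and ext.lags == (0, 0, 1)


class TestAgglomerateAtScale:
    def test_chain_recovered_and_subsets_pruned(self):
        rng = np.random.default_rng(5)
        T = 5000
        base = bernoulli_counts(rng, T, 0.15)
        counts = {}
        for i, lag in enumerate((0, 1, 2, 3)):
            counts[i] = np.roll(base, lag) + bernoulli_counts(rng, T, 0.02)
        counts[4] = bernoulli_counts(rng, T, 0.15)
        found, Z, _ = agglomerate_at_scale(counts, 0.1, l_max=5,
                                           budget=Budget(alpha=0.05, l_max=5))
        assert len(found) == 1
        a = found[0]
        assert a.unit_set == {0, 1, 2, 3}
        units, lags = a.normalized()
        assert units == (0, 1, 2, 3) and lags == (0, 1, 2, 3)

    def test_disjoint_assemblies_not_merged(self):
        rng = np.random.default_rng(6)
        T = 5000
        b1 = bernoulli_counts(rng, T, 0.15)
        b2 = bernoulli_counts(rng, T, 0.15)
        counts = {0: b1, 1: np.roll(b1, 1),
                  2: b2, 3: np.roll(b2, 2)}
        found, _, _ = agglomerate_at_scale(counts, 0.1, l_max=5,
                                           budget=Budget(alpha=0.05, l_max=5))
        sets = {a.unit_set for a in found}
        assert sets == {frozenset({0, 1}), frozenset({2, 3})}

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        T = 3000
        base = bernoulli_counts(rng, T, 0.2)
        counts = {i: np.roll(base, i) + bernoulli_counts(rng, T, 0.02)
                  for i in range(3)}
        r1 = agglomerate_at_scale(dict(counts), 0.1, 5)[0]
        r2 = agglomerate_at_scale(dict(reversed(list(counts.items()))), 0.1, 5)[0]
        assert [(a.units, a.lags, a.p_value) for a in r1] == \
               [(a.units, a.lags, a.p_value) for a in r2]


class TestHierarchicalVariant:
    def test_dendrogram_fusion_recovers_nested_structure(self):
        from spikecad.agglomeration import agglomerate_hierarchical
        rng = np.random.default_rng(12)
        T = 5000
        base = bernoulli_counts(rng, T, 0.15)
        counts = {0: base + bernoulli_counts(rng, T, 0.02),
                  1: np.roll(base, 1) + bernoulli_counts(rng, T, 0.02),
                  2: np.roll(base, 2) + bernoulli_counts(rng, T, 0.02),
                  3: bernoulli_counts(rng, T, 0.15)}
        fused = agglomerate_hierarchical(counts, 0.1, l_max=5)
        # lowest-p pair fuses first, then absorbs the third coupled unit;
        # the independent unit never joins
        assert fused, "no fusion happened"
        assert fused[-1].unit_set <= {0, 1, 2}
        assert all(3 not in a.unit_set for a in fused)
        top = max(fused, key=lambda a: a.n_units)
        assert top.unit_set == {0, 1, 2}
        units, lags = top.normalized()
        assert lags == tuple(sorted(units))  # lag equals unit index by design

    def test_no_fusion_on_independent_units(self):
        from spikecad.agglomeration import agglomerate_hierarchical
        rng = np.random.default_rng(13)
        counts = {i: bernoulli_counts(rng, 2000, 0.1) for i in range(3)}
        assert agglomerate_hierarchical(counts, 0.1, l_max=5) == []


class TestPruneCatalog:
    def _catalog(self, assemblies):
        return AssemblyCatalog(assemblies=assemblies, unit_ids=list(range(6)),
                               deltas=(0.1, 0.2), l_max=5, alpha=0.05)

    def test_within_scale_subset_removed(self):
        big = make_assembly((0, 1, 2), (0, 1, 2), delta=0.1, p=1e-6)
        small = make_assembly((0, 1), (0, 1), delta=0.1, p=1e-8)
        cat = prune_catalog(self._catalog([big, small]))
        assert [a.unit_set for a in cat.assemblies] == [{0, 1, 2}]

    def test_lag_variant_keeps_lowest_p(self):
        a1 = make_assembly((0, 1), (0, 1), delta=0.1, p=0.001)
        a2 = make_assembly((0, 1), (0, 2), delta=0.1, p=0.01)
        cat = prune_catalog(self._catalog([a1, a2]))
        assert len(cat.assemblies) == 1 and cat.assemblies[0].lags == (0, 1)

    def test_cosine_pruning_across_scales(self):
        a1 = make_assembly((0, 1, 2), (0, 0, 0), delta=0.1, p=1e-6)
        a2 = make_assembly((0, 1, 2), (0, 0, 0), delta=0.2, p=1e-4)
        cat = prune_catalog(self._catalog([a1, a2]), cosine_threshold=0.3)
        assert len(cat.assemblies) == 1
        assert cat.assemblies[0].p_value == 1e-6

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            prune_catalog(self._catalog([]), cosine_threshold=1.5)


class TestDetectAssemblies:
    def test_empty_ish_dataset_gives_empty_catalog(self):
        rng = np.random.default_rng(8)
        units = {i: np.sort(rng.uniform(0, 100, 20)) for i in range(3)}
        ds = SpikeDataset(units=units, span=(0.0, 100.0))
        cat = detect_assemblies(ds, deltas=(0.1,), l_max=3)
        assert len(cat) == 0
        assert cat.pair_tests is not None and len(cat.pair_tests) == 3

    def test_characteristic_scale_is_argmin_p(self):
        rng = np.random.default_rng(9)
        base = np.sort(rng.uniform(0, 500, 4000))
        jitter = rng.normal(0, 0.002, base.size)
        units = {0: base,
                 1: np.sort(np.clip(base + 0.01 + jitter, 0, 500)),
                 2: np.sort(rng.uniform(0, 500, 2500))}
        ds = SpikeDataset(units=units, span=(0.0, 500.0))
        cat = detect_assemblies(ds, deltas=(0.01, 0.1), l_max=3)
        pairs = [a for a in cat.assemblies if a.unit_set == {0, 1}]
        assert pairs
        best = min(pairs, key=lambda a: a.p_value)
        assert all(a.delta_star == best.delta for a in pairs)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectionConfig(deltas=(0.1, 0.05))
        with pytest.raises(ValueError):
            DetectionConfig(alpha=1.5)
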