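"""Masking levels: exact removal counts, identities, purity, determinism."""

import numpy as np
import pytest

from conftest import random_hg
from metaddi.augment import (AugmentationConfig, build_augmented_set, mask_edges,
                             mask_features, mask_subgraph)
from metaddi.metapath import MetaPathSpec, available_specs, build_subgraphs, count_paths


@pytest.fixture
def hg():
    return random_hg(np.random.default_rng(2), n_drugs=10, max_attrs=8)


@pytest.fixture
def sgs(hg):
    return build_subgraphs(hg)


class TestMaskFeatures:
    def test_zero_ratio_is_identity(self, hg):
        out = mask_features(hg, 0.0, np.random.default_rng(0))
        for t in hg.incidence:
            assert np.array_equal(out.incidence[t], hg.incidence[t])

    def test_exact_column_count_removed(self, hg):
        n_c = hg.incidence["C"].shape[1]
        out = mask_features(hg, 0.4, np.random.default_rng(0))
        removed = int((out.incidence["C"].sum(axis=0) == 0).sum()
                      - (hg.incidence["C"].sum(axis=0) == 0).sum())
        assert removed == round(0.4 * n_c)

    def test_input_not_mutated(self, hg):
        before = {t: M.copy() for t, M in hg.incidence.items()}
        mask_features(hg, 0.5, np.random.default_rng(1))
        for t in before:
            assert np.array_equal(hg.incidence[t], before[t])

    def test_masked_protein_loses_ppi_edges(self, hg):
        out = mask_features(hg, 0.5, np.random.default_rng(3))
        gone = np.flatnonzero(out.incidence["P"].sum(axis=0) == 0)
        assert not out.ppi[gone].any() and not out.ppi[:, gone].any()

    def test_masking_the_only_shared_attribute_removes_paths(self):
        hg = random_hg(np.random.default_rng(0), n_drugs=2, types=("C", "P"),
                       max_attrs=2)
        hg.incidence["C"] = np.array([[1, 1], [1, 0]])  # c0 shared, c1 private
        hg.attr_ids["C"] = ["c0", "c1"]
        # try seeds until the shared column c0 is the one masked
        for seed in range(20):
            out = mask_features(hg, 0.5, np.random.default_rng(seed))
            if out.incidence["C"][:, 0].sum() == 0:
                assert count_paths(out, MetaPathSpec("DCD"))[0, 1] == 0
                return
        pytest.fail("shared column never selected for masking")

    def test_never_removes_all_columns(self, hg):
        out = mask_features(hg, 0.99, np.random.default_rng(0))
        for t in out.incidence:
            if hg.incidence[t].shape[1] > 0:
                kept = (out.incidence[t].sum(axis=0) > 0).sum()
                assert kept >= 1 or hg.incidence[t].sum() == 0


class TestMaskEdges:
    def test_zero_ratio_is_identity(self, sgs):
        out = mask_edges(sgs, 0.0, np.random.default_rng(0))
        for a, b in zip(out.graphs, sgs.graphs):
            assert np.array_equal(a, b)

    def test_exact_edge_count_survives(self, sgs):
        for ae in (0.1, 0.3, 0.5):
            out = mask_edges(sgs, ae, np.random.default_rng(0))
            for a, b in zip(out.graphs, sgs.graphs):
                m = int(np.triu(b, 1).sum())
                expect = m - int(np.floor(ae * m + 0.5))  # round half away from zero
                assert int(np.triu(a, 1).sum()) == expect

    def test_symmetry_preserved(self, sgs):
        out = mask_edges(sgs, 0.5, np.random.default_rng(0))
        out.validate()

    def test_empty_graph_passes_through(self, sgs):
        empty = sgs.copy()
        for g in empty.graphs:
            g[:] = 0
        out = mask_edges(empty, 0.5, np.random.default_rng(0))
        for g in out.graphs:
            assert not g.any()

    def test_survival_frequency_matches_rate(self, sgs):
        # Monte-Carlo: each edge survives with frequency ~ 1 - ae
        ae, n_rep = 0.3, 400
        g0 = sgs.graphs[0]
        m = int(np.triu(g0, 1).sum())
        if m < 2:
            pytest.skip("degenerate sub-graph")
        iu, ju = np.nonzero(np.triu(g0, 1))
        survival = np.zeros(m)
        for rep in range(n_rep):
            out = mask_edges(sgs, ae, np.random.default_rng(rep))
            survival += out.graphs[0][iu, ju]
        exact = 1 - round(ae * m) / m  # without-replacement survival rate
        se = np.sqrt(exact * (1 - exact) / n_rep)
        assert np.all(np.abs(survival / n_rep - exact) < max(4 * se, 0.08))


class TestMaskSubgraph:
    def test_zero_probability_never_drops(self, sgs):
        for rep in range(50):
            assert len(mask_subgraph(sgs, 0.0, np.random.default_rng(rep))) == len(sgs)

    def test_unit_probability_always_drops_exactly_one(self, sgs):
        for rep in range(50):
            assert len(mask_subgraph(sgs, 1.0, np.random.default_rng(rep))) == len(sgs) - 1

    def test_single_graph_never_dropped(self, sgs):
        from metaddi.metapath import SubGraphSet
        one = SubGraphSet([sgs.graphs[0].copy()], [sgs.names[0]], [sgs.k_values[0]])
        out = mask_subgraph(one, 1.0, np.random.default_rng(0))
        assert len(out) == 1

    def test_drop_frequency_within_binomial_ci(self, sgs):
        from scipy import stats
        n_rep = 2000
        for ag in (0.1, 0.3, 0.5):
            drops = sum(
                len(mask_subgraph(sgs, ag, np.random.default_rng((hash(ag) % 10_000) + rep))) < len(sgs)
                for rep in range(n_rep))
            lo, hi = stats.binom.interval(0.99, n_rep, ag)
            assert lo <= drops <= hi


class TestBuildAugmentedSet:
    def test_none_mode_is_exact_identity(self, hg, sgs):
        cfg = AugmentationConfig(af=0.3, ae=0.3, ag=0.5, mode="none", seed=0)
        out = build_augmented_set(hg, available_specs(hg), cfg, epoch=0,
                                  k_values=dict(zip(sgs.names, sgs.k_values)))
        assert out.names == sgs.names
        for a, b in zip(out.graphs, sgs.graphs):
            assert np.array_equal(a, b)

    def test_fmask_only_leaves_edge_and_graph_levels_identity(self, hg, sgs):
        cfg = AugmentationConfig(af=0.0, ae=0.9, ag=1.0, mode="f", seed=0)
        # with af=0 and only the f level active nothing changes at all
        out = build_augmented_set(hg, available_specs(hg), cfg, epoch=0,
                                  k_values=dict(zip(sgs.names, sgs.k_values)))
        assert len(out) == len(sgs)
        for a, b in zip(out.graphs, sgs.graphs):
            assert np.array_equal(a, b)

    def test_gmask_only_can_shrink_set(self, hg, sgs):
        cfg = AugmentationConfig(af=0.9, ae=0.9, ag=1.0, mode="g", seed=0)
        out = build_augmented_set(hg, available_specs(hg), cfg, epoch=0,
                                  k_values=dict(zip(sgs.names, sgs.k_values)))
        assert len(out) == len(sgs) - 1
        # edge masking inactive: surviving graphs equal the clean ones
        for name, g in zip(out.names, out.graphs):
            assert np.array_equal(g, sgs.graphs[sgs.names.index(name)])

    def test_deterministic_given_seed_and_epoch(self, hg, sgs):
        cfg = AugmentationConfig(af=0.2, ae=0.3, ag=0.5, mode="full", seed=9)
        ks = dict(zip(sgs.names, sgs.k_values))
        for epoch in (0, 3):
            a = build_augmented_set(hg, available_specs(hg), cfg, epoch, ks)
            b = build_augmented_set(hg, available_specs(hg), cfg, epoch, ks)
            assert a.names == b.names
            for ga, gb in zip(a.graphs, b.graphs):
                assert np.array_equal(ga, gb)

    def test_outputs_remain_valid_adjacencies(self, hg, sgs):
        cfg = AugmentationConfig(af=0.3, ae=0.4, ag=0.5, mode="full", seed=1)
        ks = dict(zip(sgs.names, sgs.k_values))
        for epoch in range(5):
            build_augmented_set(hg, available_specs(hg), cfg, epoch, ks).validate()
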