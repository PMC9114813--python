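"""Expression inference: FPKM arithmetic, SPM, the NB Wald DE screen,
fuzzy c-means, co-expression modules and hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orphanforge.expression import (benjamini_hochberg, coexpression_modules,
                                    de_screen, enrichment, expressed_flags,
                                    fpkm, fuzzy_cmeans, module_trait_and_hubs,
                                    spm, spm_table, standardize_profiles)
from orphanforge.synthetic import (simulate_counts, simulate_de_counts,
                                   simulate_module_blocks, simulate_trends)


class TestFpkm:
    def test_formula(self):
        out = fpkm(np.array([[10.0]]), np.array([1000.0]), np.array([1e6]))
        assert out[0, 0] == pytest.approx(10.0)

    def test_zero_counts_zero_fpkm(self):
        out = fpkm(np.array([[0.0]]), np.array([500.0]), np.array([1e6]))
        assert out[0, 0] == 0.0

    def test_doubling_total_halves_fpkm(self):
        c = np.array([[40.0], [60.0]])
        l = np.array([800.0, 1200.0])
        assert np.allclose(fpkm(c, l, np.array([2e6])),
                           fpkm(c, l, np.array([1e6])) / 2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            fpkm(np.array([[1.0]]), np.array([0.0]), np.array([1e6]))


class TestExpressedFlags:
    def test_threshold_boundaries(self):
        f = np.array([[0.019, 0.001], [0.021, 0.0]])
        flags = expressed_flags(f, threshold=0.02)
        assert flags.tolist() == [False, True]

    def test_mean_rule_alternative(self):
        f = np.array([[0.03, 0.0]])          # mean 0.015 below threshold
        assert expressed_flags(f, rule="any")[0]
        assert not expressed_flags(f, rule="mean")[0]


class TestSpm:
    @pytest.mark.parametrize("x,idx,expected", [
        ([5, 0, 0, 0, 0], 0, 1.0),
        ([1, 1], 0, 0.7071),
        ([9, 1, 1, 1, 1], 0, 9 / np.sqrt(85)),
    ])
    def test_examples(self, x, idx, expected):
        assert spm(np.array(x, dtype=float))[idx] == pytest.approx(expected, abs=1e-4)

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8),
           st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, xs, k):
        x = np.array(xs)
        assert np.allclose(spm(k * x), spm(x))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            spm(np.zeros(4))

    def test_specific_gene_recovery_pipeline(self):
        recovered, fp = [], []
        for seed in range(3):
            em, truth = simulate_counts(seed=seed)
            f = fpkm(em.counts, em.gene_lengths)
            tab = spm_table(f, em.gene_ids, em.sample_ids, em.design)
            called = set(tab[tab.specific_tissue.notna()].gene_id)
            planted = set(truth[truth.is_specific].gene_id)
            recovered.append(len(called & planted) / len(planted))
            fp.append(len(called - planted))
        assert min(recovered) >= 0.96
        assert max(fp) <= 5

    def test_called_tissue_matches_planted_tissue(self):
        em, truth = simulate_counts(seed=1)
        f = fpkm(em.counts, em.gene_lengths)
        tab = spm_table(f, em.gene_ids, em.sample_ids, em.design).set_index("gene_id")
        for gid, row in truth[truth.is_specific].iterrows():
            if gid in tab.index and tab.loc[gid].specific_tissue is not None:
                assert tab.loc[gid].specific_tissue == row.specific_tissue


class TestDeScreen:
    def test_log2fc_of_planted_ratio(self):
        # identical libraries, 400 vs 100 mean counts -> log2fc close to 2
        rng = np.random.default_rng(0)
        n = 200
        base = rng.lognormal(5, 0.5, size=n)
        counts = np.column_stack([rng.poisson(base, n) for _ in range(3)]
                                 + [rng.poisson(base, n) for _ in range(3)])
        counts[0] = [400, 400, 400, 1600, 1600, 1600]
        res = de_screen(counts, [f"g{i}" for i in range(n)],
                        ["a"] * 3 + ["b"] * 3, ("a", "b"))
        assert res.log2fc[0] == pytest.approx(2.0, abs=0.05)

    def test_fdr_and_power_on_planted_truth(self):
        fdrs, powers = [], []
        for seed in range(5):
            counts, groups, truth = simulate_de_counts(seed=seed)
            res = de_screen(counts, list(truth.gene_id), groups,
                            ("control", "treated"))
            called = set(res[res.is_de].gene_id)
            true_de = set(truth[truth.is_de].gene_id)
            fdrs.append(len(called - true_de) / max(1, len(called)))
            powers.append(len(called & true_de) / len(true_de))
        assert max(fdrs) <= 0.10
        assert min(powers) >= 0.95

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            de_screen(np.ones((5, 3)), list("abcde"), ["a", "a", "b"], ("a", "b"))


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.2])
        assert np.allclose(adj, [0.03, 0.03, 0.2])

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        assert np.all(benjamini_hochberg(p) >= p - 1e-12)


class TestFuzzyCmeans:
    def test_single_cluster_full_membership(self):
        x = np.random.default_rng(0).normal(size=(20, 4))
        fc = fuzzy_cmeans(x, c=1)
        assert np.allclose(fc.memberships, 1.0)

    def test_equidistant_point_balanced_membership(self):
        x = np.vstack([np.full((20, 2), -1.0)
                       + np.random.default_rng(1).normal(0, 0.01, (20, 2)),
                       np.full((20, 2), 1.0)
                       + np.random.default_rng(2).normal(0, 0.01, (20, 2)),
                       [[0.0, 0.0]]])
        fc = fuzzy_cmeans(x, c=2, seed=3)
        assert fc.memberships[-1] == pytest.approx([0.5, 0.5], abs=0.05)

    def test_objective_non_increasing(self):
        profiles, _ = simulate_trends(seed=5)
        fc = fuzzy_cmeans(standardize_profiles(profiles), c=2, seed=5)
        obj = np.array(fc.objective)
        assert np.all(np.diff(obj) <= 1e-9)

    def test_trend_screening_recovers_planted_clusters(self):
        accs = []
        for seed in range(3):
            profiles, labels = simulate_trends(seed=seed)
            fc = fuzzy_cmeans(standardize_profiles(profiles), c=2, seed=seed)
            screened = fc.screened(0.6)
            best = 0
            for perm in ((0, 1), (1, 0)):
                ok = sum(int(labels[i] == perm[k])
                         for k, idx in screened.items() for i in idx)
                best = max(best, ok)
            accs.append(best / len(labels))
        assert min(accs) >= 0.98

    def test_membership_rows_sum_to_one(self):
        profiles, _ = simulate_trends(seed=7)
        fc = fuzzy_cmeans(standardize_profiles(profiles), c=3, seed=7)
        assert np.allclose(fc.memberships.sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def planted():
    x, labels = simulate_module_blocks(seed=21)
    ids = [f"m{i}" for i in range(len(labels))]
    return x, labels, ids, coexpression_modules(x, ids, min_module_size=30)


class TestModules:
    def test_planted_blocks_recovered(self, planted):
        x, labels, ids, result = planted
        assert set(result.labels) <= {1, 2}
        agree = 0
        for lab in (1, 2):
            members = labels[result.labels == lab]
            if len(members):
                agree += np.bincount(members).max()
        assert agree / len(labels) >= 0.95

    def test_module_sizes_respect_minimum(self, planted):
        _x, _labels, _ids, result = planted
        for lab in result.eigengenes:
            assert (result.labels == lab).sum() >= 30

    def test_identical_profiles_give_mm_one(self):
        rng = np.random.default_rng(5)
        profile = rng.normal(size=40)
        block = np.tile(profile, (35, 1))
        other = rng.normal(size=(35, 40))
        x = np.vstack([block, other])
        ids = [f"g{i}" for i in range(70)]
        result = coexpression_modules(x, ids, min_module_size=30)
        lab = result.labels[0]
        assert lab != 0
        mm = result.mm[:35][result.labels[:35] == lab]
        assert np.allclose(np.abs(mm), 1.0, atol=1e-8)

    def test_eigengene_is_leading_principal_component(self, planted):
        # the eigengene maximizes explained variance among all unit-norm
        # sample combinations: it must match the top eigenvector of z'z
        x, _labels, _ids, result = planted
        z = standardize_profiles(x)
        for lab, eg in result.eigengenes.items():
            members = z[result.labels == lab]
            w, v = np.linalg.eigh(members.T @ members)
            top = v[:, -1]
            cos = abs(np.dot(top, eg) / (np.linalg.norm(top) * np.linalg.norm(eg)))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_trait_correlation_and_hub_rule(self, planted):
        x, labels, ids, result = planted
        eg1 = result.eigengenes[1]
        traits = {"drive": eg1,
                  "noise": np.random.default_rng(8).normal(size=x.shape[1])}
        mt, genes = module_trait_and_hubs(result, x, traits)
        sub = mt[(mt.module == 1) & (mt.trait == "drive")]
        assert abs(sub.r.iloc[0]) > 0.99
        hubs = genes[genes.is_hub]
        assert (hubs.module == 1).all()
        assert (hubs.MM > 0.95).all() and (hubs.GS.abs() > 0.85).all()

    def test_no_hubs_when_trait_uncorrelated(self, planted):
        # high MM alone is not enough: with an uncorrelated trait GS stays
        # below threshold and nothing is a hub
        x, _labels, _ids, result = planted
        traits = {"noise": np.random.default_rng(9).normal(size=x.shape[1])}
        _mt, genes = module_trait_and_hubs(result, x, traits)
        assert (genes.MM > 0.95).any()
        assert not genes.is_hub.any()


class TestEnrichment:
    def test_exhaustive_overlap_probability(self):
        uni = {f"u{i}" for i in range(20)}
        sel = {f"u{i}" for i in range(5)}
        res = enrichment(sel, uni, {"T": set(sel)})
        assert res.p_value[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_selected_equals_universe_p_one(self):
        uni = {f"u{i}" for i in range(10)}
        res = enrichment(uni, uni, {"T": {f"u{i}" for i in range(4)}})
        assert res.p_value[0] == pytest.approx(1.0)

    def test_zero_overlap_near_one(self):
        uni = {f"u{i}" for i in range(100)}
        sel = {f"u{i}" for i in range(10)}
        res = enrichment(sel, uni, {"T": {f"u{i}" for i in range(90, 95)}})
        assert res.p_value[0] > 0.5

    def test_term_outside_universe_skipped(self):
        uni = {"a", "b"}
        res = enrichment({"a"}, uni, {"T": {"zz"}})
        assert len(res) == 0

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment({"x"}, {"a"}, {})
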