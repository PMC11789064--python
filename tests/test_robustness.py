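"""Inferential suite: Holm, Hedge's g, Mann-Whitney, bootstraps, cross-decoding."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectdecode.reliability import group_average
from affectdecode.robustness import (
    bootstrap_scores,
    cross_decode,
    cross_decode_matrix,
    decode_individual,
    hedges_g_paired,
    holm_adjust,
    mann_whitney,
    paired_ttest_holm,
)
from affectdecode.decoder import RidgeSpec
from affectdecode.scoring import pearson_accuracy
from affectdecode.synthetic import (
    FeatureSimConfig,
    RaterSimConfig,
    simulate_feature_bank,
    simulate_ratings,
)


class TestHolm:
    def test_hand_stepped_family_of_three(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=8))
    def test_monotone_and_never_below_raw(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPairedT:
    def test_identical_samples(self):
        x = np.arange(5.0)
        res = paired_ttest_holm({"c": (x, x.copy())}).table.iloc[0]
        assert res["hedges_g"] == 0.0
        assert res["p_holm"] == 1.0

    def test_constant_nonzero_shift_flagged(self):
        x = np.arange(5.0)
        res = paired_ttest_holm({"c": (x + 2.0, x)}).table.iloc[0]
        assert np.isnan(res["hedges_g"]) and np.isnan(res["p_raw"])

    def test_small_sample_correction_applied(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        y = x - 1.0 - 0.1 * rng.standard_normal(10)
        d = x - y
        expect = d.mean() / d.std(ddof=1) * (1 - 3 / (4 * 9 - 1))
        assert hedges_g_paired(x, y) == pytest.approx(expect)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest_holm({"c": (np.array([1.0, 2.0]), np.array([1.0, 2.0]))})

    def test_family_correction_across_cells(self):
        rng = np.random.default_rng(1)
        cells = {}
        for k in range(3):
            x = rng.standard_normal(12)
            cells[f"c{k}"] = (x + 1.0 + 0.5 * rng.standard_normal(12), x)
        table = paired_ttest_holm(cells).table
        assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()


class TestMannWhitney:
    def test_identical_multisets_not_significant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = mann_whitney(x, x.copy()).table.iloc[0]
        assert res["p"] > 0.5

    def test_full_separation_extreme_statistic(self):
        res = mann_whitney(np.array([10.0, 11, 12]), np.array([1.0, 2, 3])).table.iloc[0]
        assert res["W"] == 9.0  # n_x * n_y

    def test_four_vs_four_matches_brute_force_enumeration(self):
        x = np.array([1.3, 2.7, 3.1, 5.2])
        y = np.array([0.9, 2.1, 4.4, 4.8])
        res = mann_whitney(x, y).table.iloc[0]
        # U statistic by definition: number of (x, y) pairs with x > y (+0.5 ties)
        u_direct = sum(1.0 for a in x for b in y if a > b)
        assert res["W"] == u_direct
        # exact two-sided p by enumerating all 8!/(4!4!) group assignments
        pooled = np.concatenate([x, y])
        us = []
        for comb in itertools.combinations(range(8), 4):
            xs = pooled[list(comb)]
            ys = pooled[[i for i in range(8) if i not in comb]]
            us.append(sum(1.0 for a in xs for b in ys if a > b))
        us = np.array(us)
        dev = abs(u_direct - 8.0)  # center = n_x n_y / 2
        p_exact = np.mean(np.abs(us - 8.0) >= dev - 1e-12)
        assert res["p"] == pytest.approx(p_exact)


@pytest.fixture(scope="module")
def decode_setup():
    table, truth = simulate_ratings(RaterSimConfig(n_images=150, n_raters=12, seed=21))
    cfg = FeatureSimConfig(n_layers=2, dims_per_layer=(48, 48), decodable_fraction=0.75, seed=3)
    bank = simulate_feature_bank(cfg, truth)
    return table, truth, bank


class TestBootstrapScores:
    def test_self_comparison_null(self, decode_setup):
        table, _, bank = decode_setup
        res = bootstrap_scores({"a": bank, "b": bank}, table, B=120, seed=0)
        d = res.deltas[("a", "b")]
        np.testing.assert_allclose(d, 0.0)
        assert res.p_holm[("a", "b")] == 1.0

    def test_rank_counts_sum_to_B(self, decode_setup):
        table, truth, bank = decode_setup
        weak = simulate_feature_bank(
            FeatureSimConfig(n_layers=2, dims_per_layer=(48, 48), depth_profile="zero", seed=9),
            truth.__class__(**{**truth.__dict__}),
        )
        res = bootstrap_scores({"strong": bank, "weak": weak}, table, B=150, seed=1)
        assert (res.rank_counts.sum(axis=0) == 150).all()

    def test_dominant_model_ranked_first_everywhere(self, decode_setup):
        table, truth, bank = decode_setup
        import copy

        weak = simulate_feature_bank(
            FeatureSimConfig(n_layers=2, dims_per_layer=(48, 48), depth_profile="zero", seed=9),
            copy.copy(truth),
        )
        res = bootstrap_scores({"strong": bank, "weak": weak}, table, B=150, seed=2)
        assert res.rank_counts.loc["strong", "rank_1"] == 150
        assert res.p_holm[("strong", "weak")] < 0.05

    def test_refit_mode_agrees_with_rescore_direction(self, decode_setup):
        table, truth, bank = decode_setup
        import copy

        weak = simulate_feature_bank(
            FeatureSimConfig(n_layers=2, dims_per_layer=(48, 48), depth_profile="zero", seed=9),
            copy.copy(truth),
        )
        res = bootstrap_scores({"strong": bank, "weak": weak}, table, B=100, seed=3, mode="refit")
        assert res.deltas[("strong", "weak")].mean() > 0


class TestDecodeIndividual:
    def test_group_mean_respondent_reproduces_group_accuracy(self, decode_setup):
        table, truth, bank = decode_setup
        grp = group_average(table)
        # append a synthetic respondent whose ratings equal the group mean
        clone = pd.DataFrame(
            {
                "respondent_id": "clone",
                "image_id": grp.image_ids,
                "rating": grp.mean,
                "affect": "beauty",
                "image_category": "all",
                "dataset_id": table["dataset_id"].iloc[0],
            }
        )
        aug = pd.concat([table, clone], ignore_index=True)
        feats = bank.deepest().array
        res = decode_individual(feats, bank.image_ids, aug, RidgeSpec(lam=1e3), min_images=20)
        # group-level accuracy on the same features/targets, same LOO pipeline
        from affectdecode.decoder import ridge_loo, standardize

        grp_aug = group_average(aug)
        Pz, yz, params = standardize(feats, grp_aug.mean)
        r_group = pearson_accuracy(grp_aug.mean, params.inverse_y(ridge_loo(Pz, yz, 1e3)))
        # the clone's target differs from the augmented group mean only
        # through its own 1/(m+1) contribution
        assert res.r_individual["clone"] == pytest.approx(r_group, abs=0.02)

    def test_below_floor_respondents_skipped(self, decode_setup):
        table, _, bank = decode_setup
        res = decode_individual(
            bank.deepest().array, bank.image_ids, table, min_images=10_000
        )
        assert len(res.r_individual) == 0
        assert len(res.skipped) == table["respondent_id"].nunique()

    def test_taste_typicality_predicts_decodability(self):
        # graded idiosyncratic variance across two simulated pools: the pool
        # with more divergent raters must show lower individual decodability
        rs = {}
        for name, vi in [("typical", 0.5), ("divergent", 6.0)]:
            table, truth = simulate_ratings(
                RaterSimConfig(n_images=150, n_raters=10, var_idio=vi, seed=31)
            )
            bank = simulate_feature_bank(
                FeatureSimConfig(n_layers=2, dims_per_layer=(48, 48), decodable_fraction=0.9, seed=4),
                truth,
            )
            res = decode_individual(bank.deepest().array, bank.image_ids, table, min_images=20)
            rs[name] = res.r_individual.mean()
        assert rs["typical"] > rs["divergent"] + 0.1


class TestCrossDecode:
    def test_diagonal_equals_within_set_loo(self, decode_setup):
        table, _, bank = decode_setup
        grp = group_average(table)
        feats = bank.deepest().array
        idx = np.arange(len(grp.mean))
        from affectdecode.decoder import ridge_loo, standardize

        Pz, yz, params = standardize(feats, grp.mean)
        expect = pearson_accuracy(grp.mean, params.inverse_y(ridge_loo(Pz, yz, 1e4)))
        assert cross_decode(feats, grp.mean, idx, idx) == pytest.approx(expect)

    def test_partial_overlap_rejected(self, decode_setup):
        table, _, bank = decode_setup
        grp = group_average(table)
        feats = bank.deepest().array
        with pytest.raises(ValueError, match="disjoint"):
            cross_decode(feats, grp.mean, np.arange(0, 60), np.arange(50, 100))

    def test_matrix_diagonal_contract(self, decode_setup):
        table, _, bank = decode_setup
        grp = group_average(table)
        feats = bank.deepest().array
        n = len(grp.mean)
        labels = np.array(["g1"] * (n // 2) + ["g2"] * (n - n // 2))
        mat = cross_decode_matrix(feats, grp.mean, labels).accuracy
        for g, rows in [("g1", np.arange(n // 2)), ("g2", np.arange(n // 2, n))]:
            assert mat.loc[g, g] == pytest.approx(
                cross_decode(feats, grp.mean, rows, rows)
            )

    def test_identical_train_and_test_sets_use_loo_not_plugin(self, decode_setup):
        # guards against optimistic resubstitution on the diagonal
        table, _, bank = decode_setup
        grp = group_average(table)
        feats = bank.deepest().array
        idx = np.arange(len(grp.mean))
        r_diag = cross_decode(feats, grp.mean, idx, idx, RidgeSpec(lam=1.0))
        from affectdecode.decoder import ridge_fit, standardize

        Pz, yz, params = standardize(feats, grp.mean)
        r_plugin = pearson_accuracy(grp.mean, params.inverse_y(Pz @ ridge_fit(Pz, yz, 1.0)))
        assert r_diag < r_plugin
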