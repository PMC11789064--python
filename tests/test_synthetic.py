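"""Generator contracts: variance structure, coverage design, signal recovery."""

import numpy as np
import pytest

from affectdecode.decoder import RidgeSpec, decode_bank
from affectdecode.reliability import group_average, mm1, split_half
from affectdecode.scoring import pearson_accuracy
from affectdecode.synthetic import (
    FeatureSimConfig,
    RaterSimConfig,
    make_paired_banks,
    simulate_feature_bank,
    simulate_ratings,
    simulate_two_datasets,
)


class TestSimulateRatings:
    def test_noise_free_raters_are_identical(self):
        table, _ = simulate_ratings(
            RaterSimConfig(n_images=30, n_raters=5, var_idio=0.0, var_noise=0.0, seed=0)
        )
        r = mm1(table)
        np.testing.assert_allclose(r.to_numpy(), 1.0)

    def test_fixed_per_rater_viewing_quota(self):
        table, _ = simulate_ratings(
            RaterSimConfig(n_images=900, n_raters=100, coverage=0.25, seed=1)
        )
        counts = table.groupby("respondent_id")["image_id"].count()
        assert (counts == 225).all()

    def test_under_covered_image_rejected_by_name(self):
        with pytest.raises(ValueError, match="img"):
            simulate_ratings(RaterSimConfig(n_images=50, n_raters=2, coverage=0.1, seed=0))

    def test_ratings_within_scale(self, small_sim):
        table, _ = small_sim
        assert table["rating"].between(0.0, 7.0).all()

    def test_discretize_yields_integers(self):
        table, _ = simulate_ratings(RaterSimConfig(n_images=30, n_raters=6, discretize=True, seed=2))
        assert np.allclose(table["rating"], np.rint(table["rating"]))

    def test_group_mean_variance_matches_components(self):
        # var of per-image group means -> s + (v_i+v_e)/m on the latent scale
        cfg = RaterSimConfig(n_images=2000, n_raters=20, seed=3)
        table, truth = simulate_ratings(cfg)
        grp = group_average(table)
        var_raw = grp.mean.var() / truth.affine_scale**2
        expect = cfg.var_shared + (cfg.var_idio + cfg.var_noise) / cfg.n_raters
        assert var_raw == pytest.approx(expect, rel=0.1)

    def test_discretization_never_increases_reliability(self):
        cont, _ = simulate_ratings(RaterSimConfig(n_images=200, n_raters=10, seed=4))
        disc, _ = simulate_ratings(
            RaterSimConfig(n_images=200, n_raters=10, seed=4, discretize=True)
        )
        r_c = split_half(cont, n_splits=300, seed=0).mean
        r_d = split_half(disc, n_splits=300, seed=0).mean
        assert r_d <= r_c + 0.01

    def test_analytic_reliability_recovered(self):
        cfg = RaterSimConfig(n_images=400, n_raters=20, seed=5)
        table, truth = simulate_ratings(cfg)
        res = split_half(table, n_splits=500, seed=1)
        assert res.mean == pytest.approx(truth.expected_rsplit, abs=0.04)


class TestSimulateFeatureBank:
    def test_shapes_and_depths(self, small_sim, small_feature_cfg):
        _, truth = small_sim
        bank = simulate_feature_bank(small_feature_cfg, truth)
        assert bank.n_layers == 4
        assert bank.depths.tolist() == [0.0, 1 / 3, 2 / 3, 1.0]
        assert all(l.width == 48 for l in bank.layers)

    def test_signal_free_profile_gives_null_decoding(self):
        table, truth = simulate_ratings(RaterSimConfig(n_images=300, n_raters=10, seed=6))
        cfg = FeatureSimConfig(n_layers=2, dims_per_layer=(48, 48), depth_profile="zero", seed=1)
        bank = simulate_feature_bank(cfg, truth)
        grp = group_average(table)
        preds = decode_bank(bank, grp.mean, grp.image_ids, RidgeSpec(lam=100.0))
        for p in preds:
            assert abs(pearson_accuracy(grp.mean, p.yhat)) < 0.15

    def test_perfect_signal_noise_free_is_exact(self):
        table, truth = simulate_ratings(
            RaterSimConfig(n_images=100, n_raters=5, var_idio=0.0, var_noise=0.0, seed=7)
        )
        cfg = FeatureSimConfig(
            n_layers=2, dims_per_layer=(24, 24), n_signal_dims=8,
            decodable_fraction=1.0, noise_scale=0.0, seed=2,
        )
        bank = simulate_feature_bank(cfg, truth)
        grp = group_average(table)
        preds = decode_bank(bank, grp.mean, grp.image_ids, RidgeSpec(lam=1.0))
        assert pearson_accuracy(grp.mean, preds[-1].yhat) > 0.999

    def test_designed_signal_correlation_is_exact(self, small_sim):
        _, truth = small_sim
        cfg = FeatureSimConfig(n_layers=3, dims_per_layer=(48,) * 3, decodable_fraction=0.6, seed=3)
        simulate_feature_bank(cfg, truth)
        z = (truth.latent - truth.latent.mean()) / truth.latent.std()
        q = 0.6 * truth.expected_rsplit
        assert np.corrcoef(truth.signal, z)[0, 1] == pytest.approx(np.sqrt(q), abs=1e-10)

    def test_monotone_profile_orders_layer_accuracy(self):
        table, truth = simulate_ratings(RaterSimConfig(n_images=400, n_raters=20, seed=8))
        cfg = FeatureSimConfig(n_layers=5, dims_per_layer=(48,) * 5, decodable_fraction=0.75, seed=4)
        bank = simulate_feature_bank(cfg, truth)
        grp = group_average(table)
        preds = decode_bank(bank, grp.mean, grp.image_ids)
        rs = [pearson_accuracy(grp.mean, p.yhat) for p in preds]
        assert rs[-1] == max(rs)
        assert rs[-1] > rs[0] + 0.2


class TestPairedBanks:
    def test_identical_shapes_and_depths(self, small_sim, small_feature_cfg):
        _, truth = small_sim
        trained, untrained = make_paired_banks(small_feature_cfg, truth)
        for a, b in zip(trained.layers, untrained.layers):
            assert a.array.shape == b.array.shape
            assert a.depth == b.depth

    def test_trained_beats_untrained(self, small_sim):
        table, truth = small_sim
        cfg = FeatureSimConfig(n_layers=3, dims_per_layer=(48,) * 3, decodable_fraction=0.75, seed=6)
        trained, untrained = make_paired_banks(cfg, truth)
        grp = group_average(table)
        r_t = max(
            pearson_accuracy(grp.mean, p.yhat)
            for p in decode_bank(trained, grp.mean, grp.image_ids)
        )
        r_u = max(
            pearson_accuracy(grp.mean, p.yhat)
            for p in decode_bank(untrained, grp.mean, grp.image_ids)
        )
        assert r_t > r_u + 0.2


class TestTwoDatasets:
    def test_category_structure(self):
        sim = simulate_two_datasets(True, seed=0)
        assert sim.shared_category == "landscape"
        for table, cats in zip(sim.tables, sim.categories):
            assert set(table["image_category"]) == set(cats)
        assert sim.tables[0]["dataset_id"].iloc[0] != sim.tables[1]["dataset_id"].iloc[0]

    def test_disjoint_flag_removes_shared_category(self):
        sim = simulate_two_datasets(False, seed=0)
        assert sim.shared_category is None
        assert not set(sim.categories[0]) & set(sim.categories[1])

    def test_banks_cover_their_tables(self):
        sim = simulate_two_datasets(True, seed=1)
        for table, bank in zip(sim.tables, sim.banks):
            assert sorted(set(table["image_id"])) == sorted(bank.image_ids)
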