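"""Neighbour selection and the three prediction strategies."""

import numpy as np
import pytest

from conftest import make_dataset
from localpls import approaches, evaluate, pca, pls, simulate


@pytest.fixture(scope="module")
def fixture_ds():
    return simulate.planted_neighbour_fixture(40, 100, 10.0, seed=7)


class TestChangepointSelection:
    def test_core_predictand_recovers_core(self, fixture_ds):
        cfg = approaches.ApproachConfig(approach="local_changepoint")
        sel = approaches.select_neighbours_changepoint(
            fixture_ds, fixture_ds.sample_ids[0], cfg
        )
        assert sel.rule == "changepoint"
        assert sel.n_neighbours == 39
        assert set(sel.neighbour_ids) == set(fixture_ds.sample_ids[1:40])

    def test_distances_sorted_ascending(self, fixture_ds):
        cfg = approaches.ApproachConfig(approach="local_changepoint")
        sel = approaches.select_neighbours_changepoint(
            fixture_ds, fixture_ds.sample_ids[3], cfg
        )
        assert np.all(np.diff(sel.distances_or_correlations) >= 0)

    def test_predictand_never_a_neighbour(self, fixture_ds):
        cfg = approaches.ApproachConfig(approach="local_changepoint")
        for sid in fixture_ds.sample_ids[:5]:
            sel = approaches.select_neighbours_changepoint(fixture_ds, sid, cfg)
            assert sid not in set(sel.neighbour_ids)

    def test_min_neighbour_rule_skips_early_changepoints(self, rng):
        """With a distance break at 5 and another at 30, the first
        admissible changepoint (>= 20 neighbours) must give 30 neighbours.

        Shells around the predictand keep the geometry isotropic, so the
        eigenvalue whitening rescales all latent directions alike and the
        engineered breaks survive in Mahalanobis units.
        """

        def shell(m, radius, jitter):
            u = rng.normal(size=(m, 4))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            return u * (radius + jitter * rng.normal(size=(m, 1)))

        latent = np.vstack(
            [
                np.zeros((1, 4)),
                shell(5, 0.01, 0.001),
                shell(25, 2.0, 0.01),
                shell(260, 10.0, 1.0),
            ]
        )
        profiles = rng.normal(size=(4, 30))
        ds = make_dataset(latent @ profiles + rng.normal(0, 1e-6, size=(291, 30)))
        cfg = approaches.ApproachConfig(approach="local_changepoint", min_neighbours=20)
        sel = approaches.select_neighbours_changepoint(ds, "S000", cfg)
        assert sel.changepoint_index_used == 30
        assert sel.n_neighbours == 30

    def test_fallback_to_all_when_no_admissible_changepoint(self, rng):
        """If every changepoint sits below the minimum neighbour count the
        selection falls back to every candidate (flat tail structure)."""
        ds = simulate.planted_neighbour_fixture(21, 30, 10.0, seed=1)
        # no admissible changepoint can exist at 49: the final segment needs
        # at least two observations, so every changepoint index is <= 48
        cfg = approaches.ApproachConfig(
            approach="local_changepoint", min_neighbours=49
        )
        sel = approaches.select_neighbours_changepoint(ds, ds.sample_ids[0], cfg)
        assert sel.rule == "all"
        assert sel.n_neighbours == 50

    def test_too_few_candidates_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(10, 6)))
        cfg = approaches.ApproachConfig(approach="local_changepoint", min_neighbours=20)
        with pytest.raises(ValueError):
            approaches.select_neighbours_changepoint(ds, "S000", cfg)


class TestShenkSelection:
    def test_identical_candidate_ranked_first(self, rng):
        X = rng.normal(size=(30, 20))
        X[7] = X[0]
        ds = make_dataset(X)
        cfg = approaches.ApproachConfig(approach="local_shenk", shenk_k=5)
        sel = approaches.select_neighbours_shenk(ds, "S000", cfg)
        assert sel.neighbour_ids[0] == "S007"
        assert sel.distances_or_correlations[0] == pytest.approx(1.0)

    def test_affine_transform_has_unit_correlation(self, rng):
        X = rng.normal(size=(25, 15))
        X[3] = 2.5 * X[0] + 7.0
        ds = make_dataset(X)
        cfg = approaches.ApproachConfig(approach="local_shenk", shenk_k=3)
        sel = approaches.select_neighbours_shenk(ds, "S000", cfg)
        assert sel.neighbour_ids[0] == "S003"
        assert sel.distances_or_correlations[0] == pytest.approx(1.0)

    def test_matches_bruteforce_ranking(self, rng):
        X = rng.normal(size=(31, 12))
        ds = make_dataset(X)
        cfg = approaches.ApproachConfig(approach="local_shenk", shenk_k=5)
        sel = approaches.select_neighbours_shenk(ds, "S004", cfg)
        brute = []
        for i in range(31):
            if i == 4:
                continue
            brute.append((-np.corrcoef(X[4], X[i])[0, 1], i))
        expected = [f"S{i:03d}" for _, i in sorted(brute)[:5]]
        assert list(sel.neighbour_ids) == expected

    def test_zero_variance_candidate_excluded(self, rng):
        X = rng.normal(size=(28, 10))
        X[5] = 4.0
        ds = make_dataset(X)
        cfg = approaches.ApproachConfig(approach="local_shenk", shenk_k=26)
        sel = approaches.select_neighbours_shenk(ds, "S000", cfg)
        assert "S005" not in set(sel.neighbour_ids)


class TestPredictions:
    def test_noiseless_linear_trait_predicted_exactly(self):
        cfg = simulate.SyntheticConfig(
            seed=11,
            n_samples=60,
            n_wavelengths=30,
            trait_noise_sd={t: 0.0 for t in simulate.TRAIT_MOMENTS},
            spectral_noise_sd=0.0,
            baseline_sd=0.0,
        )
        ds = simulate.generate(cfg)
        acfg = approaches.ApproachConfig(approach="global", max_factors=10)
        details = approaches.predict_all(ds, "ph", acfg)
        y = ds.traits["ph"].to_numpy(float)
        yhat = np.array([d.value for d in details])
        assert np.max(np.abs(yhat - y)) < 1e-6 * y.std()

    def test_fast_global_path_equals_single_route(self, rng):
        ds = make_dataset(rng.normal(size=(18, 8)))
        ds.traits["y"] += rng.normal(size=18)
        acfg = approaches.ApproachConfig(approach="global", max_factors=5)
        details = approaches.predict_all(ds, "y", acfg)
        for d in details[:6]:
            single = approaches.predict_one(ds, d.predictand_id, "y", acfg)
            assert single == pytest.approx(d.value, abs=1e-8)

    def test_shenk_smoke_contract(self):
        ds = simulate.generate(
            simulate.SyntheticConfig(seed=2, n_samples=100, n_wavelengths=40)
        )
        acfg = approaches.ApproachConfig(
            approach="local_shenk", shenk_k=25, shenk_factors=5
        )
        details = approaches.predict_all(ds, "ph", acfg)
        values = np.array([d.value for d in details])
        assert np.all(np.isfinite(values))
        assert all(d.n_factors == 5 for d in details)

    def test_local_changepoint_counts_vary_on_heterogeneous_data(self):
        ds = simulate.generate(simulate.heterogeneous_config(seed=0, n_samples=150))
        acfg = approaches.ApproachConfig(approach="local_changepoint")
        sels = approaches._all_selections(ds, acfg)
        counts = {s.n_neighbours for s in sels}
        assert len(counts) > 1  # data-driven, not a fixed k

    def test_cluster_structure_helps_locality(self):
        """On two-cluster data with cluster-specific trait slopes, the
        changepoint neighbours are predominantly same-cluster and the local
        fit beats the (mis-specified) pooled calibration."""
        ds = simulate.generate(simulate.heterogeneous_config(seed=3, separation=8.0))
        y = ds.traits["rct"].to_numpy(float)
        acfg = approaches.ApproachConfig(approach="local_changepoint")
        sels = approaches._all_selections(ds, acfg)
        cluster = {s: c for s, c in zip(ds.sample_ids, ds.meta["cluster"])}
        same = total = 0
        for sel in sels:
            own = cluster[sel.predictand_id]
            matches = sum(1 for nb in sel.neighbour_ids if cluster[nb] == own)
            assert matches > sel.n_neighbours / 2  # majority same-cluster
            same += matches
            total += sel.n_neighbours
        assert same / total >= 0.95
        details = approaches.predict_all(ds, "rct", acfg, selections=sels)
        local = evaluate.rmsev(y, np.array([d.value for d in details]))
        yhat_g, _ = pls.loo_global_benchmark(ds.spectra, y, 20)
        assert local < evaluate.rmsev(y, yhat_g[:, 0])

    def test_no_leakage_across_all_approaches(self):
        ds = simulate.generate(
            simulate.SyntheticConfig(seed=9, n_samples=60, n_wavelengths=30)
        )
        for acfg in [
            approaches.ApproachConfig(approach="global", max_factors=8),
            approaches.ApproachConfig(approach="local_shenk", shenk_k=25, shenk_factors=5),
            approaches.ApproachConfig(approach="local_changepoint"),
        ]:
            details = approaches.predict_all(ds, "k20", acfg)
            assert evaluate.leakage_audit(details)

    def test_tiny_neighbour_set_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(30, 8)))
        with pytest.raises(ValueError):
            approaches._fit_and_predict(
                ds, "y", np.array([1, 2]), 0, approaches.ApproachConfig(), None
            )


class TestEdgeBehaviour:
    def test_outlying_predictands_get_fewer_neighbours(self):
        ds = simulate.planted_neighbour_fixture(40, 260, 10.0, seed=123)
        cfg = approaches.ApproachConfig(approach="local_changepoint")
        space = pca.fit_pc_space(ds.spectra, standardise=True, n_components=4)
        scores = pca.project(space, ds.spectra)
        d = pca.center_distances(space, scores)
        sels = [
            approaches.select_neighbours_changepoint(
                ds, sid, cfg, space=space, scores=scores
            )
            for sid in ds.sample_ids
        ]
        counts = np.array([s.n_neighbours for s in sels])
        k = 15  # 5% of 300
        edge = counts[np.argsort(-d)[:k]].mean()
        centre = counts[np.argsort(d)[:k]].mean()
        assert edge < centre
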