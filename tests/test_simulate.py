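"""Synthetic generator: determinism, structure and ground-truth knobs."""

import numpy as np
import pytest

from localpls import approaches, io, pca, simulate


class TestGenerate:
    def test_same_seed_identical_datasets(self):
        cfg = simulate.SyntheticConfig(seed=4, n_samples=40, n_wavelengths=25)
        a = simulate.generate(cfg)
        b = simulate.generate(cfg)
        assert np.array_equal(a.spectra, b.spectra)
        assert a.traits.equals(b.traits)
        assert list(a.sample_ids) == list(b.sample_ids)

    def test_different_seeds_differ(self):
        a = simulate.generate(simulate.SyntheticConfig(seed=1, n_samples=20, n_wavelengths=15))
        b = simulate.generate(simulate.SyntheticConfig(seed=2, n_samples=20, n_wavelengths=15))
        assert not np.array_equal(a.spectra, b.spectra)

    def test_trait_moments_match_targets(self):
        ds = simulate.generate(simulate.SyntheticConfig(seed=8, n_samples=300, n_wavelengths=30))
        for name, (mean, sd) in simulate.TRAIT_MOMENTS.items():
            v = ds.traits[name].to_numpy(float)
            assert v.mean() == pytest.approx(mean, abs=1e-9)
            assert v.std() == pytest.approx(sd, rel=1e-9)

    def test_two_separated_clusters_are_linearly_separable(self):
        cfg = simulate.SyntheticConfig(
            seed=13, n_samples=200, n_wavelengths=40, n_clusters=2, cluster_separation=10.0
        )
        ds = simulate.generate(cfg)
        space = pca.fit_pc_space(ds.spectra, standardise=False, n_components=2)
        s = pca.project(space, ds.spectra)
        c = ds.meta["cluster"]
        centroid_gap = np.linalg.norm(s[c == 0].mean(0) - s[c == 1].mean(0))
        within = max(
            np.linalg.norm(s[c == 0] - s[c == 0].mean(0), axis=1).mean(),
            np.linalg.norm(s[c == 1] - s[c == 1].mean(0), axis=1).mean(),
        )
        assert centroid_gap / within > 5

    def test_low_rank_before_noise(self):
        """Spectral rank is components + baseline terms; a singular-value
        gap separates structure from the noise floor."""
        cfg = simulate.SyntheticConfig(
            seed=6, n_samples=80, n_wavelengths=60, spectral_noise_sd=1e-6
        )
        ds = simulate.generate(cfg)
        s = np.linalg.svd(ds.spectra - ds.spectra.mean(0), compute_uv=False)
        structure = cfg.n_components + 3  # baseline is quadratic in wavelength
        assert s[structure - 1] / s[structure] > 10

    def test_outlier_injection_count(self):
        cfg = simulate.SyntheticConfig(
            seed=3, n_samples=200, n_wavelengths=20, outlier_fraction=0.04
        )
        ds = simulate.generate(cfg)
        assert len(ds.meta["outlier_cells"]) == 8

    def test_duplicate_injection(self):
        cfg = simulate.SyntheticConfig(
            seed=3, n_samples=100, n_wavelengths=20, duplicate_animal_fraction=0.1
        )
        ds = simulate.generate(cfg)
        assert ds.n_samples == 110
        animals, counts = np.unique(ds.animal_ids.astype(str), return_counts=True)
        assert (counts == 2).sum() == 10

    def test_injected_outliers_are_exactly_the_3sd_exceedances(self):
        """The >3 SD rule must identify precisely the injected cells."""
        cfg = simulate.SyntheticConfig(
            seed=17, n_samples=250, n_wavelengths=20, outlier_fraction=0.03
        )
        ds = simulate.generate(cfg)
        injected = {(s, t) for s, t in ds.meta["outlier_cells"]}
        flagged = set()
        for t in ds.trait_names:
            v = ds.traits[t].to_numpy(float)
            z = np.abs(v - v.mean()) / v.std(ddof=1)
            for sid in ds.sample_ids[z > 3]:
                flagged.add((sid, t))
        assert flagged == injected


class TestPlantedFixture:
    def test_core_is_tight_and_separated(self):
        ds = simulate.planted_neighbour_fixture(40, 100, 10.0, seed=2)
        latent = ds.meta["latent"]
        core = latent[ds.meta["is_core"]]
        bg = latent[~ds.meta["is_core"]]
        assert np.linalg.norm(core, axis=1).max() < 0.1
        assert np.linalg.norm(bg, axis=1).min() > 4.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            simulate.planted_neighbour_fixture(40, 100, 0.0, seed=0)
        with pytest.raises(ValueError, match="21"):
            simulate.planted_neighbour_fixture(10, 100, 5.0, seed=0)

    def test_minimum_rule_binds_at_smallest_core(self):
        """With a 21-sample core the selection can never drop below 20."""
        cfg = approaches.ApproachConfig(approach="local_changepoint")
        for seed in range(5):
            ds = simulate.planted_neighbour_fixture(21, 60, 10.0, seed=seed)
            sel = approaches.select_neighbours_changepoint(ds, ds.sample_ids[0], cfg)
            assert sel.n_neighbours >= 20


class TestEditingGroundTruth:
    def test_pipeline_removes_exactly_the_injections(self):
        """De-duplication keeps the PC-farther record per animal and outlier
        filtering drops exactly the injected samples."""
        cfg = simulate.SyntheticConfig(
            seed=31,
            n_samples=150,
            n_wavelengths=40,
            duplicate_animal_fraction=0.08,
            outlier_fraction=0.03,
        )
        ds = simulate.generate(cfg)
        pcfg = io.PreprocessConfig(discard_windows=[])
        edited, _ = io.edit_pipeline(ds, pcfg)
        # outlier ground truth
        outlier_samples = {s for s, _ in ds.meta["outlier_cells"]}
        assert outlier_samples & set(edited.sample_ids) == set()
        # dedup ground truth: recompute distances directly
        space = pca.fit_pc_space(ds.spectra, standardise=True, n_components=4)
        d = pca.center_distances(space, pca.project(space, ds.spectra))
        pos = {s: i for i, s in enumerate(ds.sample_ids)}
        for new, old in ds.meta["duplicate_of"].items():
            keep = new if d[pos[new]] > d[pos[old]] else old
            drop = old if keep == new else new
            assert drop not in set(edited.sample_ids)
            # the kept record survives unless it was itself an outlier
            if keep not in outlier_samples:
                assert keep in set(edited.sample_ids)
        # nothing else was removed
        expected_removed = set(outlier_samples)
        for new, old in ds.meta["duplicate_of"].items():
            expected_removed.add(new if d[pos[new]] <= d[pos[old]] else old)
        assert set(ds.sample_ids) - set(edited.sample_ids) == expected_removed
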