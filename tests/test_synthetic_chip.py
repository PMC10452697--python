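import math

import numpy as np
import pytest

from chipdpcr import (
    DEFAULT_LAYOUT, DEFAULT_PANEL, SimulationConfig, simulate_partition,
    render_images, simulate_mixture_series, stock_to_chamber,
)
from chipdpcr.synthetic_chip import (
    ChannelIntensityModel, DEFAULT_DILUTION_FACTOR, write_chip_outputs,
)


class TestStockDilution:
    def test_default_mix_ratio(self):
        # 3.5 uL template in a ~31.7 uL reaction
        assert DEFAULT_DILUTION_FACTOR == pytest.approx(3.5 / 31.7)
        assert stock_to_chamber(2e4) == pytest.approx(2208.2, abs=0.1)

    def test_rejects_negative_stock(self):
        with pytest.raises(ValueError):
            stock_to_chamber(-1.0)


class TestSimulatePartition:
    def test_zero_concentration_all_negative(self, small_layout):
        cfg = SimulationConfig(species_concentrations={"WT": 0.0},
                               seed=5, layout=small_layout)
        truth = simulate_partition(cfg)
        assert truth.counts.sum() == 0
        for ch in cfg.panel.channels:
            assert truth.positivity[ch].sum() == 0

    def test_rejects_negative_concentration(self, small_layout):
        with pytest.raises(ValueError):
            SimulationConfig(species_concentrations={"WT": -1.0},
                             seed=5, layout=small_layout)

    def test_positive_fraction_matches_poisson_occupancy(self, small_layout):
        """Over >=100 seeds the observed positive fraction stays within 3
        binomial standard errors of 1 - exp(-lambda)."""
        conc = 976.2  # in-chamber copies/uL; lambda = C * Vd ~ ln 2
        lam = conc * small_layout.chamber_volume_ul
        expected = 1.0 - math.exp(-lam)
        n_seeds, n = 120, small_layout.total_chambers
        positives = 0
        for seed in range(n_seeds):
            cfg = SimulationConfig(species_concentrations={"WT": conc},
                                   seed=seed, layout=small_layout)
            positives += simulate_partition(cfg).positives("Cy5")
        total = n_seeds * n
        se = math.sqrt(expected * (1 - expected) / total)
        assert abs(positives / total - expected) < 3 * se

    def test_half_occupancy_concentration(self):
        """In-chamber 976.2 copies/uL at Vd = 7.1e-4 uL gives lambda ~ ln 2,
        i.e. ~50% positive chambers on the full device."""
        cfg = SimulationConfig(species_concentrations={"WT": 976.2}, seed=2)
        truth = simulate_partition(cfg)
        frac = truth.positives("Cy5") / truth.n_chambers
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_mutant_positives_subset_of_reference(self, small_layout):
        cfg = SimulationConfig(
            species_concentrations={"WT": 500.0, "G12D": 500.0},
            seed=7, layout=small_layout)
        truth = simulate_partition(cfg)
        ref = truth.positivity["Cy5"]
        mut = truth.positivity["HEX"]
        assert not np.any(mut & ~ref)

    def test_detection_efficiency_thins_positives(self, small_layout):
        base = dict(species_concentrations={"WT": 2000.0}, layout=small_layout)
        full = simulate_partition(SimulationConfig(seed=9, **base))
        half = simulate_partition(SimulationConfig(
            seed=9, detection_efficiency=0.3, **base))
        assert half.positives("Cy5") < full.positives("Cy5")
        assert np.all(half.detected <= half.counts)

    def test_unfilled_chambers_have_no_positivity(self, small_layout):
        cfg = SimulationConfig(species_concentrations={"WT": 5000.0},
                               seed=13, layout=small_layout,
                               unfilled_fraction=0.3)
        truth = simulate_partition(cfg)
        assert 0 < truth.filled.sum() < truth.n_chambers
        for ch in cfg.panel.channels:
            assert not np.any(truth.positivity[ch] & ~truth.filled)

    def test_same_seed_reproduces(self, small_layout):
        mk = lambda: simulate_partition(SimulationConfig(
            species_concentrations={"WT": 800.0, "G12D": 80.0},
            seed=21, layout=small_layout))
        a, b = mk(), mk()
        assert np.array_equal(a.counts, b.counts)
        assert all(np.array_equal(a.positivity[c], b.positivity[c])
                   for c in a.panel.channels)


class TestRenderImages:
    def test_noise_free_disks_read_exact_model_means(self, noise_free_config):
        truth = simulate_partition(noise_free_config)
        images, centres = render_images(truth, noise_free_config)
        img = images["Cy5"]
        model = noise_free_config.intensity_models["Cy5"]
        r = int(noise_free_config.layout.chamber_diameter / 2
                / noise_free_config.pixel_scale) - 1
        for _, row in centres.sample(20, random_state=0).iterrows():
            y, x = int(row.y_px), int(row.x_px)
            patch = img[y - r:y + r, x - r:x + r]
            want = (model.mu_pos if truth.positivity["Cy5"][int(row.chamber_id)]
                    else model.mu_neg)
            assert patch.max() == patch.min() == want

    def test_single_positive_chamber(self, small_layout, panel,
                                     noise_free_models):
        cfg = SimulationConfig(species_concentrations={"WT": 0.0}, seed=1,
                               layout=small_layout, panel=panel,
                               intensity_models=noise_free_models,
                               background_noise_sd=0.0)
        truth = simulate_partition(cfg)
        truth.positivity["Cy5"][42] = True  # plant exactly one positive
        images, centres = render_images(truth, cfg)
        img = images["Cy5"].astype(float)
        model = cfg.intensity_models["Cy5"]
        assert (img == model.mu_pos).sum() > 0
        y, x = centres.loc[42, ["y_px", "x_px"]]
        assert img[int(y), int(x)] == model.mu_pos
        # every other chamber centre reads mu_neg
        others = centres.drop(42)
        vals = img[others.y_px.astype(int), others.x_px.astype(int)]
        assert np.all(vals == model.mu_neg)

    def test_bimodal_intensity_modes(self, small_layout):
        cfg = SimulationConfig(species_concentrations={"WT": 976.0},
                               seed=3, layout=small_layout)
        truth = simulate_partition(cfg)
        images, centres = render_images(truth, cfg)
        img = images["Cy5"].astype(float)
        vals = img[centres.y_px.astype(int), centres.x_px.astype(int)]
        pos = truth.positivity["Cy5"]
        model = cfg.intensity_models["Cy5"]
        assert vals[pos].mean() - vals[~pos].mean() == pytest.approx(
            model.mu_pos - model.mu_neg, rel=0.05)

    def test_image_dimension_cap(self, small_layout):
        cfg = SimulationConfig(species_concentrations={"WT": 10.0}, seed=1,
                               layout=small_layout, pixel_scale=0.05,
                               max_image_dim=2000)
        truth = simulate_partition(cfg)
        with pytest.raises(ValueError, match="cap"):
            render_images(truth, cfg)

    def test_rain_produces_intermediate_intensities(self, small_layout, panel):
        models = {ch: ChannelIntensityModel(sigma_neg=0, sigma_pos=0,
                                            rain_fraction=0.5)
                  for ch in panel.channels}
        cfg = SimulationConfig(species_concentrations={"WT": 3000.0}, seed=4,
                               layout=small_layout, panel=panel,
                               intensity_models=models, background_noise_sd=0)
        truth = simulate_partition(cfg)
        images, centres = render_images(truth, cfg)
        vals = images["Cy5"].astype(float)[
            centres.y_px.astype(int), centres.x_px.astype(int)]
        pos_vals = vals[truth.positivity["Cy5"]]
        m = cfg.intensity_models["Cy5"]
        assert np.any((pos_vals > m.mu_neg + 1) & (pos_vals < m.mu_pos - 1))


class TestMixtureSeries:
    def test_all_mutant_matches_reference(self, small_layout):
        runs = simulate_mixture_series([1.0], 2e4, reps=5, seed=8,
                                       layout=small_layout)
        for truth, _ in runs[0]:
            assert truth.positives("HEX") == truth.positives("Cy5")

    def test_zero_fraction_never_fires_mutation_channel(self, small_layout):
        runs = simulate_mixture_series([0.0], 2e4, reps=5, seed=8,
                                       layout=small_layout)
        for truth, _ in runs[0]:
            assert truth.positives("HEX") == 0
            assert truth.positives("Cy5") > 0

    def test_low_fraction_expected_mutant_positives(self):
        """f = 0.2% of stock 2e4 copies/uL loads ~67 mutant-positive
        chambers on the full 21,384-chamber device."""
        lam_total = stock_to_chamber(2e4) * DEFAULT_LAYOUT.chamber_volume_ul
        expected = 21384 * (1 - math.exp(-0.002 * lam_total))
        runs = simulate_mixture_series([0.002], 2e4, reps=30, seed=17)
        counts = [t.positives("HEX") for t, _ in runs[0]]
        se = math.sqrt(expected / 30)  # Poisson SE of the mean
        assert np.mean(counts) == pytest.approx(expected, abs=4 * se)
        assert expected == pytest.approx(67, abs=3)

    def test_rejects_fraction_outside_unit_interval(self):
        with pytest.raises(ValueError):
            simulate_mixture_series([1.5], 2e4, reps=1, seed=1)

    def test_render_flag_returns_images(self, small_layout):
        runs = simulate_mixture_series([0.5], 1e4, reps=1, seed=2,
                                       layout=small_layout, render=True)
        truth, images = runs[0][0]
        assert set(images) == set(truth.panel.channels)
        assert images["Cy5"].dtype == np.uint16


class TestOutputs:
    def test_written_files_and_seed_echo(self, tmp_path, noise_free_config):
        truth = simulate_partition(noise_free_config)
        images, _ = render_images(truth, noise_free_config)
        paths = write_chip_outputs(tmp_path, "chipA", truth, images,
                                   noise_free_config)
        import yaml
        assert (tmp_path / "chipA_Cy5.tif").exists()
        assert (tmp_path / "chipA_truth.csv").exists()
        echoed = yaml.safe_load((tmp_path / "chipA_config.yaml").read_text())
        assert echoed["seed"] == noise_free_config.seed
        assert len(paths) == len(images) + 2
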