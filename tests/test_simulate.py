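"""Generator: population model, calibration, spatial modes, rendering."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from trimscope.config import DegKinetics, GradientConfig, NoiseConfig, SimConfig
from trimscope.presets import PERM_FRACTION_HEK, build_preset
from trimscope.simulate import (
    apply_spatial_mode,
    calibrate_knockdown,
    calibrate_permeabilization,
    expected_bulk_knockdown,
    remaining_target_fraction,
    render_labels,
    render_rounds,
    sample_population,
)

BIG_FIELD = dict(field_shape=(3072, 3072))  # room for analytic-size populations


class TestSamplePopulation:
    def test_zero_dose_boundary(self):
        gt = sample_population(SimConfig(n_cells=200, slo_dose=0.0, seed=1))
        assert not gt["permeabilized"].any()
        assert (gt["A"] == 0).all()

    def test_no_degradation_limit(self):
        cfg = SimConfig(
            n_cells=300, deg_kinetics=DegKinetics(k_max=0.0), condition="targeting", seed=2
        )
        gt = sample_population(cfg)
        assert np.array_equal(gt["X"].to_numpy(), gt["X0"].to_numpy())

    def test_latent_invariants(self):
        gt = sample_population(SimConfig(n_cells=500, seed=3, **BIG_FIELD))
        assert (gt["X"] <= gt["X0"] + 1e-12).all()
        assert (gt.loc[gt["A"] > 0, "permeabilized"]).all()
        assert (gt.loc[~gt["permeabilized"], "A"] == 0).all()
        # NC condition leaves the target untouched
        nc = sample_population(SimConfig(n_cells=500, condition="NC", seed=3, **BIG_FIELD))
        assert np.array_equal(nc["X"].to_numpy(), nc["X0"].to_numpy())

    def test_minimum_spacing(self):
        cfg = SimConfig(n_cells=60, field_shape=(300, 300), seed=4)
        gt = sample_population(cfg)
        d = pdist(gt[["row", "col"]].to_numpy())
        assert d.min() >= cfg.min_spacing_px

    def test_field_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            sample_population(SimConfig(n_cells=500, field_shape=(256, 256)))

    def test_seed_determinism(self, small_config):
        a = sample_population(small_config)
        b = sample_population(small_config)
        pd.testing.assert_frame_equal(a, b)
        ia = render_rounds(a, small_config)
        ib = render_rounds(b, small_config)
        for ra, rb in zip(ia.rounds, ib.rounds):
            for ch in ra:
                assert np.array_equal(ra[ch], rb[ch])

    def test_slo_preset_permeabilized_fraction(self):
        """Calibrated Hill curve reproduces the measured 74.6% delivery rate
        at the optimal SLO dose, within the binomial 99% CI at n=10,000."""
        preset = build_preset("SLO-titration-HEK")
        cfg = preset.targeting.replace(n_cells=10_000, seed=11, **BIG_FIELD)
        gt = sample_population(cfg)
        frac = gt["permeabilized"].mean()
        ci99 = 2.576 * np.sqrt(0.746 * 0.254 / 10_000)
        assert abs(frac - PERM_FRACTION_HEK) < ci99

    def test_dose_monotonicity(self):
        fracs = []
        for dose in (0.02, 0.05, 0.1, 0.2, 0.4):
            cfg = SimConfig(n_cells=4000, slo_dose=dose, seed=12, **BIG_FIELD)
            fracs.append(sample_population(cfg)["permeabilized"].mean())
        assert all(b >= a - 0.02 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]


class TestKinetics:
    def test_resistant_fraction_limit(self):
        """Saturated antibody/TRIM21 and long incubation leave exactly the
        resistant pool (closed-form limit of the rate law)."""
        cfg = SimConfig(
            deg_kinetics=DegKinetics(k_max=1.0, resistant_fraction=0.2), incubation_h=1e6
        )
        frac = remaining_target_fraction(np.array([1e12]), np.array([1e12]), cfg)
        assert frac[0] == pytest.approx(0.2, abs=1e-9)

    def test_knockdown_monotone_in_A_T_time(self):
        cfg = SimConfig(deg_kinetics=DegKinetics(k_max=1.0))
        A = np.linspace(1, 1e4, 50)
        f = remaining_target_fraction(A, np.full(50, 500.0), cfg)
        assert (np.diff(f) <= 1e-15).all()
        T = np.linspace(1, 1e4, 50)
        f = remaining_target_fraction(np.full(50, 500.0), T, cfg)
        assert (np.diff(f) <= 1e-15).all()
        f_t = [
            remaining_target_fraction(np.array([300.0]), np.array([300.0]),
                                      cfg.replace(incubation_h=t))[0]
            for t in (0.5, 1, 3, 12)
        ]
        assert (np.diff(f_t) <= 0).all()


class TestCalibration:
    def test_target_zero_gives_zero_rate(self):
        cfg = calibrate_knockdown(SimConfig(), 0.0)
        assert cfg.deg_kinetics.k_max == 0.0

    def test_feasibility_ceiling(self):
        """Bulk knockdown can never exceed permeabilized fraction x (1-f_res)."""
        cfg = calibrate_permeabilization(SimConfig(), 0.5)
        with pytest.raises(ValueError, match="ceiling"):
            calibrate_knockdown(cfg, 0.65)

    def test_ikk3h_calibration_recovers_bulk(self):
        """Re-simulating 20,000 cells reproduces the calibrated 65% bulk
        reduction (the 3-hour measured value) within 0.02."""
        preset = build_preset("IKKa-3h")
        t_cfg = preset.targeting.replace(n_cells=20_000, seed=21, field_shape=(4096, 4096))
        nc_cfg = t_cfg.replace(condition="NC")
        gt_t = sample_population(t_cfg)
        gt_c = sample_population(nc_cfg)
        alive_t, alive_c = gt_t[~gt_t["died"]], gt_c[~gt_c["died"]]
        bulk = 1 - alive_t["X"].mean() / alive_c["X"].mean()
        assert bulk == pytest.approx(0.65, abs=0.02)

    def test_bulk_ceiling_property(self):
        """Over random configurations, expected bulk knockdown stays below the
        permeabilized mass times (1 - resistant fraction)."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            cfg = SimConfig(
                slo_dose=float(rng.uniform(0.05, 0.4)),
                deg_kinetics=DegKinetics(
                    k_max=float(rng.uniform(0, 20)),
                    resistant_fraction=float(rng.uniform(0, 0.5)),
                ),
                incubation_h=float(rng.uniform(0.5, 12)),
            )
            gt = sample_population(cfg.replace(n_cells=4000, seed=int(rng.integers(1e6)), **BIG_FIELD))
            perm = gt["permeabilized"].mean()
            bulk = expected_bulk_knockdown(cfg, n=4000)
            assert bulk <= perm * (1 - cfg.deg_kinetics.resistant_fraction) + 0.03


class TestSpatialMode:
    def test_uniform_identity(self, small_config):
        gt = sample_population(small_config)
        pd.testing.assert_frame_equal(apply_spatial_mode(gt, small_config), gt)

    def test_zero_amplitude_identity(self, small_config):
        cfg = small_config.replace(
            spatial_mode="center_gradient", gradient=GradientConfig(amplitude=0.0)
        )
        gt = sample_population(cfg)
        pd.testing.assert_frame_equal(apply_spatial_mode(gt, cfg), gt)

    def test_center_gradient_enriches_center(self):
        cfg = SimConfig(
            n_cells=3000,
            spatial_mode="center_gradient",
            gradient=GradientConfig(midpoint_frac=0.3, steepness=10.0, amplitude=0.9),
            seed=31,
            **BIG_FIELD,
        )
        gt = apply_spatial_mode(sample_population(cfg), cfg)
        h, w = cfg.field_shape
        r = np.hypot(gt["row"] - (h - 1) / 2, gt["col"] - (w - 1) / 2)
        R = np.hypot((h - 1) / 2, (w - 1) / 2)
        inner = gt.loc[r < 0.2 * R, "permeabilized"].mean()
        outer = gt.loc[r > 0.8 * R, "permeabilized"].mean()
        assert inner >= 3 * max(outer, 1e-9)

    def test_gradient_keeps_invariants(self):
        cfg = SimConfig(n_cells=2000, spatial_mode="center_gradient", seed=32, **BIG_FIELD)
        gt = apply_spatial_mode(sample_population(cfg), cfg)
        assert (gt.loc[~gt["permeabilized"], "A"] == 0).all()
        assert (gt["X"] <= gt["X0"] + 1e-9).all()
        lost = ~gt["permeabilized"]
        assert np.allclose(gt.loc[lost, "X"], gt.loc[lost, "X0"])


class TestRender:
    def test_noise_free_region_means_exact(self, noisefree_config, noisefree_field):
        """With noise, drift and carryover off, the mean over any cell's
        region in the antibody channel equals its configured true mean."""
        from scipy import ndimage as ndi

        gt, images = noisefree_field
        nuc, cells = render_labels(gt, noisefree_config)
        ids = gt["cell_id"].to_numpy()
        ab = images.rounds[0]["Ab"].astype(float)
        means = ndi.mean(ab, cells, ids)
        assert np.array_equal(np.asarray(means), gt["true_Ab"].to_numpy())

    def test_noise_free_sum_conservation(self, noisefree_config, noisefree_field):
        from scipy import ndimage as ndi

        gt, images = noisefree_field
        nuc, cells = render_labels(gt, noisefree_config)
        ids = gt["cell_id"].to_numpy()
        areas = ndi.sum_labels(np.ones_like(cells), cells, ids)
        sums = ndi.sum_labels(images.rounds[0]["Ab"].astype(float), cells, ids)
        assert np.allclose(sums, gt["true_Ab"].to_numpy() * np.asarray(areas))

    def test_recorded_shift_matches_brute_force_correlation(self, small_config):
        """The stored true_shift is recoverable by exhaustive integer-shift
        cross-correlation of the two nuclear images."""
        cfg = small_config.replace(shift_px_sd=3.0, seed=41)
        gt = sample_population(cfg)
        images = render_rounds(gt, cfg)
        true = images.true_shifts[1]
        a = images.rounds[0]["Hoechst"].astype(float)
        b = images.rounds[1]["Hoechst"].astype(float)
        best, best_score = None, -np.inf
        for dy in range(-8, 9):
            for dx in range(-8, 9):
                rolled = np.roll(np.roll(b, -dy, axis=0), -dx, axis=1)
                score = np.corrcoef(a.ravel(), rolled.ravel())[0, 1]
                if score > best_score:
                    best, best_score = (dy, dx), score
        assert best == (int(true[0]), int(true[1]))

    def test_bleach_carryover_arithmetic(self):
        """A blank round-2 channel over a round-1 stained region reads
        carryover x the round-1 signal (noise off)."""
        from scipy import ndimage as ndi

        cfg = SimConfig(
            n_cells=30,
            field_shape=(256, 256),
            rounds=(("Hoechst", "Ab"), ("Hoechst", "PI")),
            pi_channel="PI",
            reseal_fail_prob=0.0,  # PI channel stays blank
            bleach_carryover=0.05,
            noise=NoiseConfig.off(),
            shift_px_sd=0.0,
            seed=42,
        )
        gt = sample_population(cfg)
        images = render_rounds(gt, cfg)
        nuc, cells = render_labels(gt, cfg)
        ids = gt["cell_id"].to_numpy()
        ab1 = np.asarray(ndi.mean(images.rounds[0]["Ab"].astype(float), cells, ids))
        pi2 = np.asarray(ndi.mean(images.rounds[1]["PI"].astype(float), cells, ids))
        assert np.abs(pi2 - 0.05 * ab1).max() <= 0.5  # 16-bit quantization only

    def test_unknown_channel_rejected(self):
        cfg = SimConfig(n_cells=10, field_shape=(256, 256),
                        rounds=(("Hoechst", "Mystery"),), seed=1)
        with pytest.raises(ValueError, match="Mystery"):
            sample_population(cfg)

    def test_invalid_parameters_name_the_field(self):
        with pytest.raises(ValueError, match="reseal_fail_prob"):
            SimConfig(reseal_fail_prob=1.5)
        with pytest.raises(ValueError, match="bleach_carryover"):
            SimConfig(bleach_carryover=1.0)
        with pytest.raises(ValueError, match="nuclear channel"):
            SimConfig(rounds=(("Ab",),))
        with pytest.raises(ValueError, match="k_max"):
            SimConfig(deg_kinetics=DegKinetics(k_max=float("nan")))
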