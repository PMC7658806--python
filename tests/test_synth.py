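"""Synthetic generator: geometry, designs, observers, BOLD forward model."""

import numpy as np
import pytest

from layerlearn.containers import LAYERS
from layerlearn.synth import (
    DesignSpec,
    EffectSpec,
    Observer,
    ObserverSpec,
    PatchSpec,
    VascularSpec,
    coupled_latents,
    double_gamma_hrf,
    generate_design,
    generate_patch,
    generate_session_designs,
    simulate_bold,
    simulate_two_regions,
)


class TestGeneratePatch:
    def test_flat_depth_varies_linearly_with_z(self):
        vol = generate_patch(PatchSpec(grid_shape=(4, 4, 6),
                                       voxel_size_mm=(1, 1, 0.5),
                                       thickness_mm=3.0), seed=0)
        # voxel centers at z = 0.25, 0.75, ... -> depth = z / 3
        iz = np.argwhere(vol.gm_mask)[:, 2]
        expected = (iz + 0.5) * 0.5 / 3.0
        assert np.allclose(vol.depth[vol.gm_mask], expected)

    def test_wedge_depth_matches_radial_formula(self):
        # white radius 10 mm, pial radius 12 mm
        spec = PatchSpec(grid_shape=(12, 2, 10), voxel_size_mm=(0.5, 0.5, 0.5),
                         thickness_mm=2.0, curvature=0.1)
        vol = generate_patch(spec, seed=0)
        r_wm = 10.0
        x = (np.argwhere(vol.gm_mask)[:, 0] + 0.5) * 0.5
        z = r_wm - 1.0 + (np.argwhere(vol.gm_mask)[:, 2] + 0.5) * 0.5
        r = np.sqrt(x**2 + z**2)
        assert np.allclose(vol.depth[vol.gm_mask], (r - r_wm) / 2.0)

    def test_same_seed_identical(self):
        spec = PatchSpec(thickness_jitter_sd=0.2)
        a = generate_patch(spec, seed=3)
        b = generate_patch(spec, seed=3)
        assert np.array_equal(a.thickness_mm, b.thickness_mm)
        assert np.array_equal(a.depth[a.gm_mask], b.depth[b.gm_mask])

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            generate_patch(PatchSpec(thickness_mm=0.0), seed=0)


class TestGenerateDesign:
    def test_block_counts(self, design_spec):
        d = generate_design(design_spec, seed=0)
        assert d.n_condition_blocks == 24  # 4 repeats x 6 conditions
        # opening fixation + one fixation closing each repeat
        assert (d.events["trial_type"] == "fixation").sum() == 5

    def test_single_repeat_each_condition_once(self):
        d = generate_design(DesignSpec(repeats_per_run=1), seed=1)
        counts = d.condition_events["trial_type"].value_counts()
        assert len(counts) == 6 and (counts == 1).all()

    def test_locations_alternate_between_blocks(self, design_spec):
        d = generate_design(design_spec, seed=2)
        locs = d.condition_events["location"].to_numpy()
        for repeat in range(4):
            six = locs[6 * repeat: 6 * repeat + 6]
            assert all(six[i] != six[i + 1] for i in range(5))

    def test_onsets_sorted_and_non_overlapping(self, design_spec):
        d = generate_design(design_spec, seed=3)
        ev = d.events
        assert (np.diff(ev["onset"]) >= ev["duration"][:-1] - 1e-9).all()

    def test_two_seeds_same_counts_different_orders(self, design_spec):
        d1 = generate_design(design_spec, seed=10)
        d2 = generate_design(design_spec, seed=11)
        c1 = d1.condition_events["trial_type"].value_counts()
        c2 = d2.condition_events["trial_type"].value_counts()
        assert c1.sort_index().equals(c2.sort_index())
        assert (d1.condition_events["trial_type"].to_numpy()
                != d2.condition_events["trial_type"].to_numpy()).any()

    def test_block_duration_is_six_trs(self, design_spec):
        # 12.36 s at TR 2.06 s is exactly 6 volumes
        assert design_spec.block_trs == 6


class TestObserver:
    def test_asymptote_is_one_minus_lapse(self):
        for family in ("cumulative-gaussian", "weibull"):
            obs = Observer(ObserverSpec(psychometric_family=family,
                                        lapse_rate=0.05))
            assert obs.percent_correct(1e6) == pytest.approx(0.95, abs=1e-9)

    def test_threshold_criterion_cumulative_gaussian(self):
        # defining criterion: p(threshold) = 0.75 - lapse/2
        obs = Observer(ObserverSpec(threshold_deg=2.0, lapse_rate=0.02))
        assert obs.percent_correct(2.0) == pytest.approx(0.75 - 0.01)

    def test_threshold_criterion_weibull(self):
        obs = Observer(ObserverSpec(psychometric_family="weibull",
                                    threshold_deg=2.0, lapse_rate=0.0))
        assert obs.percent_correct(2.0) == pytest.approx(0.5 + 0.5 * (1 - np.exp(-1)))

    def test_monotone_in_level(self):
        obs = Observer(ObserverSpec())
        levels = np.linspace(0, 10, 200)
        p = obs.percent_correct(levels)
        assert np.all(np.diff(p) >= -1e-12)

    def test_empirical_rate_matches_analytic(self):
        # binomial oracle: 10,000 draws at a fixed level within 3 SE
        obs = Observer(ObserverSpec(threshold_deg=2.0, slope=3.0, seed=99))
        level = 2.5
        p_true = obs.percent_correct(level)
        draws = np.array([obs.respond(level) for _ in range(10_000)])
        se = np.sqrt(p_true * (1 - p_true) / draws.size)
        assert abs(draws.mean() - p_true) < 3 * se

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            Observer(ObserverSpec()).percent_correct(-1.0)


class TestSimulateBold:
    def test_deterministic_given_seed(self, flat_volume, short_designs,
                                      default_effect, default_vascular):
        a, _ = simulate_bold(flat_volume, short_designs, default_effect,
                             default_vascular, seed=5)
        b, _ = simulate_bold(flat_volume, short_designs, default_effect,
                             default_vascular, seed=5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)

    def test_no_confound_limit_equal_layer_means(self, flat_volume, short_designs):
        # superficial_gain 1, drainage 0, no veins: mean stimulus response
        # should not differ across layers beyond noise
        eff = EffectSpec(pattern_amplitude=0.0, activation_amplitude=2.0,
                         lateralized=False)
        vas = VascularSpec(superficial_gain=1.0, drainage_lambda=0.0,
                           vein_fraction=0.0)
        runs, gt = simulate_bold(flat_volume, short_designs, eff, vas,
                                 noise_sd=0.5, seed=1)
        data = runs[0].data
        means = [data[gt.layer_of_voxel == k].mean() for k in range(3)]
        assert np.ptp(means) < 0.2

    def test_superficial_bias_raises_upper_layer_response(self, flat_volume,
                                                          short_designs):
        eff = EffectSpec(pattern_amplitude=0.0, activation_amplitude=2.0,
                         lateralized=False)
        vas = VascularSpec(superficial_gain=3.0, drainage_lambda=0.0,
                           vein_fraction=0.0)
        runs, gt = simulate_bold(flat_volume, short_designs, eff, vas,
                                 noise_sd=0.1, seed=1)
        resp = runs[0].data.std(axis=1)  # response variance tracks amplitude
        by_layer = [resp[gt.layer_of_voxel == k].mean() for k in range(3)]
        assert by_layer[0] < by_layer[1] < by_layer[2]

    def test_drainage_mixing_closed_form(self, flat_volume, short_designs):
        # with zero noise the superficial time course with drainage equals
        # the lambda=0 course plus lambda x same-column donor mean exactly
        eff = EffectSpec(pattern_amplitude=0.04, activation_amplitude=2.0,
                         pattern_seed=3)
        lam = 0.5
        vas0 = VascularSpec(superficial_gain=2.0, drainage_lambda=0.0,
                            vein_fraction=0.0)
        vas1 = VascularSpec(superficial_gain=2.0, drainage_lambda=lam,
                            vein_fraction=0.0)
        runs0, gt = simulate_bold(flat_volume, short_designs[:1], eff, vas0,
                                  noise_sd=0.0, seed=2)
        flat_volume.vein_mask = None  # force re-draw under second spec
        runs1, _ = simulate_bold(flat_volume, short_designs[:1], eff, vas1,
                                 noise_sd=0.0, seed=2)
        y0, y1 = runs0[0].data, runs1[0].data
        cols = flat_volume.column_id[flat_volume.gm_mask]
        sup = gt.layer_of_voxel == 2
        # independent mixing-equation reconstruction per column
        for col in np.unique(cols)[:20]:
            donors = (cols == col) & ~sup
            target = (cols == col) & sup
            if not donors.any() or not target.any():
                continue
            donor_mean = (y0[donors] - 100.0).mean(axis=0)
            expected = y0[target] + lam * donor_mean
            assert np.allclose(y1[target], expected, atol=1e-9)
        # and the implied covariance increase
        i = np.flatnonzero(sup)[0]
        col = cols[i]
        donor_mean = (y0[(cols == col) & ~sup] - 100.0).mean(axis=0)
        cov0 = np.cov(y0[i], donor_mean)[0, 1]
        cov1 = np.cov(y1[i], donor_mean)[0, 1]
        assert cov1 - cov0 == pytest.approx(lam * np.var(donor_mean, ddof=1))

    def test_vein_voxels_low_mean_high_variance(self, flat_volume,
                                                short_designs, default_effect):
        vas = VascularSpec(vein_fraction=0.1)
        flat_volume.vein_mask = None
        runs, gt = simulate_bold(flat_volume, short_designs, default_effect,
                                 vas, noise_sd=3.0, seed=4)
        data = runs[0].data
        assert data[gt.vein_mask].mean() < data[~gt.vein_mask].mean()
        # noise sd is doubled, but stimulus-response variance (shared by
        # all voxels) dilutes the total-std ratio below 2
        assert data[gt.vein_mask].std(axis=1).mean() > 1.2 * data[~gt.vein_mask].std(axis=1).mean()
        tsnr = data.mean(axis=1) / data.std(axis=1)
        assert tsnr[gt.vein_mask].mean() < 0.5 * tsnr[~gt.vein_mask].mean()

    def test_mismatched_design_rejected(self, flat_volume, short_designs,
                                        default_effect, default_vascular):
        runs, _ = simulate_bold(flat_volume, short_designs, default_effect,
                                default_vascular, seed=0)
        from layerlearn.containers import BoldRun
        with pytest.raises(ValueError, match="timepoints"):
            BoldRun(data=runs[0].data[:, :-3], tr_s=2.06, run_id=0,
                    session="pre", design=short_designs[0])


class TestCoupledLatents:
    def test_rho_one_identical_series_on_coupled_blocks(self, short_designs):
        ea = EffectSpec(target_layer="superficial", coupled_fluctuation_sd=0.5)
        eb = EffectSpec(target_layer="middle", coupled_fluctuation_sd=0.5)
        la, lb = coupled_latents(short_designs, ea, eb, coupling_rho=1.0,
                                 seed=0, coupled_orientation="trained")
        for d, a, b in zip(short_designs, la, lb):
            coupled = (d.condition_events["orientation"] == "trained").to_numpy()
            assert np.allclose(a["superficial"][coupled], b["middle"][coupled])
            assert not np.allclose(a["superficial"][~coupled], b["middle"][~coupled])

    def test_recovered_correlation_matches_rho(self, session_designs):
        ea = EffectSpec(target_layer="superficial", coupled_fluctuation_sd=1e-9)
        eb = EffectSpec(target_layer="middle", coupled_fluctuation_sd=1e-9)
        rho = 0.8
        # correlate the underlying z-draws via many blocks
        la, lb = coupled_latents(session_designs * 3, ea, eb, coupling_rho=rho,
                                 seed=1, coupled_orientation="trained")
        za = np.concatenate([(l["superficial"] - 1) / 1e-9 for l in la])
        zb = np.concatenate([(l["middle"] - 1) / 1e-9 for l in lb])
        mask = np.concatenate(
            [(d.condition_events["orientation"] == "trained").to_numpy()
             for d in session_designs * 3])
        got = np.corrcoef(za[mask], zb[mask])[0, 1]
        assert got == pytest.approx(rho, abs=0.1)

    def test_invalid_rho_rejected(self, short_designs):
        with pytest.raises(ValueError):
            coupled_latents(short_designs, EffectSpec(), EffectSpec(),
                            coupling_rho=1.5, seed=0)

    def test_other_layer_pairs_uncoupled(self, session_designs):
        ea = EffectSpec(target_layer="superficial", coupled_fluctuation_sd=0.5)
        eb = EffectSpec(target_layer="middle", coupled_fluctuation_sd=0.5)
        la, lb = coupled_latents(session_designs, ea, eb, coupling_rho=0.9, seed=2)
        a_deep = np.concatenate([l["deeper"] for l in la])
        b_deep = np.concatenate([l["deeper"] for l in lb])
        assert abs(np.corrcoef(a_deep, b_deep)[0, 1]) < 0.2


def test_hrf_peaks_early_and_undershoots():
    h = double_gamma_hrf(tr_s=2.06)
    t = np.arange(h.size) * 2.06
    assert h.max() == pytest.approx(1.0)
    assert 4.0 <= t[np.argmax(h)] <= 8.0
    assert h.min() < 0  # post-stimulus undershoot


def test_simulate_two_regions_deterministic(flat_volume, short_designs,
                                            default_effect, default_vascular):
    eff_b = EffectSpec(target_layer="middle", lateralized=False,
                       pattern_seed=5)
    flat_volume.vein_mask = None
    out1 = simulate_two_regions(flat_volume, flat_volume, short_designs,
                                default_effect, eff_b, default_vascular,
                                coupling_rho=0.5, seed=9)
    flat_volume.vein_mask = None
    out2 = simulate_two_regions(flat_volume, flat_volume, short_designs,
                                default_effect, eff_b, default_vascular,
                                coupling_rho=0.5, seed=9)
    assert np.array_equal(out1[0][0][0].data, out2[0][0][0].data)
    assert np.array_equal(out1[1][0][0].data, out2[1][0][0].data)
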