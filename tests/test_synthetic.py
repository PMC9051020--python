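import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hflpol.grid import CANONICAL_GRID
from hflpol.synthetic import (OCT_AXIAL_UM_PER_PX, SimConfig,
                              composite_retardance, draw_subject,
                              hfl_thickness_profile, nm_to_rad,
                              simulate_cohort, simulate_oct_boundaries,
                              simulate_retardation_map)


def closed_form_retardance(d1, t1, d2, t2):
    """Independent oracle: two-retarder composition via the scalar identity."""
    c = abs(math.cos(d1 / 2) * math.cos(d2 / 2)
            - math.sin(d1 / 2) * math.sin(d2 / 2) * math.cos(2 * (t1 - t2)))
    return 2 * math.acos(min(1.0, c))


class TestThicknessProfile:
    def test_zero_at_center(self, base_cfg):
        assert hfl_thickness_profile(base_cfg, 0.0, 0) == 0.0

    def test_peak_value(self, base_cfg):
        assert hfl_thickness_profile(base_cfg, base_cfg.r_peak, 0) \
            == pytest.approx(base_cfg.t_max)

    def test_closed_form_value(self):
        # shape=2, r = 2*r_peak, t_max=30 -> 30 * 2^2 * exp(2*(1-2))
        cfg = replace(SimConfig(), shape=2.0, t_max=30.0, r_peak=2.0)
        expected = 30.0 * 4.0 * math.exp(-2.0)
        assert hfl_thickness_profile(cfg, 4.0, 0) == pytest.approx(expected)

    def test_negative_r_rejected(self, base_cfg):
        with pytest.raises(ValueError):
            hfl_thickness_profile(base_cfg, -0.1, 0)

    def test_bad_meridian_index(self, base_cfg):
        with pytest.raises(ValueError):
            hfl_thickness_profile(base_cfg, 1.0, 4)

    def test_meridian_modulation(self):
        cfg = replace(SimConfig(), meridian_mod=(0.1, -0.1, 0.2, 0.0))
        base = hfl_thickness_profile(replace(cfg, meridian_mod=(0,) * 4), 1.0, 0)
        for m, mod in enumerate(cfg.meridian_mod):
            assert hfl_thickness_profile(cfg, 1.0, m) \
                == pytest.approx(base * (1 + mod))

    @given(shape=st.floats(0.5, 4.0), r_peak=st.floats(0.5, 3.0),
           t_max=st.floats(5.0, 60.0))
    @settings(max_examples=30, deadline=None)
    def test_unimodal_peak_at_r_peak(self, shape, r_peak, t_max):
        cfg = replace(SimConfig(), shape=shape, r_peak=r_peak, t_max=t_max)
        r = np.linspace(0, 4 * r_peak, 400)
        t = hfl_thickness_profile(cfg, r, 0)
        assert np.all(t >= 0)
        assert t[0] == 0.0
        peak_idx = int(np.argmax(t))
        assert r[peak_idx] == pytest.approx(r_peak, abs=r[1] - r[0])
        # strictly increasing before, decreasing after (unimodality)
        assert np.all(np.diff(t[: peak_idx + 1]) >= 0)
        assert np.all(np.diff(t[peak_idx:]) <= 0)


class TestCompositeRetardance:
    def test_identity_element(self):
        d = composite_retardance(0.7, 0.3, 0.0, 1.1)
        assert d == pytest.approx(0.7, abs=1e-12)

    def test_crossed_equal_retarders_cancel(self):
        d = composite_retardance(0.9, 0.2, 0.9, 0.2 + math.pi / 2)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_quarter_wave_at_45(self):
        d = composite_retardance(math.pi / 2, 0.0, math.pi / 2, math.pi / 4)
        assert d == pytest.approx(2 * math.pi / 3, abs=1e-9)

    def test_negative_retardance_rejected(self):
        with pytest.raises(ValueError):
            composite_retardance(-0.1, 0.0, 0.5, 0.0)

    def test_oracle_equivalence_grid(self):
        deltas = np.linspace(0.0, math.pi, 20)
        thetas = np.linspace(0.0, math.pi, 20)
        for d1 in deltas:
            for d2 in deltas:
                for th in thetas:
                    got = composite_retardance(d1, 0.0, d2, th)
                    want = closed_form_retardance(d1, 0.0, d2, th)
                    assert got == pytest.approx(want, abs=1e-9)

    def test_vectorized_matches_scalar(self, rng):
        d1 = rng.uniform(0, math.pi, 50)
        t1 = rng.uniform(0, math.pi, 50)
        d2 = rng.uniform(0, math.pi, 50)
        t2 = rng.uniform(0, math.pi, 50)
        vec = composite_retardance(d1, t1, d2, t2)
        for i in range(50):
            assert vec[i] == pytest.approx(
                closed_form_retardance(d1[i], t1[i], d2[i], t2[i]), abs=1e-9)


class TestSimulateRetardationMap:
    def test_variable_rings_constant(self, variable_map_noiseless, noiseless_cfg):
        from hflpol.slp import RetardationMap, ring_profile
        rmap, truth = variable_map_noiseless
        # exact azimuthal constancy on the noise-free retardance field
        exact = RetardationMap(noiseless_cfg.gain * truth.retardance_map_nm,
                               rmap.deg_per_px, "variable")
        for ecc in (0.5, 1.0, 2.0, 3.0):
            prof = ring_profile(exact, truth.foveal_center_px, ecc)
            # bilinear sampling of a curved radial field leaves ~0.4%
            # azimuthal ripple; that is the interpolation tolerance
            assert np.ptp(prof.intensity) < 0.005 * prof.intensity.mean()
            # the 8-bit rendering is constant to quantization tolerance
            quant = ring_profile(rmap, truth.foveal_center_px, ecc)
            assert np.ptp(quant.intensity) <= 2.0

    def test_fixed_rings_second_harmonic(self, fixed_map_noiseless):
        from hflpol.slp import cross_amplitude, ring_profile
        rmap, truth = fixed_map_noiseless
        for ecc in (1.0, 1.5, 2.0):
            prof = ring_profile(rmap, truth.foveal_center_px, ecc)
            _, _, r2 = cross_amplitude(prof)
            assert r2 > 0.99

    def test_zero_coupling_uniform(self, noiseless_cfg):
        cfg = replace(noiseless_cfg, coupling=0.0)
        rmap, _ = simulate_retardation_map(cfg, "fixed", 0)
        expected = cfg.gain * cfg.corneal_residual_nm
        assert np.all(rmap.pixels == pytest.approx(expected, abs=0.51))
        assert np.ptp(rmap.pixels) == 0

    def test_truth_consistency(self, fixed_map_noiseless):
        rmap, truth = fixed_map_noiseless
        r, t = truth.thickness_by_meridian["temporal"]
        assert t[0] == 0.0
        assert np.all(t >= 0)
        assert truth.retardance_map_nm.shape == rmap.pixels.shape

    def test_fov_too_small(self, noiseless_cfg):
        cfg = replace(noiseless_cfg, fov_deg=(5.0, 5.0))
        with pytest.raises(ValueError, match="field of view"):
            simulate_retardation_map(cfg, "fixed", 0)

    def test_unknown_mode(self, noiseless_cfg):
        with pytest.raises(ValueError, match="mode"):
            simulate_retardation_map(noiseless_cfg, "enhanced", 0)

    def test_fixed_composes_corneal(self, noiseless_cfg):
        """Noise-free retardance equals the composition oracle per pixel."""
        rmap, truth = simulate_retardation_map(noiseless_cfg, "fixed", 3)
        r0, c0 = truth.foveal_center_px
        row, col = 60, 300
        dy, dx = -(row - r0), col - c0
        ecc = math.hypot(dx, dy) * noiseless_cfg.deg_per_px
        phi = math.atan2(dy, dx)
        hfl_nm = noiseless_cfg.coupling * hfl_thickness_profile(
            noiseless_cfg, ecc, 0)
        want_rad = closed_form_retardance(
            nm_to_rad(hfl_nm), phi,
            nm_to_rad(noiseless_cfg.corneal_residual_nm),
            math.radians(noiseless_cfg.corneal_axis_deg))
        got_nm = truth.retardance_map_nm[row, col]
        assert got_nm == pytest.approx(want_rad * 780 / (2 * math.pi), rel=1e-9)


class TestSimulateOctBoundaries:
    def test_noiseless_difference_is_truth(self, noiseless_cfg):
        scan = simulate_oct_boundaries(noiseless_cfg, "horizontal", +1, 0)
        ecc = (scan.anterior.columns - scan.true_foveal_col) \
            * scan.meta.lateral_um_per_px / 320.0
        m_idx = np.where(ecc < 0, 0, 2)
        t_px = np.array([
            hfl_thickness_profile(noiseless_cfg, abs(e), int(m))
            for e, m in zip(ecc, m_idx)]) / OCT_AXIAL_UM_PER_PX
        diff = scan.posterior.depths - scan.anterior.depths
        np.testing.assert_allclose(diff, t_px, atol=1e-9)

    def test_os_band_peaks_at_fovea(self, noiseless_cfg):
        scan = simulate_oct_boundaries(noiseless_cfg, "vertical", -1, 5)
        peak_col = scan.os_band.columns[np.argmax(scan.os_band.depths)]
        assert peak_col == scan.true_foveal_col

    def test_offset_sign_swaps_masks(self, noiseless_cfg):
        plus = simulate_oct_boundaries(noiseless_cfg, "horizontal", +1, 2)
        minus = simulate_oct_boundaries(noiseless_cfg, "horizontal", -1, 2)
        rel = plus.anterior.columns - plus.true_foveal_col
        # anterior: proximal side; posterior: distal side
        np.testing.assert_array_equal(plus.anterior.valid, rel >= 0)
        np.testing.assert_array_equal(minus.anterior.valid, rel <= 0)
        np.testing.assert_array_equal(plus.posterior.valid, rel <= 0)
        np.testing.assert_array_equal(minus.posterior.valid, rel >= 0)
        # union covers every column for both boundaries
        assert np.all(plus.anterior.valid | minus.anterior.valid)
        assert np.all(plus.posterior.valid | minus.posterior.valid)

    def test_same_fovea_across_offsets(self, base_cfg):
        plus = simulate_oct_boundaries(base_cfg, "vertical", +1, 7)
        minus = simulate_oct_boundaries(base_cfg, "vertical", -1, 7)
        assert plus.true_foveal_col == minus.true_foveal_col

    def test_unknown_meridian(self, noiseless_cfg):
        with pytest.raises(ValueError, match="meridian"):
            simulate_oct_boundaries(noiseless_cfg, "oblique", +1, 0)

    def test_offset_magnitude(self, noiseless_cfg):
        scan = simulate_oct_boundaries(noiseless_cfg, "horizontal", -1, 0)
        assert scan.meta.offset_mm == -3.0


class TestSimulateCohort:
    def test_deterministic_files(self, noiseless_cfg, tmp_path):
        for d in ("a", "b"):
            simulate_cohort(noiseless_cfg, 2, "fixed", seed=3,
                            out_dir=tmp_path / d)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_subject_count_and_validation(self, noiseless_cfg):
        with pytest.raises(ValueError):
            simulate_cohort(noiseless_cfg, 0, "fixed")
        bundles = simulate_cohort(noiseless_cfg, 3, "variable", seed=1)
        assert len(bundles) == 3
        assert len({b.subject_id for b in bundles}) == 3

    def test_no_corneal_variation_when_sd_zero(self, noiseless_cfg):
        cfgs = [draw_subject(noiseless_cfg, "fixed", i) for i in range(4)]
        assert len({c.corneal_residual_nm for c in cfgs}) == 1
        assert len({c.corneal_axis_deg for c in cfgs}) == 1
        # subjects still differ, but only through thickness-profile fields
        assert len({(c.t_max, c.shape, c.r_peak) for c in cfgs}) == 4

    def test_corneal_varies_in_fixed_mode(self, base_cfg):
        mags = {draw_subject(base_cfg, "fixed", i).corneal_residual_nm
                for i in range(4)}
        assert len(mags) == 4

    def test_variable_mode_residual_zero(self, base_cfg):
        for i in range(3):
            assert draw_subject(base_cfg, "variable", i).corneal_residual_nm == 0.0
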