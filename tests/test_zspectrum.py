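"""Z-spectrum processing: normalization, B0 correction, asymmetry metric."""

import numpy as np
import pytest

from aptperf.bmsim import simulate_offset, simulate_zspectrum
from aptperf.zspectrum import (AptwConfig, ZSpectrum, aptw, b0_correct,
                               compute_aptw_maps, fluid_suppress, interp_z,
                               normalize_zspectrum)

OFFSETS = np.round(np.arange(-5.0, 5.01, 0.5), 6)


def lorentzian_spec(center=0.0, depth=0.8, width=1.0, offsets=OFFSETS):
    z = 1.0 - depth / (1.0 + ((offsets - center) / width) ** 2)
    return ZSpectrum(offsets=offsets, z=z)


class TestNormalize:
    def test_identity_when_saturated_equals_reference(self):
        spec = normalize_zspectrum(np.full(21, 800.0), 800.0, offsets=OFFSETS)
        assert np.allclose(spec.z, 1.0)
        assert spec.b0_shift == 0.0

    def test_nonpositive_s0_rejected(self):
        with pytest.raises(ValueError):
            normalize_zspectrum(np.ones(21), 0.0, offsets=OFFSETS)
        with pytest.raises(ValueError):
            normalize_zspectrum(np.ones(21), np.nan, offsets=OFFSETS)

    def test_round_trip_against_bloch_mcconnell_forward(self, wm, sat, plan):
        """Normalizing simulated raw intensities reproduces simulated Z."""
        s0_sim = abs(simulate_offset(wm, sat, plan.s0_offset))
        s_sat = np.array([abs(simulate_offset(wm, sat, w)) for w in plan.offsets])
        scale = 1234.5  # arbitrary scanner gain, cancels in the ratio
        spec = normalize_zspectrum(s_sat * scale, s0_sim * scale,
                                   offsets=np.asarray(plan.offsets))
        ref = simulate_zspectrum(wm, sat, plan)
        np.testing.assert_allclose(spec.z, ref.z, atol=1e-10)


class TestB0Correct:
    def test_centered_spectrum_unchanged(self):
        spec = b0_correct(lorentzian_spec(center=0.0))
        assert abs(spec.b0_shift) < 1e-12
        assert not spec.uncorrectable

    @pytest.mark.parametrize("shift", [-0.4, -0.3, -0.15, 0.15, 0.3, 0.4])
    def test_known_shift_recovered(self, shift):
        spec = b0_correct(lorentzian_spec(center=shift))
        assert spec.b0_shift == pytest.approx(shift, abs=0.05)
        # the corrected axis places the minimum at ~0 ppm
        k = int(np.argmin(spec.z))
        assert abs(spec.offsets[k]) <= 0.5

    def test_flat_spectrum_flagged_uncorrectable(self):
        spec = b0_correct(ZSpectrum(offsets=OFFSETS, z=np.full(21, 0.9)))
        assert spec.uncorrectable and spec.b0_shift == 0.0

    def test_boundary_minimum_flagged(self):
        z = np.linspace(0.2, 1.0, 21)  # minimum at the left edge
        spec = b0_correct(ZSpectrum(offsets=OFFSETS, z=z))
        assert spec.uncorrectable

    def test_idempotent_on_smooth_spectra(self):
        first = b0_correct(lorentzian_spec(center=0.3))
        second = b0_correct(first)
        assert abs(second.b0_shift) < 1e-6


class TestInterp:
    def test_knot_identity_and_midpoint(self):
        spec = ZSpectrum(offsets=np.array([3.0, 3.5]), z=np.array([0.6, 0.8]))
        with pytest.raises(ValueError):
            interp_z(spec, 2.9)
        spec5 = ZSpectrum(offsets=np.array([2.0, 2.5, 3.0, 3.5, 4.0]),
                          z=np.array([0.5, 0.55, 0.6, 0.8, 0.9]))
        assert interp_z(spec5, 3.0) == 0.6
        assert interp_z(spec5, 3.25) == pytest.approx(0.7, abs=1e-15)

    def test_matches_independent_two_point_formula(self):
        rng = np.random.default_rng(3)
        z = rng.uniform(0.3, 1.0, len(OFFSETS))
        spec = ZSpectrum(offsets=OFFSETS, z=z)
        for omega in rng.uniform(-5, 5, 200):
            i = np.searchsorted(OFFSETS, omega, side="right") - 1
            i = min(max(i, 0), len(OFFSETS) - 2)
            w = (omega - OFFSETS[i]) / (OFFSETS[i + 1] - OFFSETS[i])
            expected = (1 - w) * z[i] + w * z[i + 1]
            assert interp_z(spec, omega) == pytest.approx(expected, abs=1e-12)


def riemann_aptw(spec, cfg=AptwConfig(), n=100_000):
    """Brute-force asymmetry integral of the linear interpolant."""
    d1, d2 = cfg.delta_omega_1, cfg.delta_omega_2
    wneg = np.linspace(-d2, -d1, n)
    wpos = np.linspace(d1, d2, n)
    zneg = np.interp(wneg, spec.offsets, spec.z)
    zpos = np.interp(wpos, spec.offsets, spec.z)
    return 100.0 * (np.trapezoid(zneg, wneg) - np.trapezoid(zpos, wpos)) / (d2 - d1)


class TestAptw:
    def test_symmetric_spectrum_gives_zero(self):
        spec = lorentzian_spec()
        assert aptw(spec) == pytest.approx(0.0, abs=1e-10)

    def test_constant_band_values(self):
        z = np.ones(21)
        z[(OFFSETS >= -4.0) & (OFFSETS <= -3.0)] = 0.7
        z[(OFFSETS >= 3.0) & (OFFSETS <= 4.0)] = 0.6
        spec = ZSpectrum(offsets=OFFSETS, z=z)
        assert aptw(spec) == pytest.approx(10.0, abs=1e-12)

    def test_matches_brute_force_riemann(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            spec = ZSpectrum(offsets=OFFSETS, z=rng.uniform(0.2, 1.0, 21))
            assert aptw(spec) == pytest.approx(riemann_aptw(spec), abs=1e-6)

    def test_mirror_antisymmetry(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(0.2, 1.0, 21)
        spec = ZSpectrum(offsets=OFFSETS, z=z)
        mirrored = ZSpectrum(offsets=OFFSETS, z=z[::-1])
        assert aptw(mirrored) == pytest.approx(-aptw(spec), abs=1e-12)

    def test_invariant_to_common_intensity_scaling(self):
        rng = np.random.default_rng(2)
        s_sat = rng.uniform(300, 900, 21)
        a1 = aptw(normalize_zspectrum(s_sat, 1000.0, offsets=OFFSETS))
        a2 = aptw(normalize_zspectrum(3.7 * s_sat, 3700.0, offsets=OFFSETS))
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_bounds_outside_range_rejected(self):
        spec = ZSpectrum(offsets=np.linspace(-3, 3, 13), z=np.full(13, 0.8))
        with pytest.raises(ValueError):
            aptw(spec)


class TestFluidSuppress:
    cfg = AptwConfig()

    def test_white_matter_reference_is_identity(self):
        assert fluid_suppress(2.0, 0.4, self.cfg) == pytest.approx(2.0)

    def test_direct_substitution(self):
        assert fluid_suppress(2.0, 0.8, self.cfg) == pytest.approx(0.5)

    def test_csf_like_reference_attenuates(self):
        out = fluid_suppress(2.0, 1.0, self.cfg)
        assert out == pytest.approx(0.32)
        assert out < 2.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            fluid_suppress(2.0, 0.0, self.cfg)

    def test_order_preserving_in_aptw(self):
        vals = np.linspace(-1, 4, 20)
        out = [fluid_suppress(v, 0.7, self.cfg) for v in vals]
        assert np.all(np.diff(out) > 0)


class TestMaps:
    def test_uniform_phantom_gives_constant_maps(self):
        z = lorentzian_spec(depth=0.6).z
        vol = np.broadcast_to(z * 900.0, (4, 5, 3, 21)).copy()
        s0 = np.full((4, 5, 3), 900.0)
        mask = np.ones((4, 5, 3), bool)
        maps = compute_aptw_maps(vol, s0, mask, offsets=OFFSETS)
        assert np.nanstd(maps.aptw) < 1e-12
        assert np.nanstd(maps.aptw_fs) < 1e-12

    def test_mask_and_invalid_voxels_are_nan(self):
        z = lorentzian_spec(depth=0.6).z
        vol = np.broadcast_to(z * 900.0, (3, 3, 2, 21)).copy()
        s0 = np.full((3, 3, 2), 900.0)
        s0[0, 0, 0] = 0.0  # invalid normalizer
        mask = np.ones((3, 3, 2), bool)
        mask[1, 1, 1] = False
        maps = compute_aptw_maps(vol, s0, mask, offsets=OFFSETS)
        assert np.isnan(maps.aptw[0, 0, 0]) and np.isnan(maps.aptw[1, 1, 1])
        assert np.isnan(maps.aptw_fs[1, 1, 1]) and np.isnan(maps.b0_map[1, 1, 1])
        other = np.ones((3, 3, 2), bool)
        other[0, 0, 0] = other[1, 1, 1] = False
        assert np.all(np.isfinite(maps.aptw[other]))

    def test_map_chain_equals_scalar_chain_per_tissue(self, clean_subject,
                                                      clean_config):
        """Vectorized map pipeline == scalar single-voxel chain, noiselessly."""
        from aptperf.cohort import subject_parameter_maps
        from aptperf.phantom import LABELS

        maps = subject_parameter_maps(clean_subject, clean_config)
        cfg = AptwConfig()
        for name in ("NAWM", "ET", "edema"):
            spec = b0_correct(clean_subject.truth.spectra[name])
            expect_aptw = aptw(spec, cfg)
            expect_fs = fluid_suppress(expect_aptw,
                                       interp_z(spec, cfg.ref_offset), cfg)
            sel = clean_subject.labels == LABELS[name]
            got = maps["APTw"][sel]
            np.testing.assert_allclose(got, expect_aptw, atol=1e-9)
            np.testing.assert_allclose(maps["APTw_FS"][sel], expect_fs, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_aptw_maps(np.zeros((2, 2, 2, 5)), np.ones((2, 2, 2)),
                              np.ones((2, 2, 2), bool), offsets=OFFSETS)
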