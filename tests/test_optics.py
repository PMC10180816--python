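"""Transfer functions, the 4f filtering step, and the nanobrick library."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaspi import optics
from metaspi.optics import (
    ComplexField,
    NanobrickLibrary,
    OpticalConfig,
    apply_4f,
    build_transfer,
    circular_aperture,
    constant_transfer,
    field_intensity,
    perturb_transfer,
    quantize_transfer,
    spiral_transfer,
    wrap_phase,
)


@given(st.floats(-50, 50, allow_nan=False))
@settings(max_examples=50, deadline=None)
def test_wrap_phase_lands_in_half_open_interval(x):
    w = float(wrap_phase(x))
    assert -np.pi < w <= np.pi
    assert np.isclose(np.exp(1j * w), np.exp(1j * x), atol=1e-9)


class TestSpiralTransfer:
    def test_phase_on_positive_axes(self):
        h = spiral_transfer(64, 0.0)
        c = 32  # DC index
        assert np.angle(h.values[c, c + 5]) == pytest.approx(0.0, abs=1e-12)  # +u axis
        assert np.angle(h.values[c + 5, c]) == pytest.approx(np.pi / 2, abs=1e-12)  # +v axis

    def test_constant_offset_c1(self):
        h = spiral_transfer(64, 0.7)
        assert np.angle(h.values[32, 40]) == pytest.approx(0.7, abs=1e-12)

    def test_unit_modulus_off_dc_and_opaque_singularity(self):
        h = spiral_transfer(32, 0.0)
        mod = np.abs(h.values)
        assert mod[16, 16] == 0.0  # vortex singularity blocks DC
        mod[16, 16] = 1.0
        np.testing.assert_allclose(mod, 1.0, atol=1e-12)

    def test_phase_winds_once_around_dc(self):
        # brute-force unwrap along the 8-neighbor loop around the DC sample
        h = spiral_transfer(32, 0.0)
        c = 16
        # counterclockwise in (v, u): +row is +v with the centered convention
        loop = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1)]
        phases = np.array([np.angle(h.values[c + dr, c + dc]) for dr, dc in loop])
        winding = np.sum(wrap_phase(np.diff(phases)))
        assert winding == pytest.approx(2 * np.pi, abs=1e-9)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            spiral_transfer(7)


class TestConstantTransfer:
    @pytest.mark.parametrize("c2,expected", [(0.0, 1.0 + 0j), (np.pi / 2, 1j)])
    def test_uniform_value(self, c2, expected):
        h = constant_transfer(16, c2)
        np.testing.assert_allclose(h.values, expected, atol=1e-12)

    def test_global_phase_only_in_4f(self, rng):
        img = rng.random((16, 16))
        out = apply_4f(ComplexField(img), constant_transfer(16, 0.9))
        np.testing.assert_allclose(out.values, img * np.exp(0.9j), atol=1e-10)


class TestApply4f:
    def test_identity_filter(self, rng):
        img = rng.random((32, 32))
        out = apply_4f(ComplexField(img), constant_transfer(32, 0.0))
        assert np.max(np.abs(out.values - img)) < 1e-12

    def test_spiral_annihilates_uniform_field(self):
        out = apply_4f(ComplexField(np.ones((64, 64))), spiral_transfer(64, 0.0))
        assert np.mean(field_intensity(out)) < 1e-3

    def test_impulse_response_is_inverse_transform_of_h(self):
        n = 16
        impulse = np.zeros((n, n))
        impulse[n // 2, n // 2] = 1.0
        h = spiral_transfer(n, 0.2)
        out = apply_4f(ComplexField(impulse), h)
        # impulse spectrum is a pure (alternating-sign) phase ramp; divide it out
        spectrum = np.fft.fftshift(np.fft.fft2(impulse))
        expected = np.fft.ifft2(np.fft.ifftshift(spectrum * h.values))
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_matches_direct_double_loop_dft_oracle(self, rng):
        n = 8
        img = rng.random((n, n)) + 1j * rng.random((n, n))
        h = spiral_transfer(n, 0.4)
        # independent oracle: explicit double-loop DFT -> multiply -> inverse DFT
        f = np.zeros((n, n), complex)
        for v in range(n):
            for u in range(n):
                for y in range(n):
                    for x in range(n):
                        f[v, u] += img[y, x] * np.exp(-2j * np.pi * (u * x + v * y) / n)
        g = f * np.fft.ifftshift(h.values)
        expected = np.zeros((n, n), complex)
        for y in range(n):
            for x in range(n):
                for v in range(n):
                    for u in range(n):
                        expected[y, x] += g[v, u] * np.exp(2j * np.pi * (u * x + v * y) / n)
        expected /= n * n
        out = apply_4f(ComplexField(img), h)
        assert np.max(np.abs(out.values - expected)) < 1e-9

    def test_energy_conservation_for_unit_modulus_h(self, rng):
        img = rng.random((32, 32)) + 1j * rng.random((32, 32))
        h = constant_transfer(32, 0.0)
        h.values[:] = np.exp(1j * rng.uniform(-np.pi, np.pi, (32, 32)))  # random all-pass
        out = apply_4f(ComplexField(img), h)
        e_in = np.sum(np.abs(img) ** 2)
        e_out = np.sum(field_intensity(out))
        assert abs(e_out - e_in) / e_in < 1e-9

    def test_linearity(self, rng):
        h = spiral_transfer(16, 0.0)
        e1 = rng.random((16, 16))
        e2 = rng.random((16, 16))
        a, b = 2.5, -0.7
        lhs = apply_4f(ComplexField(a * e1 + b * e2), h).values
        rhs = a * apply_4f(ComplexField(e1), h).values + b * apply_4f(ComplexField(e2), h).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_4f(ComplexField(np.ones((16, 16))), constant_transfer(32, 0.0))


class TestNanobrickLibrary:
    def test_bundled_table_matches_published_values(self, library):
        assert len(library.entries) == 16
        e6 = library.entries[5]
        assert (e6.a_nm, e6.b_nm, e6.delta_x, e6.t_x, e6.delta_y, e6.t_y) == (
            96, 160, -1.10, 1.0, 0.38, 0.94,
        )
        e15 = library.entries[14]
        assert (e15.a_nm, e15.b_nm, e15.delta_x) == (152, 40, -3.14)

    def test_entry_invariants(self, library):
        for e in library.entries:
            assert 0.0 <= e.t_x <= 1.0 and 0.0 <= e.t_y <= 1.0
            assert -np.pi < e.delta_x <= np.pi and -np.pi < e.delta_y <= np.pi

    def test_wrong_size_rejected(self, library):
        with pytest.raises(ValueError):
            NanobrickLibrary(library.entries[:10])

    def test_max_quantization_error_from_gap_table(self, library):
        # brute-force gap oracle over the sorted delta_x column
        p = np.sort([e.delta_x for e in library.entries])
        gaps = np.diff(np.concatenate([p, [p[0] + 2 * np.pi]]))
        assert library.max_quantization_error("xlp") == pytest.approx(np.max(gaps) / 2)


class TestQuantizeTransfer:
    def test_exact_library_phase_maps_to_its_brick(self, library):
        h = constant_transfer(16, -1.10)  # delta_x of brick NUM 6, t_x = 1
        q = quantize_transfer(h, library, mode="xlp")
        np.testing.assert_allclose(q.values, 1.0 * np.exp(-1.10j), atol=1e-12)

    def test_zero_phase_snaps_to_nearest_brick(self, library):
        # 0.18 (NUM 11, t=0.98) beats -0.24 (NUM 9): |0-0.18| < |0-(-0.24)|
        h = constant_transfer(16, 0.0)
        q = quantize_transfer(h, library, mode="xlp")
        np.testing.assert_allclose(np.angle(q.values), 0.18, atol=1e-12)
        np.testing.assert_allclose(np.abs(q.values), 0.98, atol=1e-12)

    @pytest.mark.parametrize("mode", ["xlp", "ylp"])
    def test_error_bounded_by_half_largest_gap(self, library, mode):
        h = spiral_transfer(64, 0.3)
        q = quantize_transfer(h, library, mode=mode)
        live = np.abs(h.values) > 0
        err = np.abs(optics.wrap_phase(np.angle(q.values[live]) - np.angle(h.values[live])))
        assert np.max(err) <= library.max_quantization_error(mode) + 1e-12

    def test_idempotent(self, library):
        q1 = quantize_transfer(spiral_transfer(32, 0.0), library, mode="xlp")
        q2 = quantize_transfer(q1, library, mode="xlp")
        np.testing.assert_array_equal(q1.values, q2.values)

    def test_invalid_library_rejected(self):
        with pytest.raises(TypeError):
            quantize_transfer(spiral_transfer(16), library=None)


class TestPerturbTransfer:
    def test_zero_sigma_is_identity(self, library):
        h = quantize_transfer(spiral_transfer(32), library)
        p = perturb_transfer(h, 0.0, 0.0, seed=3)
        np.testing.assert_array_equal(p.values, h.values)

    def test_phase_sd_calibration(self):
        h = constant_transfer(128, 0.5)
        p = perturb_transfer(h, 0.1, 0.0, seed=11)
        dphi = np.angle(p.values * np.conj(h.values))
        assert 0.09 <= float(np.std(dphi)) <= 0.11  # >= 16384 samples

    def test_seeded_determinism(self):
        h = spiral_transfer(32)
        a = perturb_transfer(h, 0.2, 0.05, seed=9)
        b = perturb_transfer(h, 0.2, 0.05, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_amplitude_stays_physical(self):
        p = perturb_transfer(constant_transfer(32, 0.0), 0.0, 0.8, seed=1)
        assert np.all(np.abs(p.values) <= 1.0 + 1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            perturb_transfer(constant_transfer(16), -0.1)


class TestFieldIntensityAndConfig:
    def test_intensity_scaling(self, rng):
        f = ComplexField(rng.random((16, 16)) * np.exp(1j * rng.random((16, 16))))
        i1 = field_intensity(f)
        i2 = field_intensity(ComplexField(2.0 * f.values))
        np.testing.assert_allclose(i2, 4.0 * i1, atol=1e-12)
        assert np.all(i1 >= 0)

    def test_config_wraps_constants_and_builds_both_modes(self, library):
        cfg = OpticalConfig(grid_size=16, mode="xlp", c1=3 * np.pi)
        assert -np.pi < cfg.c1 <= np.pi
        hx = build_transfer(cfg)
        hy = build_transfer(OpticalConfig(grid_size=16, mode="ylp", quantization="library16"), library)
        assert hx.mode == "xlp" and not hx.quantized
        assert hy.mode == "ylp" and hy.quantized

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OpticalConfig(grid_size=4)
        with pytest.raises(ValueError):
            OpticalConfig(grid_size=16, mode="circular")  # type: ignore[arg-type]

    def test_circular_aperture_masks_high_frequencies(self):
        h = circular_aperture(constant_transfer(32, 0.0), radius_frac=0.5)
        assert h.values[16, 16] == 1.0  # DC kept
        assert h.values[0, 0] == 0.0  # corner cropped


def test_hdf5_round_trip(tmp_path, rng, library):
    from metaspi import io as mio

    f = ComplexField(rng.random((16, 16)) + 1j * rng.random((16, 16)), pixel_pitch=0.36)
    mio.save_field(tmp_path / "f.h5", f)
    g = mio.load_field(tmp_path / "f.h5")
    np.testing.assert_array_equal(f.values, g.values)
    assert g.pixel_pitch == pytest.approx(0.36)

    h = quantize_transfer(spiral_transfer(16, 0.1), library)
    mio.save_transfer(tmp_path / "h.h5", h)
    h2 = mio.load_transfer(tmp_path / "h.h5")
    np.testing.assert_array_equal(h.values, h2.values)
    assert h2.quantized and h2.mode == "xlp"
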