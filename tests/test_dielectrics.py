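"""Dispersion models, Cole-Cole -> Debye conversion, heterogeneity bounds
and the intensity-to-property mapping."""

import numpy as np
import pytest

from mwibreast.dielectrics import (
    EPS0,
    DispersionParams,
    TissueCurveTable,
    build_bound_curves,
    cole_cole_eval,
    cole_to_debye,
    debye_eval,
    frequency_grid,
    generate_property_maps,
    map_intensity_to_property,
    validate_frequency,
)
from mwibreast.errors import FrequencyGridError, ParameterError, TableError
from mwibreast.volume import Volume3D


def complex_oracle(p: DispersionParams, f_ghz: float):
    """Independent complex-arithmetic evaluation of either dispersion."""
    w = 2 * np.pi * f_ghz * 1e9
    eps_c = (
        p.eps_inf
        + p.delta_eps / (1 + (1j * w * p.tau) ** (1 - p.alpha))
        + p.sigma_s / (1j * w * EPS0)
    )
    return eps_c.real, -w * EPS0 * eps_c.imag


class TestFrequencyGrid:
    def test_grid_is_3_to_10_step_001(self):
        grid = frequency_grid()
        assert grid.size == 701
        assert grid[0] == 3.0 and grid[-1] == 10.0
        np.testing.assert_allclose(np.diff(grid), 0.01, atol=1e-9)

    @pytest.mark.parametrize("f", [2.99, 10.01, 6.005, 2.5, 0.0])
    def test_off_grid_rejected(self, f):
        with pytest.raises(FrequencyGridError):
            validate_frequency(f)

    @pytest.mark.parametrize("f", [3.0, 6.0, 6.05, 9.99, 10.0])
    def test_on_grid_accepted(self, f):
        assert validate_frequency(f) == f

    def test_error_names_nearest_valid(self):
        with pytest.raises(FrequencyGridError, match="6.00, 6.01"):
            validate_frequency(6.005)


class TestDispersionEval:
    def test_dispersionless_limit(self):
        p = DispersionParams("debye", 4.0, 0.0, 13e-12, 0.0)
        for f in (3.0, 6.0, 10.0):
            eps, sig = debye_eval(p, f)
            assert eps == 4.0 and sig == 0.0

    def test_analytic_midpoint_at_omega_tau_one(self):
        tau = 13e-12
        f_ghz = 1.0 / (2 * np.pi * tau) / 1e9  # w = 1/tau
        p = DispersionParams("debye", 4.0, 3.0, tau, 0.1)
        eps, sig = debye_eval(p, f_ghz)
        np.testing.assert_allclose(eps, 4.0 + 1.5, rtol=1e-12)
        np.testing.assert_allclose(sig, 0.1 + EPS0 * 3.0 / (2 * tau), rtol=1e-12)

    def test_debye_matches_complex_oracle(self):
        p = DispersionParams("debye", 4.0, 3.0, 13e-12, 0.1)
        eps, sig = debye_eval(p, 6.0)
        eps_o, sig_o = complex_oracle(p, 6.0)
        np.testing.assert_allclose(eps, eps_o, rtol=1e-12)
        np.testing.assert_allclose(sig, sig_o, rtol=1e-12)

    def test_cole_cole_alpha_zero_reduces_to_debye(self):
        d = DispersionParams("debye", 7.0, 45.0, 10e-12, 0.7)
        c = DispersionParams("cole_cole", 7.0, 45.0, 10e-12, 0.7, alpha=0.0)
        for f in frequency_grid()[::100]:
            np.testing.assert_allclose(
                cole_cole_eval(c, f), debye_eval(d, f), rtol=1e-12
            )

    def test_cole_cole_matches_complex_power_oracle(self):
        p = DispersionParams("cole_cole", 6.749, 50.09, 10.5e-12, 0.794,
                             alpha=0.1)
        eps, sig = cole_cole_eval(p, 5.0)
        eps_o, sig_o = complex_oracle(p, 5.0)
        np.testing.assert_allclose((eps, sig), (eps_o, sig_o), rtol=1e-12)

    def test_permittivity_decreasing_in_band(self):
        p = DispersionParams("cole_cole", 6.749, 50.09, 10.5e-12, 0.794,
                             alpha=0.051)
        eps, _ = cole_cole_eval(p, frequency_grid())
        assert (np.diff(eps) < 0).all()

    def test_random_parameter_sets_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = DispersionParams(
                "cole_cole",
                eps_inf=1 + 20 * rng.random(),
                delta_eps=60 * rng.random(),
                tau=(5 + 15 * rng.random()) * 1e-12,
                sigma_s=rng.random(),
                alpha=0.3 * rng.random(),
            )
            f = float(rng.choice(frequency_grid()))
            np.testing.assert_allclose(
                cole_cole_eval(p, f), complex_oracle(p, f), rtol=1e-12
            )

    def test_model_mismatch_rejected(self):
        p = DispersionParams("debye", 4.0, 3.0, 13e-12, 0.1)
        with pytest.raises(ParameterError):
            cole_cole_eval(p, 6.0)


class TestColeToDebye:
    def test_alpha_zero_fixed_point(self):
        p = DispersionParams("cole_cole", 10.0, 30.0, 12e-12, 0.5, alpha=0.0)
        q = cole_to_debye(p)
        np.testing.assert_allclose(
            [q.eps_inf, q.delta_eps, q.tau, q.sigma_s],
            [10.0, 30.0, 12e-12, 0.5],
            rtol=1e-6,
        )

    def test_malignant_like_fit_within_5_percent(self):
        p = DispersionParams("cole_cole", 6.749, 50.09, 10.5e-12, 0.794,
                             alpha=0.1)
        q = cole_to_debye(p)
        grid = frequency_grid()
        eps_c, sig_c = cole_cole_eval(p, grid)
        eps_d, sig_d = debye_eval(q, grid)
        assert np.max(np.abs(eps_d - eps_c) / eps_c) < 0.05
        assert np.max(np.abs(sig_d - sig_c) / sig_c) < 0.05

    def test_residual_stable_under_grid_subsampling(self):
        p = DispersionParams("cole_cole", 6.749, 50.09, 10.5e-12, 0.794,
                             alpha=0.051)
        grid = frequency_grid()

        def rms(q, g):
            eps_c, sig_c = cole_cole_eval(p, g)
            eps_d, sig_d = debye_eval(q, g)
            res = np.concatenate([(eps_d - eps_c) / eps_c,
                                  (sig_d - sig_c) / sig_c])
            return float(np.sqrt(np.mean(res ** 2)))

        r_full = rms(cole_to_debye(p, grid), grid)
        r_half = rms(cole_to_debye(p, grid[::2]), grid[::2])
        assert abs(r_full - r_half) <= 0.1 * max(r_full, r_half)


class TestBoundCurves:
    def test_five_percent_band_exact(self):
        nominal = DispersionParams("debye", 15.93, 23.83, 13e-12, 0.831)
        lower, upper = build_bound_curves(nominal, 0.05)
        for f in frequency_grid()[::50]:
            eps_n, sig_n = debye_eval(nominal, f)
            eps_u, sig_u = upper(f)
            eps_l, sig_l = lower(f)
            np.testing.assert_allclose(eps_u / eps_n, 1.05, rtol=1e-12)
            np.testing.assert_allclose(sig_u / sig_n, 1.05, rtol=1e-12)
            np.testing.assert_allclose(eps_l / eps_n, 0.95, rtol=1e-12)
            np.testing.assert_allclose(sig_l / sig_n, 0.95, rtol=1e-12)

    def test_zero_fraction_collapses(self):
        nominal = DispersionParams("debye", 4.0, 3.0, 13e-12, 0.1)
        lower, upper = build_bound_curves(nominal, 0.0)
        assert lower(6.0) == upper(6.0) == debye_eval(nominal, 6.0)

    def test_ordering_and_validation(self):
        nominal = DispersionParams("debye", 4.0, 3.0, 13e-12, 0.1)
        lower, upper = build_bound_curves(nominal, 0.05)
        eps_l, _ = lower(6.0)
        eps_n, _ = debye_eval(nominal, 6.0)
        eps_u, _ = upper(6.0)
        assert eps_l < eps_n < eps_u
        with pytest.raises(ParameterError):
            build_bound_curves(nominal, 1.0)


class TestIntensityMapping:
    def test_endpoints_and_midpoint(self):
        assert map_intensity_to_property(0.2, 0.2, 0.8, 10.0, 20.0) == 10.0
        assert map_intensity_to_property(0.8, 0.2, 0.8, 10.0, 20.0) == 20.0
        assert map_intensity_to_property(0.5, 0.2, 0.8, 10.0, 20.0) == 15.0

    def test_degenerate_range_returns_midpoint(self):
        assert map_intensity_to_property(0.5, 0.5, 0.5, 10.0, 20.0) == 15.0

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            v = map_intensity_to_property(0.9, 0.2, 0.8, 10.0, 20.0)
        assert v == 20.0


class TestGeneratePropertyMaps:
    def _inputs(self):
        labels = np.zeros((4, 4, 8), dtype=np.int16)
        labels[:, :, 0:2] = -2   # skin
        labels[:, :, 2:4] = 6    # fat median
        labels[:, :, 4:6] = 2    # fibroglandular median
        labels[:, :, 6:8] = -3   # malignant
        rng = np.random.default_rng(0)
        W = rng.random(labels.shape)
        return Volume3D(labels), Volume3D(W)

    def test_off_grid_frequency_rejected(self):
        labels, W = self._inputs()
        with pytest.raises(FrequencyGridError):
            generate_property_maps(labels, W, f_ghz=2.5)

    def test_voxelwise_scalar_oracle(self):
        labels, W = self._inputs()
        table = TissueCurveTable.default()
        maps = generate_property_maps(labels, W, table, 6.0)
        # straight-line scalar recomputation per voxel
        from mwibreast.dielectrics import _label_envelope
        for lab in (-2, 6, 2, -3):
            sel = labels.data == lab
            (el, sl), (eu, su) = _label_envelope(lab, table, 6.0, "detailed")
            w = W.data[sel]
            i_min, i_max = w.min(), w.max()
            t = (w - i_min) / (i_max - i_min)
            np.testing.assert_allclose(
                maps.permittivity.data[sel], el + t * (eu - el), rtol=1e-12
            )
            np.testing.assert_allclose(
                maps.conductivity.data[sel], sl + t * (su - sl), rtol=1e-12
            )

    def test_background_is_free_space(self):
        labels = Volume3D(np.zeros((3, 3, 3), dtype=np.int16))
        W = Volume3D(np.random.default_rng(1).random((3, 3, 3)))
        maps = generate_property_maps(labels, W, f_ghz=6.0)
        assert (maps.permittivity.data == 1.0).all()
        assert (maps.conductivity.data == 0.0).all()

    def test_constant_intensity_class_gets_midpoint(self):
        labels = np.full((3, 3, 3), -2, dtype=np.int16)  # all skin
        W = Volume3D(np.full((3, 3, 3), 0.4))
        table = TissueCurveTable.default()
        maps = generate_property_maps(Volume3D(labels), W, table, 6.0)
        eps_n, _ = debye_eval(table.curve("skin"), 6.0)
        np.testing.assert_allclose(maps.permittivity.data, eps_n, rtol=1e-12)

    def test_monotone_in_water_intensity_within_class(self):
        labels, W = self._inputs()
        maps = generate_property_maps(labels, W, f_ghz=6.0)
        for lab in (-2, 6, 2, -4, 1, 3, 5, 7, -1, 4):
            sel = labels.data == lab
            if not sel.any():
                continue
            order = np.argsort(W.data[sel])
            eps_sorted = maps.permittivity.data[sel][order]
            sig_sorted = maps.conductivity.data[sel][order]
            assert (np.diff(eps_sorted) >= -1e-12).all()
            assert (np.diff(sig_sorted) >= -1e-12).all()

    def test_unknown_label_rejected(self):
        labels = Volume3D(np.full((2, 2, 2), 9, dtype=np.int16))
        W = Volume3D(np.zeros((2, 2, 2)))
        with pytest.raises(TableError):
            generate_property_maps(labels, W, f_ghz=6.0)

    def test_properties_physical_for_all_tissues(self):
        table = TissueCurveTable.default()
        grid = frequency_grid()[::70]
        from mwibreast.dielectrics import eval_dispersion
        for name, p in table.params.items():
            for f in grid:
                eps, sig = eval_dispersion(p, f)
                assert eps >= 1.0 and sig >= 0.0

    def test_fat_below_fibroglandular_everywhere(self):
        table = TissueCurveTable.default()
        from mwibreast.dielectrics import eval_dispersion
        for f in frequency_grid()[::35]:
            fat_hi, _ = eval_dispersion(table.curve("fat_high"), f)
            fib_lo, _ = eval_dispersion(table.curve("fibroglandular_low"), f)
            assert fat_hi < fib_lo
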