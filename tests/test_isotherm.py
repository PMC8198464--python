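"""Isotherm thermodynamics: modulus, phases, A_EXT, transitions, shifts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from langmuir_workbench import (
    AVOGADRO,
    Isotherm,
    IsothermError,
    IsothermModelParams,
    PlateauInversionError,
    analyze,
    classify_phase,
    compression_modulus,
    detect_transitions,
    extrapolated_area,
    generate_isotherm,
    isotherm_shift,
    mean_molecular_area,
    model_pressure,
    presets,
    smooth_isotherm,
)


class TestCompressionModulus:
    def test_linear_isotherm(self):
        a = np.linspace(2.0, 0.4, 81)  # grid contains A = 1.2 exactly
        curve = compression_modulus(Isotherm(area=a, pressure=10.0 - 5.0 * a))
        # Cs^-1 = -A * (-5) = 5A; at A = 1.2 that is 6.0
        i = np.argmin(np.abs(a - 1.2))
        assert curve.modulus[i] == pytest.approx(6.0, rel=1e-12)
        np.testing.assert_allclose(curve.modulus, 5.0 * a, rtol=1e-10)

    def test_ideal_gas_modulus_equals_pressure(self):
        # pi = c/A  =>  Cs^-1 = -A(-c/A^2) = c/A = pi, over a decade of c
        a = np.linspace(0.5, 2.0, 6000)
        for c in (1.0, 3.0, 10.0):
            curve = compression_modulus(Isotherm(area=a, pressure=c / a))
            np.testing.assert_allclose(
                curve.modulus[5:-5], curve.pressure[5:-5], rtol=1e-6
            )

    def test_quadratic_isotherm_matches_analytic_derivative(self):
        a = np.linspace(1.0, 0.4, 301)  # grid contains A = 0.5 exactly
        curve = compression_modulus(Isotherm(area=a, pressure=50.0 * (1 - a) ** 2))
        expected = 100.0 * a * (1 - a)  # -A * d/dA[50(1-A)^2]
        np.testing.assert_allclose(curve.modulus[1:-1], expected[1:-1], rtol=1e-9)
        i = np.argmin(np.abs(a - 0.5))
        assert curve.modulus[i] == pytest.approx(25.0, rel=1e-9)

    def test_boundary_points_one_sided(self):
        a = np.linspace(1.0, 0.5, 10)
        curve = compression_modulus(Isotherm(area=a, pressure=8.0 - 4.0 * a))
        assert curve.modulus[0] == pytest.approx(4.0 * a[0])
        assert curve.modulus[-1] == pytest.approx(4.0 * a[-1])


class TestPhaseClassification:
    @pytest.mark.parametrize(
        "modulus, label",
        [
            (5.0, "G/LE-gas"),
            (12.5, "LE"),
            (30.0, "LE"),
            (49.999, "LE"),
            (50.0, "L"),
            (99.999, "L"),
            (100.0, "LC"),
            (150.0, "LC"),
            (250.0, "LC"),
            (250.1, "S"),
            (-3.0, "unstable/artifact"),
        ],
    )
    def test_davies_rideal_breakpoints(self, modulus, label):
        assert classify_phase(modulus) == label

    @given(st.floats(min_value=-1e4, max_value=1e4))
    def test_total_with_exactly_six_outputs(self, m):
        assert classify_phase(m) in {
            "G/LE-gas", "LE", "L", "LC", "S", "unstable/artifact",
        }

    def test_nonfinite_rejected(self):
        with pytest.raises(IsothermError):
            classify_phase(np.nan)


class TestMeanMolecularArea:
    def test_against_hand_calculation(self):
        # 30 uL of a 1 mM DPPC solution: 3e-8 mol -> 1.807e16 molecules
        conc = 1e-3 * 734.039  # mg/mL equivalent of 1 mM
        n = 30 * conc * 1e-6 / 734.039 * AVOGADRO
        assert n == pytest.approx(1.8066e16, rel=1e-4)
        a = mean_molecular_area(273.0, 30.0, conc, x_w=0.0)
        assert a == pytest.approx(273.0e14 / n, rel=1e-12)

    def test_linearity_in_trough_area(self):
        a1 = mean_molecular_area(273.0, 30.0, 0.734, 0.0)
        a2 = mean_molecular_area(136.5, 30.0, 0.734, 0.0)
        assert a2 == pytest.approx(a1 / 2)

    def test_nanoparticle_mass_excluded(self):
        a0 = mean_molecular_area(273.0, 30.0, 0.734, x_w=0.0)
        a5 = mean_molecular_area(273.0, 30.0, 0.734, x_w=0.5)
        assert a5 == pytest.approx(2 * a0)

    def test_no_phospholipid_rejected(self):
        with pytest.raises(IsothermError):
            mean_molecular_area(273.0, 30.0, 0.734, x_w=1.0)


class TestSmoothing:
    def test_reproduces_quadratic_exactly(self):
        a = np.linspace(1.0, 0.4, 80)
        iso = Isotherm(area=a, pressure=3.0 + 2.0 * a + 5.0 * a**2)
        sm = smooth_isotherm(iso, window=11, polyorder=2)
        np.testing.assert_allclose(sm.pressure, iso.pressure, atol=1e-10)
        np.testing.assert_array_equal(sm.area, iso.area)

    def test_minimal_window_identity_on_linear_data(self):
        a = np.linspace(1.0, 0.4, 40)
        iso = Isotherm(area=a, pressure=6.0 - 4.0 * a)
        sm = smooth_isotherm(iso, window=3, polyorder=1)
        np.testing.assert_allclose(sm.pressure, iso.pressure, atol=1e-10)

    def test_reduces_noise_on_synthetic_isotherm(self):
        iso = generate_isotherm(presets.DPPC_ISOTHERM, noise_sd=0.05, seed=1)
        truth = model_pressure(presets.DPPC_ISOTHERM, iso.area)
        sm = smooth_isotherm(iso, window=11, polyorder=3)
        assert np.std(sm.pressure - truth) < 0.6 * np.std(iso.pressure - truth)

    def test_window_validation(self):
        iso = generate_isotherm(presets.DPPC_ISOTHERM, n_points=50, noise_sd=0.0)
        with pytest.raises(IsothermError):
            smooth_isotherm(iso, window=51)
        with pytest.raises(IsothermError):
            smooth_isotherm(iso, window=4, polyorder=1)
        with pytest.raises(IsothermError):
            smooth_isotherm(iso, window=3, polyorder=3)


class TestExtrapolatedArea:
    def test_exact_linear_branch_any_window(self):
        a = np.linspace(1.0, 0.5, 100)
        iso = Isotherm(area=a, pressure=20.0 * (0.9 - a) * (a < 0.9))
        for window in [(1.0, 4.0), (2.0, 7.0), (0.5, 6.5)]:
            res = extrapolated_area(iso, fit_window=window)
            assert res.a_ext == pytest.approx(0.9, abs=1e-9)

    def test_default_window_matches_continuous_chord_formula(self, dppc_isotherm):
        # least-squares line through the quadratic LE branch over
        # pi in [0.3, 0.9] pi_C: zero crossing at x0 = s/6 + q/(3s) in the
        # normalised coordinate x = (A_lift - A)/(A_lift - A_C)
        x1, x2 = np.sqrt(0.3), np.sqrt(0.9)
        s, q = x1 + x2, x1 * x2
        expected = 1.02 - 0.25 * (s / 6 + q / (3 * s))
        res = extrapolated_area(dppc_isotherm, onset_pressure=5.0)
        assert res.a_ext == pytest.approx(expected, abs=2e-3)
        assert res.r_squared > 0.99

    def test_window_anchored_at_onset_approaches_tangent_value(self, dppc_isotherm):
        # narrow window just below the plateau onset ~ tangent at A_C,
        # which crosses zero at 0.895 nm^2
        res = extrapolated_area(dppc_isotherm, fit_window=(4.5, 4.995))
        assert res.a_ext == pytest.approx(0.895, abs=5e-3)

    def test_positive_slope_rejected(self):
        a = np.linspace(1.0, 0.5, 50)
        iso = Isotherm(area=a, pressure=np.linspace(8.0, 0.0, 50))
        # reversed mapping: pressure increases with area
        with pytest.raises(IsothermError):
            extrapolated_area(iso, fit_window=(1.0, 7.0))

    def test_sparse_window_flagged(self, dppc_isotherm):
        res = extrapolated_area(dppc_isotherm, fit_window=(4.8, 4.999))
        assert any("points" in f for f in res.flags)

    def test_unreachable_window_rejected(self, dppc_isotherm):
        with pytest.raises(IsothermError):
            extrapolated_area(dppc_isotherm, fit_window=(10.0, 80.0))


class TestTransitionDetection:
    def test_dppc_plateau_onset(self, dppc_isotherm):
        curve, rep = analyze(dppc_isotherm)
        assert rep.a_c == pytest.approx(0.77, rel=0.01)
        assert rep.pi_c == pytest.approx(5.0, rel=0.01)
        assert rep.max_modulus_le == pytest.approx(30.8, rel=0.05)
        assert rep.max_modulus_lc == pytest.approx(0.55 * 250.0, rel=0.05)
        assert rep.a_ext is not None and rep.a_ext >= rep.a_c

    @pytest.mark.parametrize(
        "name, onset", [("fe3o4_s", 12.0), ("fe3o4_as", 10.0)]
    )
    def test_binary_film_onsets(self, name, onset):
        iso = generate_isotherm(presets.ISOTHERM_SCENARIOS[name], noise_sd=0.0)
        _, rep = analyze(iso)
        assert rep.pi_c == pytest.approx(onset, rel=0.01)

    def test_linear_isotherm_reports_no_transition(self, linear_isotherm):
        rep = detect_transitions(linear_isotherm)
        assert not rep.has_transition
        assert rep.pi_c is None and rep.pi_c_prime is None
        # A_EXT is still available by tangent extrapolation
        assert rep.a_ext == pytest.approx(1.0, abs=1e-6)

    def test_tilted_plateau_reports_entry_and_exit(self):
        params = IsothermModelParams(1.02, 0.77, 5.0, 0.55, plateau_tilt=2.0)
        _, rep = analyze(generate_isotherm(params, noise_sd=0.0))
        assert rep.pi_c_prime == pytest.approx(5.0, rel=0.01)
        assert rep.pi_c_double_prime == pytest.approx(7.0, rel=0.01)
        assert rep.pi_c_prime < rep.pi_c_double_prime

    def test_near_horizontal_plateau_collapses_to_single_point(self):
        params = IsothermModelParams(1.02, 0.77, 5.0, 0.55, plateau_tilt=0.1)
        _, rep = analyze(generate_isotherm(params, noise_sd=0.0))
        assert rep.has_transition
        assert rep.pi_c_double_prime is None

    def test_phase_map_follows_modulus(self, dppc_isotherm):
        _, rep = analyze(dppc_isotherm)
        assert rep.phase_at(3.0) == "LE"
        assert rep.phase_at(5.2) == "G/LE-gas"  # inside the coexistence dip
        assert rep.phase_at(20.0) == "LC"

    def test_closed_loop_parameter_grid_noise_free(self):
        """Transition recovery within 1% over >= 20 parameter sets."""
        n_sets = 0
        for a_c in (0.70, 0.77, 0.85):
            for pi_c in (4.0, 8.0, 12.0):
                for tilt in (0.8, 1.6):
                    for le in (0.0, 0.15):
                        params = IsothermModelParams(
                            1.02, a_c, pi_c, 0.50,
                            plateau_tilt=tilt, le_shift=le,
                        )
                        iso = generate_isotherm(params, noise_sd=0.0)
                        _, rep = analyze(iso)
                        n_sets += 1
                        assert rep.a_c == pytest.approx(a_c + le, rel=0.01)
                        assert rep.pi_c == pytest.approx(pi_c, rel=0.01)
                        assert rep.pi_c_prime == pytest.approx(pi_c, rel=0.01)
        assert n_sets >= 20

    def test_closed_loop_noisy_after_smoothing(self):
        """Recovery within 5% at noise sd 0.05 mN/m after smoothing."""
        for name, a_c, pi_c in (
            ("dppc", 0.77, 5.0),
            ("fe3o4_s", 0.96, 12.0),
            ("fe3o4_as", 0.91, 10.0),
        ):
            for seed in (0, 1):
                iso = generate_isotherm(
                    presets.ISOTHERM_SCENARIOS[name], noise_sd=0.05, seed=seed
                )
                _, rep = analyze(iso, smooth_window=21)
                assert rep.a_c == pytest.approx(a_c, rel=0.05)
                assert rep.pi_c == pytest.approx(pi_c, rel=0.05)


class TestIsothermShift:
    def test_self_shift_is_zero(self, dppc_isotherm):
        assert isotherm_shift(dppc_isotherm, dppc_isotherm, 30.0) == 0.0

    def test_antisymmetry(self, dppc_isotherm):
        other = generate_isotherm(presets.FE3O4_AS_DPPC_036, noise_sd=0.0)
        fwd = isotherm_shift(other, dppc_isotherm, 30.0)
        assert isotherm_shift(dppc_isotherm, other, 30.0) == pytest.approx(-fwd)

    def test_s_film_shifted_to_smaller_areas_at_high_pressure(self, dppc_isotherm):
        # on the condensed branch the S film sits at
        # lc_shift + (pi'_C,S - pi_C,DPPC)/k_LC = -0.05 + 7/250 = -0.022 nm^2
        s_film = generate_isotherm(presets.FE3O4_S_DPPC_036, noise_sd=0.0)
        expected = -0.05 + (12.5 - 5.5) / 250.0
        got = isotherm_shift(s_film, dppc_isotherm, 30.0)
        assert got == pytest.approx(expected, abs=1e-6)
        assert got < 0

    def test_as_film_remains_shifted_to_greater_areas(self, dppc_isotherm):
        as_film = generate_isotherm(presets.FE3O4_AS_DPPC_036, noise_sd=0.0)
        assert isotherm_shift(as_film, dppc_isotherm, 30.0) > 0

    def test_plateau_pressure_raises_naming_bounds(self, dppc_isotherm):
        with pytest.raises(PlateauInversionError) as err:
            isotherm_shift(dppc_isotherm, dppc_isotherm, 5.2)
        assert err.value.lower <= 5.2 <= err.value.upper

    def test_pressure_out_of_range_rejected(self, dppc_isotherm):
        with pytest.raises(IsothermError):
            isotherm_shift(dppc_isotherm, dppc_isotherm, 80.0)


class TestIsothermContainer:
    def test_increasing_input_reversed_into_compression_order(self):
        a = np.linspace(0.5, 1.0, 20)
        iso = Isotherm(area=a, pressure=10.0 * (1.0 - a))
        assert iso.area[0] == 1.0 and np.all(np.diff(iso.area) < 0)

    def test_too_short_and_non_monotone_rejected(self):
        with pytest.raises(IsothermError):
            Isotherm(area=np.linspace(1, 0.5, 5), pressure=np.zeros(5))
        a = np.linspace(1.0, 0.5, 20)
        a[10] = a[9]
        with pytest.raises(IsothermError):
            Isotherm(area=a, pressure=np.zeros(20))

    def test_large_negative_pressure_rejected(self):
        a = np.linspace(1.0, 0.5, 20)
        p = np.zeros(20)
        p[3] = -1.0
        with pytest.raises(IsothermError):
            Isotherm(area=a, pressure=p)
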