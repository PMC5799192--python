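"""Annular profiles, the force-balance model and the scaling-law fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ciliaswirl as cs
from ciliaswirl.synthetic import expected_sin_alpha


def tuft_ring(n=200, radius=100.0, beat="tangential", area=10.0):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    if beat == "tangential":
        d = theta + np.pi / 2
    elif beat == "radial":
        d = theta
    else:
        d = np.full(n, beat)
    return pd.DataFrame(
        {
            "x_um": radius * np.cos(theta),
            "y_um": radius * np.sin(theta),
            "beat_dir_rad": np.mod(d, 2 * np.pi),
            "area_um2": area,
        }
    )


valid_params = st.builds(
    cs.ModelParams,
    V_R=st.floats(0.0, 1e-4),
    phi=st.floats(0.01, 0.5),
    n_c=st.floats(10, 500),
    f_c=st.floats(1e-13, 1e-11),
    A_cc=st.floats(1e-11, 1e-9),
    eta_pc=st.floats(1e-3, 1e-1),
    e=st.floats(1e-7, 1e-5),
)


class TestAnnularProfile:
    def test_tangential_beats_give_unit_order(self):
        prof = cs.annular_profile(tuft_ring(beat="tangential"), (0, 0), dr=50)
        assert np.allclose(prof["sin_alpha_r"], 1.0)

    def test_radial_beats_give_zero_order(self):
        prof = cs.annular_profile(tuft_ring(beat="radial"), (0, 0), dr=50)
        assert np.allclose(prof["sin_alpha_r"], 0.0, atol=1e-12)

    def test_force_proxy_is_exact_product(self):
        gt = cs.SwirlGroundTruth()
        tufts = cs.generate_swirl_tufts(gt, 5000, seed=0)
        prof = cs.annular_profile(tufts, (0, 0), dr=30)
        assert np.allclose(prof["force_proxy"],
                           prof["nu_r"] * prof["sin_alpha_r"], rtol=0)

    def test_affine_density_recovered_within_two_se(self):
        gt = cs.SwirlGroundTruth(
            center=(0, 0), radius=300.0, density_intercept=0.05,
            density_slope=1.5e-3,
            tangential_concentration=lambda r: 2 + 0.02 * np.asarray(r, float),
            omega=0.1,
        )
        tufts = cs.generate_swirl_tufts(gt, 10_000, seed=1)
        prof = cs.annular_profile(tufts, (0, 0), dr=20, r_max=300)
        fit = cs.LinearFit.from_xy(prof["r_mid_um"], prof["nu_r"])
        assert abs(fit.slope - gt.density_slope) <= 2 * fit.stderr_slope
        assert abs(fit.intercept - gt.density_intercept) <= 2 * fit.stderr_intercept

    def test_sin_alpha_blind_to_direction_sign(self):
        tufts = tuft_ring(beat=1.234)
        flipped = tufts.assign(
            beat_dir_rad=np.mod(tufts["beat_dir_rad"] + np.pi, 2 * np.pi)
        )
        a = cs.annular_profile(tufts, (0, 0), dr=50)
        b = cs.annular_profile(flipped, (0, 0), dr=50)
        assert np.allclose(a["sin_alpha_r"], b["sin_alpha_r"], atol=1e-12)

    def test_rotation_invariance_about_center(self):
        gt = cs.SwirlGroundTruth()
        tufts = cs.generate_swirl_tufts(gt, 3000, seed=2)
        rot = 0.7
        c, s = np.cos(rot), np.sin(rot)
        rotated = tufts.assign(
            x_um=tufts.x_um * c - tufts.y_um * s,
            y_um=tufts.x_um * s + tufts.y_um * c,
            beat_dir_rad=np.mod(tufts.beat_dir_rad + rot, 2 * np.pi),
        )
        a = cs.annular_profile(tufts, (0, 0), dr=30, r_max=300)
        b = cs.annular_profile(rotated, (0, 0), dr=30, r_max=300)
        assert np.allclose(a["nu_r"], b["nu_r"], atol=1e-9)
        assert np.allclose(a["sin_alpha_r"], b["sin_alpha_r"], atol=1e-9)

    def test_empty_table_rejected_and_far_center_warns(self):
        with pytest.raises(ValueError):
            cs.annular_profile(pd.DataFrame(columns=["x_um", "y_um",
                                                     "beat_dir_rad", "area_um2"]),
                               (0, 0))
        with pytest.warns(UserWarning):
            cs.annular_profile(tuft_ring(), (10_000.0, 0.0), dr=50, r_max=100)


class TestForceProxyFit:
    def test_constructed_affine_profile_recovered_exactly(self):
        r = np.arange(10.0, 210.0, 20.0)
        prof = pd.DataFrame(
            {"r_mid_um": r, "nu_r": 0.05 + 0.001 * r, "sin_alpha_r": 1.0,
             "n_tufts": 100, "force_proxy": 0.05 + 0.001 * r}
        )
        fit = cs.force_proxy_fit(prof)
        assert fit.slope == pytest.approx(0.001, abs=1e-12)
        assert fit.intercept == pytest.approx(0.05, abs=1e-10)

    def test_constant_profile_zero_slope(self):
        r = np.arange(10.0, 110.0, 20.0)
        prof = pd.DataFrame({"r_mid_um": r, "nu_r": 0.3, "sin_alpha_r": 0.5,
                             "n_tufts": 50, "force_proxy": 0.15})
        assert cs.force_proxy_fit(prof).slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_annuli_rejected(self):
        prof = pd.DataFrame({"r_mid_um": [10.0, 30.0], "force_proxy": [0.1, 0.2]})
        with pytest.raises(ValueError):
            cs.force_proxy_fit(prof)


class TestModelOperations:
    def test_printed_parameters_give_forty_microns_per_second(self):
        p = cs.ModelParams(V_R=0.0)
        assert abs(cs.model_slope(p) - 4e-5) / 4e-5 < 1e-12

    def test_propulsive_stress_defaults(self):
        p = cs.ModelParams(V_R=0.0)
        assert cs.propulsive_stress(p, 0.0) == 0.0
        assert cs.propulsive_stress(p, 1.0) == pytest.approx(0.2)
        assert cs.propulsive_stress(p, 0.5) == pytest.approx(
            0.5 * cs.propulsive_stress(p, 1.0)
        )

    def test_friction_stress_values(self):
        p = cs.ModelParams(V_R=0.0)
        assert cs.friction_stress(p, 0.0) == 0.0
        assert cs.friction_stress(p, 4e-5) == pytest.approx(0.2)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(params=valid_params, nu=st.floats(0.0, 1.0))
    def test_exact_vs_approx_friction_gap_is_phi_nu(self, params, nu):
        exact = cs.friction_stress(params, 1e-5, nu, exact=True)
        approx = cs.friction_stress(params, 1e-5, nu, exact=False)
        assert (approx - exact) / approx == pytest.approx(params.phi * nu,
                                                          abs=1e-12)

    def test_doubling_fc_doubles_slope(self):
        p = cs.ModelParams(V_R=0.0)
        p2 = cs.ModelParams(V_R=0.0, f_c=2 * p.f_c)
        assert cs.model_slope(p2) == pytest.approx(2 * cs.model_slope(p))

    def test_slope_times_friction_coefficient_equals_unit_stress(self):
        p = cs.ModelParams(V_R=0.0)
        assert cs.model_slope(p) * p.eta_pc / p.e == pytest.approx(
            cs.propulsive_stress(p, 1.0)
        )

    def test_onset_proxy_gives_zero_velocity(self):
        p = cs.ModelParams(V_R=1e-5)
        onset = p.V_R / cs.model_slope(p)
        v, below = cs.steady_velocity(p, onset)
        assert v == pytest.approx(0.0, abs=1e-18)
        v2, below2 = cs.steady_velocity(p, onset / 2)
        assert v2 == 0.0 and below2

    def test_zero_recovery_full_proxy_gives_model_slope(self):
        p = cs.ModelParams(V_R=0.0)
        v, below = cs.steady_velocity(p, 1.0)
        assert v == pytest.approx(cs.model_slope(p)) and not below

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(params=valid_params, proxy=st.floats(0.0, 1.0))
    def test_force_balance_roundtrip(self, params, proxy):
        v, below = cs.steady_velocity(params, proxy)
        if below:
            return
        prop = cs.propulsive_stress(params, proxy)
        fric = cs.friction_stress(params, v)
        assert abs(prop - fric) <= 1e-12 * max(prop, fric)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cs.ModelParams(V_R=0.0, phi=1.5)
        with pytest.raises(ValueError):
            cs.ModelParams(V_R=-1.0)
        with pytest.raises(ValueError):
            cs.ModelParams(V_R=0.0, eta_pc=0.0)


class TestVelocityForceFit:
    def test_constructed_affine_relation_recovered_exactly(self):
        proxy = np.linspace(0.2, 0.6, 8)
        prof = pd.DataFrame(
            {"r_mid_um": np.arange(8.0), "nu_r": proxy, "sin_alpha_r": 1.0,
             "n_tufts": 100, "force_proxy": proxy,
             "V_um_s": 40.0 * proxy - 5.0}
        )
        fit, vr = cs.fit_velocity_force(prof)
        assert fit.slope == pytest.approx(40.0, abs=1e-10)
        assert vr == pytest.approx(5.0, abs=1e-10)

    def test_proportional_relation_gives_zero_recovery_speed(self):
        proxy = np.linspace(0.1, 0.5, 6)
        prof = pd.DataFrame({"r_mid_um": np.arange(6.0), "force_proxy": proxy,
                             "V_um_s": 12.0 * proxy})
        fit, vr = cs.fit_velocity_force(prof)
        assert vr == pytest.approx(0.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        prof = pd.DataFrame({"force_proxy": [0.1, 0.2], "V_um_s": [1.0, 2.0],
                             "r_mid_um": [10.0, 30.0]})
        with pytest.raises(ValueError):
            cs.fit_velocity_force(prof)

    def test_end_to_end_slope_recovery_at_study_size(self):
        """Swirl built to obey the force balance: slope ratio in [0.9, 1.1]
        at 1e4 tufts and 200 beads."""
        gt = cs.SwirlGroundTruth(
            center=(0, 0), radius=300.0, density_intercept=0.12,
            density_slope=1.8e-3,
            tangential_concentration=lambda r: 2 + 0.03 * np.asarray(r, float),
            omega=0.1,
        )
        S, V_R = 40.0, 4.0
        tufts, beads = cs.generate_model_consistent_swirl(
            gt, S, V_R, n_tufts=10_000, n_beads=200, seed=1
        )
        prof = cs.annular_profile(tufts, (0, 0), dr=20, r_max=300)
        vel = cs.velocity_profile(beads, (0, 0), 20, r_max=300)
        fit, vr = cs.fit_velocity_force(cs.attach_velocity(prof, vel))
        assert 0.9 <= fit.slope / S <= 1.1


class TestPowerLaw:
    def test_noiseless_exponent_exact(self):
        nu = np.logspace(-3, 0, 20)
        data = pd.DataFrame({"nu": nu, "R_um": 5e3 * nu**2})
        res = cs.fit_power_law(data)
        assert res.exponent == pytest.approx(2.0, abs=1e-12)

    def test_three_decades_beat_one_decade_precision(self):
        ses = {}
        for decades, lo in [(1, 0.1), (3, 1e-3)]:
            se = []
            for seed in range(10):
                df = cs.generate_scaling_dataset(
                    prefactor=3e4, exponent=1.5, n=30, log_noise_sigma=0.15,
                    nu_range=(lo, 1.0), seed=seed,
                )
                se.append(cs.fit_power_law(df).stderr_exponent)
            ses[decades] = np.mean(se)
        assert ses[3] < ses[1]

    def test_noisy_recovery_within_two_se(self):
        df = cs.generate_scaling_dataset(prefactor=3e4, exponent=1.5, n=30,
                                         log_noise_sigma=0.15,
                                         nu_range=(1e-3, 1.0), seed=5)
        res = cs.fit_power_law(df)
        assert abs(res.exponent - 1.5) <= 2 * res.stderr_exponent

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            cs.fit_power_law(pd.DataFrame({"nu": [0.1, -0.2, 0.3],
                                           "R_um": [1.0, 2.0, 3.0]}))

    def test_largest_swirl_per_chamber_selected(self):
        nu = np.array([0.1, 0.1, 0.4, 0.4, 0.8, 0.8])
        R = 1e3 * nu  # exact law on the larger of each pair
        data = pd.DataFrame({"nu": nu, "R_um": np.where(np.arange(6) % 2, R, R / 7),
                             "chamber": [0, 0, 1, 1, 2, 2]})
        res = cs.fit_power_law(data)
        assert res.exponent == pytest.approx(1.0, abs=1e-12)
        assert res.log10_prefactor == pytest.approx(3.0, abs=1e-12)


def test_estimate_swirl_center_recovers_truth():
    gt = cs.SwirlGroundTruth(
        center=(40.0, -25.0), radius=250.0, density_intercept=0.2,
        density_slope=1e-3,
        tangential_concentration=lambda r: np.full_like(np.asarray(r, float), 8.0),
        omega=0.1,
    )
    tufts = cs.generate_swirl_tufts(gt, 5000, seed=3)
    cx, cy = cs.estimate_swirl_center(tufts)
    assert np.hypot(cx - 40.0, cy + 25.0) < 15.0
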