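"""Contact-mechanics forward models and force-curve fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellmech.mechanics import (
    BECSpec,
    ContactNotFoundError,
    ForceCurve,
    InsufficientDataError,
    PLRParameters,
    TipGeometry,
    bec_factor,
    detect_contact_point,
    fit_hertz,
    fit_plr,
    hertz_force,
    plr_relaxation,
    ting_force,
)
from cellmech.synth import make_force_curve

from conftest import triangular_trajectory


class TestBECFactor:
    def test_zero_indentation_is_one(self, micron_tip):
        assert bec_factor(0.0, BECSpec(thickness=1e-6), micron_tip) == 1.0

    def test_thick_sample_limit_is_one(self, micron_tip):
        assert bec_factor(1e-6, BECSpec(thickness=np.inf), micron_tip) == 1.0

    def test_default_series_at_chi_01(self):
        # chi = sqrt(R*delta)/h = 0.1 with the bonded-sphere coefficients:
        # 1 + 1.133*0.1 + 1.497*0.01 + 1.469*1e-3 + 0.755*1e-4 = 1.12985...
        geom = TipGeometry(radius=1e-6)
        spec = BECSpec(thickness=1e-6)   # delta=1e-8 -> chi = 0.1
        expected = 1 + 1.133e-1 + 1.497e-2 + 1.469e-3 + 0.755e-4
        assert bec_factor(1e-8, spec, geom) == pytest.approx(expected, rel=1e-12)

    def test_negative_indentation_rejected(self, micron_tip):
        with pytest.raises(ValueError):
            bec_factor(-1e-9, BECSpec(thickness=1e-6), micron_tip)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(d1=st.floats(0, 2e-6), d2=st.floats(0, 2e-6),
           h=st.floats(2e-7, 1e-5))
    def test_factor_ge_one_and_monotone(self, d1, d2, h):
        geom = TipGeometry(radius=1e-6)
        spec = BECSpec(thickness=h)
        f1, f2 = bec_factor(d1, spec, geom), bec_factor(d2, spec, geom)
        assert f1 >= 1.0 and f2 >= 1.0
        if d1 <= d2:
            assert f1 <= f2 + 1e-12


class TestHertzForce:
    def test_zero_indentation(self, micron_tip):
        assert hertz_force(0.0, 750.0, micron_tip) == 0.0

    def test_reference_value(self, micron_tip):
        # E=750 Pa, nu=0.5, R=1um, delta=1um: (4/3)(750/0.75)*1e-3*1e-9 N
        f = hertz_force(1e-6, 750.0, micron_tip)
        assert f == pytest.approx(4.0 / 3.0 * 1000.0 * 1e-3 * 1e-9, rel=1e-12)
        assert f == pytest.approx(1.333e-9, rel=1e-3)

    def test_three_halves_scaling(self, micron_tip):
        f1 = hertz_force(0.5e-6, 2000.0, micron_tip)
        f2 = hertz_force(1.0e-6, 2000.0, micron_tip)
        assert f2 / f1 == pytest.approx(2**1.5, rel=1e-12)

    def test_invalid_modulus(self, micron_tip):
        with pytest.raises(ValueError):
            hertz_force(1e-6, -5.0, micron_tip)


class TestPLRRelaxation:
    def test_unit_time_gives_e0(self):
        p = PLRParameters(E0=1234.0, alpha=0.31)
        assert plr_relaxation(1.0, p) == pytest.approx(1234.0)

    def test_solid_like_is_constant(self):
        p = PLRParameters(E0=800.0, alpha=0.0)
        assert plr_relaxation(17.0, p) == pytest.approx(800.0)

    def test_half_exponent(self):
        assert plr_relaxation(4.0, PLRParameters(1000.0, 0.5)) == pytest.approx(500.0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            plr_relaxation(0.0, PLRParameters(1000.0, 0.2))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(alpha=st.floats(0.0, 0.95), t1=st.floats(1e-3, 10.0),
           t2=st.floats(1e-3, 10.0))
    def test_monotone_non_increasing(self, alpha, t1, t2):
        p = PLRParameters(1000.0, alpha)
        if t1 <= t2:
            assert plr_relaxation(t1, p) >= plr_relaxation(t2, p) - 1e-9


class TestTingForce:
    def test_elastic_limit_equals_hertz(self, micron_tip, ramp_trajectory,
                                        plr_solid):
        f = ting_force(ramp_trajectory, plr_solid, micron_tip)
        app = ramp_trajectory.time <= ramp_trajectory.t_approach
        ref = hertz_force(ramp_trajectory.indentation[app], plr_solid.E0,
                          micron_tip)
        rel = np.abs(f[app][1:] - ref[1:]) / ref[1:]
        assert rel.max() < 1e-4

    def test_closed_form_alpha_half(self, micron_tip, ramp_trajectory):
        # linear ramp, alpha = 1/2: F(t) = pi sqrt(R) E0 v^(3/2) t / (1-nu^2)
        p = PLRParameters(E0=1000.0, alpha=0.5, eta=0.0)
        f = ting_force(ramp_trajectory, p, micron_tip)
        t = ramp_trajectory.time
        app = t <= ramp_trajectory.t_approach
        exact = np.pi * 1e-3 * 1000.0 * 1e-9 * t[app] / 0.75
        i_end = int(app.sum()) - 1
        assert f[i_end] == pytest.approx(4.19e-9, rel=5e-3)
        assert f[i_end] == pytest.approx(exact[-1], rel=5e-3)
        # away from the vanishing-force contact region the whole ramp agrees
        half = slice(i_end // 2, i_end + 1)
        rel = np.abs(f[app][half] - exact[half]) / exact[half]
        assert rel.max() < 5e-3

    def test_zero_before_contact_and_after_detachment(self, micron_tip):
        traj = triangular_trajectory()
        p = PLRParameters(1000.0, 0.3, 0.5)
        f = ting_force(traj, p, micron_tip)
        assert f[0] == 0.0
        assert np.all(f >= -1e-18)
        assert np.all(f[-3:] == 0.0)     # fully detached by the ramp end

    def test_t1_non_increasing_during_retraction(self, micron_tip):
        traj = triangular_trajectory()
        p = PLRParameters(1000.0, 0.35, 0.0)
        _, t1 = ting_force(traj, p, micron_tip, return_t1=True)
        ret = traj.time > traj.t_approach
        diffs = np.diff(t1[ret])
        assert np.all(diffs <= 1e-9)

    def test_nonmonotone_time_rejected(self, micron_tip):
        from cellmech.mechanics import IndentationTrajectory

        with pytest.raises(ValueError):
            IndentationTrajectory(time=np.array([0.0, 1.0, 0.5]),
                                  indentation=np.zeros(3), t_approach=1.0)


class TestContactDetection:
    def test_noise_free_within_one_sample(self, soft_probe):
        c = make_force_curve(PLRParameters(2000.0, 0.0, 0.0), soft_probe,
                             pre_contact=32)
        idx, _ = detect_contact_point(c, soft_probe)
        assert abs(idx - 32) <= 1

    def test_noisy_within_three_samples(self, soft_probe):
        hits = []
        for seed in range(8):
            c = make_force_curve(PLRParameters(2000.0, 0.0, 0.0), soft_probe,
                                 pre_contact=32, noise=20e-12,
                                 rng=np.random.default_rng(seed))
            idx, _ = detect_contact_point(c, soft_probe)
            hits.append(abs(idx - 32) <= 3)
        assert np.mean(hits) >= 0.9

    def test_flat_curve_raises(self, soft_probe):
        c = ForceCurve(np.linspace(0, 1, 64), np.linspace(0, 1e-6, 64),
                       np.zeros(64))
        with pytest.raises(ContactNotFoundError):
            detect_contact_point(c, soft_probe)


class TestFitHertz:
    def test_noise_free_round_trip(self, soft_probe):
        c = make_force_curve(PLRParameters(2000.0, 0.0, 0.0), soft_probe)
        r = fit_hertz(c, soft_probe)
        assert r.modulus == pytest.approx(2000.0, rel=0.01)

    def test_omitted_bec_biases_high(self, soft_probe):
        c = make_force_curve(PLRParameters(2000.0, 0.0, 0.0), soft_probe,
                             thickness=1e-6)
        r = fit_hertz(c, soft_probe)   # fitted without the correction
        assert r.modulus > 2000.0

    def test_never_indenting_curve_raises(self, soft_probe):
        t = np.linspace(0, 1, 64)
        z = np.concatenate([np.linspace(0, 1e-6, 32),
                            np.linspace(1e-6, 0, 32)])
        t = np.linspace(0, 1, 64)
        f = np.zeros(64)
        f[30] = 1e-9    # single spike, no post-contact ramp
        c = ForceCurve(t, z, f)
        with pytest.raises((InsufficientDataError, ContactNotFoundError)):
            fit_hertz(c, soft_probe)

    def test_rate_dependence_of_apparent_modulus(self, soft_probe):
        # viscoelastic samples look stiffer at faster loading
        moduli = [fit_hertz(make_force_curve(
            PLRParameters(2000.0, 0.25, 1.0), soft_probe, speed=v),
            soft_probe).modulus for v in (20e-6, 60e-6, 183e-6)]
        assert moduli[0] < moduli[1] < moduli[2]


class TestFitPLR:
    def test_noise_free_round_trip(self, soft_probe):
        truth = PLRParameters(2000.0, 0.2, 1.0)
        r = fit_plr(make_force_curve(truth, soft_probe), soft_probe)
        assert r.converged
        assert r.params.E0 == pytest.approx(truth.E0, rel=0.02)
        assert r.params.alpha == pytest.approx(truth.alpha, rel=0.02)
        assert r.params.eta == pytest.approx(truth.eta, rel=0.02)

    def test_solid_like_boundary(self, soft_probe):
        r = fit_plr(make_force_curve(PLRParameters(2000.0, 0.0, 1.0),
                                     soft_probe), soft_probe)
        assert 0.0 <= r.params.alpha <= 0.02

    def test_missing_retraction_raises(self, soft_probe):
        c = make_force_curve(PLRParameters(2000.0, 0.2, 1.0), soft_probe)
        turn = c.turnaround_index
        approach_only = ForceCurve(c.time[: turn + 2], c.z[: turn + 2],
                                   c.force[: turn + 2])
        with pytest.raises(InsufficientDataError):
            fit_plr(approach_only, soft_probe)
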