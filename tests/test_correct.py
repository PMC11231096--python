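"""Navigator-based ghost and off-resonance estimation, and frame correction."""

import dataclasses

import numpy as np
import pytest

from dynb0 import (FieldState, FieldTimeline, acquire_frame, acquire_session,
                   estimate_dky, estimate_phi0_dkx, ghost_params_from_nav,
                   make_field_timeline, make_phantom)
from dynb0.correct import (PerturbationEstimate, correct_frame,
                           correct_nav_ghost, estimate_frame,
                           estimate_session, estimates_to_frame,
                           reference_navigators)
from dynb0.fourier import cfft, cifft, coords
from dynb0.recon import nyquist_correct


@pytest.fixture(scope="module")
def zero_frame(phantom, coils, protocol):
    return acquire_frame(phantom.grid[[0, 2]], coils, FieldState(), protocol,
                         "physics", rng=0)


@pytest.fixture(scope="module")
def nav_ref(zero_frame):
    g = ghost_params_from_nav(zero_frame.nav, zero_frame.nav_polarity)
    return correct_nav_ghost(zero_frame.nav, zero_frame.nav_polarity, g)


class TestGhostEstimation:
    def test_recovers_injected_parameters(self, zero_frame, protocol):
        g = ghost_params_from_nav(zero_frame.nav, zero_frame.nav_polarity)
        assert g.theta0 == pytest.approx(protocol.ghost_theta0, abs=1e-3)
        assert g.theta1 == pytest.approx(protocol.ghost_theta1, abs=1e-3)

    def test_zero_ghost_recovered_as_zero(self, phantom, coils, protocol):
        p0 = dataclasses.replace(protocol, ghost_theta0=0.0, ghost_theta1=0.0)
        fr = acquire_frame(phantom.grid[[0, 2]], coils, FieldState(), p0, rng=0)
        g = ghost_params_from_nav(fr.nav, fr.nav_polarity)
        assert abs(g.theta0) < 1e-9 and abs(g.theta1) < 1e-9

    def test_polarity_swap_flips_sign(self, zero_frame):
        g = ghost_params_from_nav(zero_frame.nav, zero_frame.nav_polarity)
        g2 = ghost_params_from_nav(zero_frame.nav, -zero_frame.nav_polarity)
        assert g2.theta0 == pytest.approx(-g.theta0, abs=1e-6)
        assert g2.theta1 == pytest.approx(-g.theta1, abs=1e-6)

    def test_zero_navigator_rejected(self, zero_frame):
        with pytest.raises(ValueError):
            ghost_params_from_nav(np.zeros_like(zero_frame.nav),
                                  zero_frame.nav_polarity)


class TestPhi0DkxEstimation:
    def test_identity_gives_zero(self, nav_ref):
        phi0, dkx = estimate_phi0_dkx(nav_ref, nav_ref)
        assert abs(phi0) < 1e-12 and abs(dkx) < 1e-12

    def test_constructed_global_phase(self, nav_ref):
        phi0, dkx = estimate_phi0_dkx(nav_ref * np.exp(1j * np.pi / 4), nav_ref)
        assert phi0 == pytest.approx(np.pi / 4, abs=1e-6)
        assert dkx == pytest.approx(0.0, abs=1e-6)

    def test_constructed_linear_ramp(self, nav_ref, protocol):
        x = coords(protocol.n)
        hyb = cifft(nav_ref, axis=-1) * np.exp(2j * np.pi * 0.25 * x)
        nav_t = cfft(hyb, axis=-1)
        phi0, dkx = estimate_phi0_dkx(nav_t, nav_ref)
        assert dkx == pytest.approx(0.25, abs=0.005)
        assert phi0 == pytest.approx(0.0, abs=0.01)

    def test_injected_translate_mode_recovery(self, phantom, coils, protocol,
                                              nav_ref):
        fs = FieldState.from_kspace(0.3, 0.25, 0.0, protocol.te)
        fr = acquire_frame(phantom.grid[[0, 2]], coils, fs, protocol,
                           "translate", rng=0)
        g = ghost_params_from_nav(fr.nav, fr.nav_polarity)
        nav_c = correct_nav_ghost(fr.nav, fr.nav_polarity, g)
        phi0_n, dkx_n = estimate_phi0_dkx(nav_c, nav_ref)
        scale = protocol.te / float(np.mean(protocol.nav_times()))
        assert phi0_n * scale == pytest.approx(0.3, abs=0.01)
        assert dkx_n * scale == pytest.approx(0.25, abs=0.01)

    def test_empty_reference_rejected(self, nav_ref):
        with pytest.raises(ValueError):
            estimate_phi0_dkx(nav_ref, np.zeros_like(nav_ref))


class TestDkyEstimation:
    def test_identity_gives_zero(self, nav_ref, operators):
        dky, obj, amb = estimate_dky(nav_ref, nav_ref, operators.shift_ky)
        assert dky == 0.0
        assert obj < 1e-20

    @pytest.mark.parametrize("dky_true", [0.4, -0.3])
    def test_injected_value_recovered(self, phantom, coils, protocol, operators,
                                      nav_ref, dky_true):
        fs = FieldState.from_kspace(0.0, 0.0, dky_true, protocol.te)
        fr = acquire_frame(phantom.grid[[0, 2]], coils, fs, protocol,
                           "translate", rng=0)
        est = estimate_frame(fr, nav_ref, operators.shift_ky, protocol)
        assert est.dky == pytest.approx(dky_true, abs=0.02)
        assert np.sign(est.dky) == np.sign(dky_true)


class TestCorrectFrame:
    def test_zero_estimate_is_bit_identity(self, zero_frame, operators, protocol):
        est = PerturbationEstimate()
        out = correct_frame(zero_frame, est, operators.shift_ky, protocol)
        assert np.array_equal(out.data, zero_frame.data)
        assert np.array_equal(out.nav, zero_frame.nav)

    def test_truth_correction_restores_zero_field_frame(self, phantom, coils,
                                                        protocol, operators,
                                                        zero_frame):
        phi0, dkx, dky = 0.5, 0.3, 0.4
        fs = FieldState.from_kspace(phi0, dkx, dky, protocol.te)
        fr = acquire_frame(phantom.grid[[0, 2]], coils, fs, protocol,
                           "translate", rng=0)
        g = ghost_params_from_nav(zero_frame.nav, zero_frame.nav_polarity)
        ref = nyquist_correct(zero_frame, g)
        cor = correct_frame(nyquist_correct(fr, g),
                            PerturbationEstimate(phi0, dkx, dky),
                            operators.shift_ky, protocol)
        err = np.linalg.norm(cor.data - ref.data) / np.linalg.norm(ref.data)
        assert err < 0.02

    def test_correction_roundtrip_with_negation(self, zero_frame, operators,
                                                protocol):
        est = PerturbationEstimate(0.5, 0.3, 0.4)
        neg = PerturbationEstimate(-0.5, -0.3, -0.4)
        out = correct_frame(correct_frame(zero_frame, est, operators.shift_ky,
                                          protocol),
                            neg, operators.shift_ky, protocol)
        err = np.linalg.norm(out.data - zero_frame.data) / np.linalg.norm(zero_frame.data)
        assert err < 0.01

    def test_nonfinite_estimate_rejected(self, zero_frame, operators, protocol):
        with pytest.raises(ValueError):
            correct_frame(zero_frame, PerturbationEstimate(np.nan, 0, 0),
                          operators.shift_ky, protocol)


class TestEstimateSession:
    def test_zero_timeline_estimates_zero(self, phantom, coils, protocol,
                                          operators, events):
        tl = make_field_timeline(4, (0, 0, 0), "smooth", seed=1)
        ses = acquire_session(phantom, coils, tl, events, protocol, seed=2)
        ests = estimate_session(ses, operators)
        df = estimates_to_frame(ests)
        assert np.abs(df[["phi0", "dkx", "dky"]].to_numpy()).max() < 0.01

    def test_spike_locality_of_estimates(self, phantom, coils, protocol,
                                         operators, events):
        arr = np.zeros((5, 3))
        arr[3] = [0.0, 0.0, 12.0]
        tl = FieldTimeline.from_array(arr)
        ses = acquire_session(phantom, coils, tl, events, protocol, seed=2)
        ests = estimate_session(ses, operators)
        df = estimates_to_frame(ests)
        spike = df[df.frame == 3]
        rest = df[df.frame != 3]
        assert np.all(np.abs(spike["dky"]) > 0.05)
        assert np.all(np.abs(rest["dky"]) < 0.05)

    def test_parameter_recovery_grid_noiseless(self, phantom, coils, protocol,
                                               operators, nav_ref):
        errs = []
        for phi0 in (-1.0, 0.0, 0.7):
            for dkx in (-0.5, 0.3):
                for dky in (-0.5, 0.0, 0.5):
                    fs = FieldState.from_kspace(phi0, dkx, dky, protocol.te)
                    fr = acquire_frame(phantom.grid[[0, 2]], coils, fs, protocol,
                                       "translate", rng=0)
                    est = estimate_frame(fr, nav_ref, operators.shift_ky, protocol)
                    errs.append([abs(est.phi0 - phi0), abs(est.dkx - dkx),
                                 abs(est.dky - dky)])
        assert np.max(errs, axis=0) == pytest.approx([0, 0, 0], abs=0.02)

    def test_physics_mode_dky_slope_near_unity(self, phantom, coils, protocol,
                                               operators, nav_ref):
        xs, ys = [], []
        for dky in np.linspace(-0.3, 0.3, 5):
            fs = FieldState(0.0, 0.0, dky / protocol.te)
            fr = acquire_frame(phantom.grid[[0, 2]], coils, fs, protocol,
                               "physics", rng=0)
            est = estimate_frame(fr, nav_ref, operators.shift_ky, protocol)
            xs.append(dky)
            ys.append(est.dky)
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_noise_robustness_dky_rmse(self, phantom, coils, noisy_protocol):
        from dynb0 import acquire_calibration
        from dynb0.calib import train_operators

        cal = acquire_calibration(phantom, coils, noisy_protocol, seed=1)
        ops = train_operators(cal.calib, noisy_protocol)
        rng = np.random.default_rng(2)
        fr0 = acquire_frame(phantom.grid[[0, 2]], coils, FieldState(),
                            noisy_protocol, "physics", rng=rng)
        g = ghost_params_from_nav(fr0.nav, fr0.nav_polarity)
        ref = correct_nav_ghost(fr0.nav, fr0.nav_polarity, g)
        errs = []
        for _ in range(50):
            dky = float(rng.uniform(-0.5, 0.5))
            fs = FieldState.from_kspace(float(rng.uniform(-1, 1)),
                                        float(rng.uniform(-0.5, 0.5)),
                                        dky, noisy_protocol.te)
            fr = acquire_frame(phantom.grid[[0, 2]], coils, fs, noisy_protocol,
                               "translate", rng=rng)
            est = estimate_frame(fr, ref, ops.shift_ky, noisy_protocol)
            errs.append(est.dky - dky)
        assert np.sqrt(np.mean(np.square(errs))) < 0.05

    def test_reference_frame_estimates_itself_as_zero(self, phantom, coils,
                                                      protocol, operators,
                                                      events):
        tl = make_field_timeline(3, (5, 8, 8), "smooth", seed=1)
        ses = acquire_session(phantom, coils, tl, events, protocol, seed=2)
        refs = reference_navigators(ses)
        est = estimate_frame(ses.frames[0][0], refs[0], operators.shift_ky,
                             protocol)
        # phi0/dkx are exact phase fits; dky only to the search tolerance
        assert abs(est.phi0) < 1e-6 and abs(est.dkx) < 1e-6 and abs(est.dky) < 0.01


class TestDkxOperatorPath:
    def test_operator_search_agrees_with_phase_fit(self, phantom, coils,
                                                   protocol, calibration,
                                                   nav_ref):
        """The alternative operator-search estimator for the readout
        translation agrees with the default projection-phase fit."""
        from dynb0 import train_shift_operator
        from dynb0.correct import (correct_nav_ghost, estimate_dkx_operator,
                                   estimate_phi0_dkx, ghost_params_from_nav,
                                   remove_phi0_dkx)

        op_kx = train_shift_operator(calibration.calib, protocol, axis="kx", w=1)
        dkx_true = 0.3
        fs = FieldState.from_kspace(0.0, dkx_true, 0.0, protocol.te)
        fr = acquire_frame(phantom.grid[[0, 2]], coils, fs, protocol,
                           "translate", rng=0)
        g = ghost_params_from_nav(fr.nav, fr.nav_polarity)
        nav_c = correct_nav_ghost(fr.nav, fr.nav_polarity, g)
        phi0_n, dkx_phase = estimate_phi0_dkx(nav_c, nav_ref)
        nav_c2 = remove_phi0_dkx(nav_c, phi0_n, 0.0)  # keep the translation
        dkx_op, _, _ = estimate_dkx_operator(nav_c2, nav_ref, op_kx)
        scale = protocol.te / float(np.mean(protocol.nav_times()))
        assert dkx_phase * scale == pytest.approx(dkx_true, abs=0.01)
        assert dkx_op * scale == pytest.approx(dkx_true, abs=0.05)
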