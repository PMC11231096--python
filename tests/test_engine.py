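"""SMS-EPI acquisition engine: encoding physics, noise, session container."""

import dataclasses

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from dynb0 import (FieldState, acquire_frame, acquire_session, load_session,
                   make_field_timeline, save_session)
from dynb0.fourier import cfft2, cifft2, translation_ramp
from dynb0.recon import coil_combine


def _full_protocol(protocol, **kw):
    """Fully sampled single-band variant for shift-theorem style checks."""
    kw = {"mb": 1, "r": 1, "ghost_theta0": 0.0, "ghost_theta1": 0.0, **kw}
    return dataclasses.replace(protocol, **kw)


class TestAcquireFrame:
    def test_zero_field_modes_agree(self, phantom, coils, protocol):
        sl = phantom.grid[[0, 2]]
        a = acquire_frame(sl, coils, FieldState(), protocol, "physics", rng=0)
        b = acquire_frame(sl, coils, FieldState(), protocol, "translate", rng=0)
        assert np.allclose(a.data, b.data, atol=1e-10 * np.abs(a.data).max())
        assert np.allclose(a.nav, b.nav, atol=1e-10 * np.abs(a.nav).max())

    def test_integer_kx_shift_rolls_kspace(self, phantom, coils, protocol):
        p = _full_protocol(protocol)
        fs = FieldState.from_kspace(0.0, 1.0, 0.0, p.te)
        fr = acquire_frame(phantom.grid[[0]], coils, fs, p, "translate", rng=0)
        fr0 = acquire_frame(phantom.grid[[0]], coils, FieldState(), p, "translate", rng=0)
        shifted = np.roll(fr0.data, 1, axis=-1)
        assert np.linalg.norm(fr.data - shifted) / np.linalg.norm(shifted) < 1e-10

    def test_shift_theorem_undoes_translate_corruption(self, phantom, coils, protocol):
        p = _full_protocol(protocol)
        phi0, dkx, dky = 0.3, 0.25, 0.4
        fs = FieldState.from_kspace(phi0, dkx, dky, p.te)
        fr = acquire_frame(phantom.grid[[0]], coils, fs, p, "translate", rng=0)
        fr0 = acquire_frame(phantom.grid[[0]], coils, FieldState(), p, "translate", rng=0)
        undone = cfft2(cifft2(fr.data)
                       * np.conj(translation_ramp(p.n, dkx, dky, phi0))[None])
        assert np.linalg.norm(undone - fr0.data) / np.linalg.norm(fr0.data) < 1e-10

    def test_physics_c0_causes_expected_bulk_shift(self, phantom, coils, protocol):
        # a constant off-resonance shifts the EPI image along phase-encode by
        # c0 * esp / R * N pixels (from the linear-in-ky phase across the train)
        p = _full_protocol(protocol, r=2)
        c0 = 40.0
        fr = acquire_frame(phantom.grid[[0]], coils, FieldState(c0=c0), p,
                           "physics", rng=0)
        fr0 = acquire_frame(phantom.grid[[0]], coils, FieldState(), p,
                            "physics", rng=0)
        # fill missing lines by zero (shift estimate robust via correlation)
        grid = np.zeros((p.n_coils, p.n, p.n), dtype=complex)
        grid0 = np.zeros_like(grid)
        rows = p.acquired_ky + p.n // 2
        grid[:, rows] = fr.data
        grid0[:, rows] = fr0.data
        img = coil_combine(cifft2(grid))
        img0 = coil_combine(cifft2(grid0))
        shift, *_ = phase_cross_correlation(img0, img, upsample_factor=50)
        dt = np.diff(p.line_times()).mean()
        expected = c0 * dt / p.r * p.n  # pixels along y
        assert abs(shift[0]) == pytest.approx(expected, abs=0.15)
        # derived prediction: applying the per-line c0 phase to the zero-field
        # k-space reproduces the shifted image (pins the direction too)
        alpha = 2 * np.pi * c0 * dt / p.r
        kappa = np.arange(p.n) - p.n // 2
        pred = coil_combine(cifft2(grid0 * np.exp(1j * alpha * kappa)[None, :, None]))
        assert np.linalg.norm(pred - img) / np.linalg.norm(img) < 0.02

    def test_physics_translate_agree_for_small_shift(self, phantom, coils, protocol):
        # net-translation approximation: RSS images agree within 5% for
        # |dk| <= 0.3, c0 = 0
        fs = FieldState(0.0, 0.3 / protocol.te, 0.25 / protocol.te)
        rows = protocol.acquired_ky + protocol.n // 2

        def rss_image(mode):
            fr = acquire_frame(phantom.grid[[0, 2]], coils, fs, protocol, mode, rng=0)
            grid = np.zeros((protocol.n_coils, protocol.n, protocol.n), dtype=complex)
            grid[:, rows] = fr.data
            return coil_combine(cifft2(grid))

        a, b = rss_image("physics"), rss_image("translate")
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.05

    def test_noise_variance_matches_sigma(self, phantom, coils, noisy_protocol):
        clean = dataclasses.replace(noisy_protocol, sigma=0.0)
        f0 = acquire_frame(phantom.grid[[0, 2]], coils, FieldState(), clean,
                           "physics", rng=0)
        f1 = acquire_frame(phantom.grid[[0, 2]], coils, FieldState(), noisy_protocol,
                           "physics", rng=0)
        diff = f1.data - f0.data
        var = 0.5 * (diff.real.var() + diff.imag.var())
        assert var == pytest.approx(noisy_protocol.sigma**2, rel=0.05)

    def test_unknown_mode_rejected(self, phantom, coils, protocol):
        with pytest.raises(ValueError):
            acquire_frame(phantom.grid[[0, 2]], coils, FieldState(), protocol,
                          "warp", rng=0)

    def test_navigators_have_three_lines_and_increasing_times(self, phantom, coils,
                                                              protocol):
        fr = acquire_frame(phantom.grid[[0, 2]], coils, FieldState(), protocol, rng=0)
        assert fr.nav.shape[1] == 3
        assert np.all(np.diff(fr.line_times) > 0)
        assert np.all(np.diff(fr.nav_times) > 0)
        assert fr.data.shape == (protocol.n_coils, protocol.n_lines, protocol.n)


class TestCalibration:
    def test_calib_matches_object(self, calibration, phantom, coils):
        img = coil_combine(cifft2(calibration.calib[0]))
        truth = np.abs(phantom.grid[0]) * coils.rss()
        assert np.linalg.norm(img - truth) / np.linalg.norm(truth) < 1e-10

    def test_single_band_reference_quality(self, calibration, phantom, coils,
                                           protocol):
        assert calibration.sb_ref.shape[0] == protocol.n_slices
        truth = np.abs(phantom.grid[1]) * coils.rss()
        err = np.linalg.norm(calibration.sb_ref[1] - truth) / np.linalg.norm(truth)
        assert err < 0.03

    def test_deterministic(self, phantom, coils, protocol):
        from dynb0 import acquire_calibration

        a = acquire_calibration(phantom, coils, protocol, seed=5)
        b = acquire_calibration(phantom, coils, protocol, seed=5)
        assert np.array_equal(a.calib, b.calib)
        assert np.array_equal(a.sb_ref, b.sb_ref)


class TestSession:
    def test_static_session_frames_identical(self, coils, protocol, events):
        from dynb0 import make_phantom

        ph0 = make_phantom(protocol.n, protocol.n_slices, seed=1,
                           activation_amplitude=0.0)
        tl = make_field_timeline(5, (0, 0, 0), "smooth", seed=1)
        ses = acquire_session(ph0, coils, tl, events, protocol, seed=2)
        for g in range(ses.n_groups):
            ref = ses.frames[0][g].data
            for t in range(1, 5):
                assert np.array_equal(ses.frames[t][g].data, ref)

    def test_spike_locality(self, coils, protocol, events):
        from dynb0 import FieldTimeline, make_phantom

        ph0 = make_phantom(protocol.n, protocol.n_slices, seed=1,
                           activation_amplitude=0.0)
        arr = np.zeros((5, 3))
        arr[2] = [5.0, 8.0, 8.0]
        tl = FieldTimeline.from_array(arr)
        ses = acquire_session(ph0, coils, tl, events, protocol, seed=2)
        ref = ses.frames[0][0].data
        assert not np.array_equal(ses.frames[2][0].data, ref)
        for t in (1, 3, 4):
            assert np.array_equal(ses.frames[t][0].data, ref)

    def test_timeline_length_mismatch_rejected(self, phantom, coils, protocol,
                                               events):
        tl = make_field_timeline(5, (0, 0, 0), "smooth", seed=1)
        ses = acquire_session(phantom, coils, tl, events, protocol, seed=2)
        assert ses.n_frames == 5

    def test_hdf5_round_trip_bit_identical(self, phantom, coils, protocol, events,
                                           tmp_path):
        tl = make_field_timeline(3, (5, 8, 8), "smooth", seed=1)
        ses = acquire_session(phantom, coils, tl, events, protocol, seed=2)
        path = tmp_path / "session.h5"
        save_session(ses, path)
        back = load_session(path)
        assert back.n_frames == ses.n_frames
        for t in range(ses.n_frames):
            for g in range(ses.n_groups):
                assert np.array_equal(back.frames[t][g].data, ses.frames[t][g].data)
                assert np.array_equal(back.frames[t][g].nav, ses.frames[t][g].nav)
        assert np.array_equal(back.calibration.calib, ses.calibration.calib)
        assert np.array_equal(back.truth.timeline.as_array(), tl.as_array())
        assert back.protocol == ses.protocol
        assert np.array_equal(back.truth.events.offer, ses.truth.events.offer)


class TestOperatorPersistence:
    def test_operators_round_trip(self, calibration, protocol, operators,
                                  tmp_path):
        from dynb0.engine import load_operators, save_operators

        path = tmp_path / "ops.h5"
        save_operators(path, operators)
        back = load_operators(path)
        assert np.array_equal(back.inplane.weights, operators.inplane.weights)
        assert np.array_equal(back.shift_ky.Wx, operators.shift_ky.Wx)
        assert back.shift_ky.w == operators.shift_ky.w
        line = calibration.calib[0][:, protocol.n // 2 - 2, :]
        assert np.allclose(back.shift_ky.apply_power(line, 0.5),
                           operators.shift_ky.apply_power(line, 0.5))
        for a, b in zip(back.slices, operators.slices):
            for wa, wb in zip(a.weights, b.weights):
                assert np.array_equal(wa, wb)

    def test_estimates_round_trip(self, tmp_path):
        import pandas as pd

        from dynb0.engine import load_estimates, save_estimates

        df = pd.DataFrame({"frame": [0, 0, 1], "group": [0, 1, 0],
                           "phi0": [0.1, 0.2, 0.3], "dkx": [0.0, 0.1, -0.1],
                           "dky": [0.4, -0.2, 0.0], "objective": [1e-3] * 3,
                           "ambiguous": [False, False, True]})
        path = tmp_path / "sess.h5"
        save_estimates(path, df)
        back = load_estimates(path)
        for col in ("frame", "phi0", "dky", "ambiguous"):
            assert np.array_equal(back[col].to_numpy(), df[col].to_numpy())
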