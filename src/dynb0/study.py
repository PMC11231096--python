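"""End-to-end simulation studies comparing the corrected and uncorrected
reconstruction arms, plus self-contained validation experiments for the
estimator, the shift operators and the GLM machinery.

The default study conditions: 64x64 matrix, 4 slices (2 SMS groups), 8
coils, MB=2, R=2, TE/TR = 25.4/1282 ms, coil-combined SNR ~ 30, smooth
body-motion-like field timelines with (c0, cx, cy) amplitudes (10, 15, 15)
Hz / Hz-per-FOV (max |dk| ~ 0.38 grid units at TE), 2% BOLD activation,
T = 200 frames per session.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calib import train_operators, train_shift_operator
from .correct import (correct_nav_ghost, estimate_frame, estimate_session,
                      estimates_to_frame, ghost_params_from_nav)
from .engine import (acquire_calibration, acquire_frame, acquire_session,
                     sigma_for_snr)
from .fourier import cfft2, cifft2, translation_ramp
from .glm import (build_design, fit_glm, preprocess_series,
                  split_half_reliability, whitened_residual_autocorr)
from .phantom import (FieldState, make_coil_maps, make_field_timeline,
                      make_phantom)
from .protocol import Protocol, RunConfig
from .qc import bias_map, cov_map, paired_compare, roi_summary, tsnr_map
from .recon import reconstruct_session
from .task import make_task_events

ARMS = ("corrected", "uncorrected")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


# ---------------------------------------------------------------------------
# Stand-alone validation experiments
# ---------------------------------------------------------------------------

def shift_theorem_error(seed: int = 0) -> float:
    """Relative error of undoing a translate-mode corruption with the exact
    conjugate image-domain phase ramp (fully sampled, ghost-free, sigma=0)."""
    p = Protocol(mb=1, r=1, ghost_theta0=0.0, ghost_theta1=0.0, sigma=0.0)
    ph = make_phantom(p.n, p.n_slices, seed=seed)
    coils = make_coil_maps(p.n_coils, p.n, seed=seed)
    fs = FieldState.from_kspace(0.3, 0.25, 0.4, p.te)
    fr = acquire_frame(ph.grid[[0]], coils, fs, p, "translate", rng=seed)
    fr0 = acquire_frame(ph.grid[[0]], coils, FieldState(), p, "translate", rng=seed)
    phi0, dkx, dky = fs.to_kspace(p.te)
    undone = cfft2(cifft2(fr.data) * np.conj(translation_ramp(p.n, dkx, dky, phi0))[None])
    return float(np.linalg.norm(undone - fr0.data) / np.linalg.norm(fr0.data))


def semigroup_errors(seed: int = 0) -> dict:
    """Shift-operator composition errors on calibration data."""
    p = Protocol(sigma=0.0)
    ph = make_phantom(p.n, p.n_slices, seed=seed)
    coils = make_coil_maps(p.n_coils, p.n, seed=seed)
    cal = acquire_calibration(ph, coils, p, seed=seed)
    op = train_shift_operator(cal.calib, p, axis="ky")
    line = cal.calib[0][:, p.n // 2 - 2, :]
    errs = []
    for a in (-0.5, -0.25, 0.25, 0.5):
        for b in (-0.5, -0.25, 0.25, 0.5):
            lhs = op.apply_power(op.apply_power(line, a), b)
            rhs = op.apply_power(line, a + b)
            errs.append(np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs))
    ident = op.fractional_power(0.0)
    id_err = float(np.abs(ident - np.eye(p.n_coils)[None]).max())
    return {"semigroup_max_rel_err": float(max(errs)), "w0_identity_err": id_err}


def parameter_recovery(seed: int = 0, n_noisy: int = 50) -> dict:
    """Recovery of injected (phi0, dkx, dky) in translate mode.

    Noiseless grid over phi0 in [-1, 1] rad, dkx/dky in [-0.5, 0.5] grid
    units, then RMSE of dky over ``n_noisy`` random frames at SNR 30.
    """
    p = Protocol(sigma=0.0)
    ph = make_phantom(p.n, p.n_slices, seed=seed)
    coils = make_coil_maps(p.n_coils, p.n, seed=seed)
    cal = acquire_calibration(ph, coils, p, seed=seed)
    op = train_shift_operator(cal.calib, p, axis="ky")
    fr0 = acquire_frame(ph.grid[[0, p.n_groups]], coils, FieldState(), p,
                        "physics", rng=seed)
    g0 = ghost_params_from_nav(fr0.nav, fr0.nav_polarity)
    nav_ref = correct_nav_ghost(fr0.nav, fr0.nav_polarity, g0)

    errs = []
    for phi0 in (-1.0, -0.4, 0.0, 0.7):
        for dkx in (-0.5, 0.0, 0.3):
            for dky in (-0.5, -0.2, 0.0, 0.3, 0.5):
                fs = FieldState.from_kspace(phi0, dkx, dky, p.te)
                fr = acquire_frame(ph.grid[[0, p.n_groups]], coils, fs, p,
                                   "translate", rng=seed)
                est = estimate_frame(fr, nav_ref, op, p)
                errs.append([abs(est.phi0 - phi0), abs(est.dkx - dkx),
                             abs(est.dky - dky)])
    max_err = np.max(errs, axis=0)

    sig = sigma_for_snr(ph, coils, p, 30.0)
    pn = dataclasses.replace(p, sigma=sig)
    caln = acquire_calibration(ph, coils, pn, seed=seed + 1)
    opn = train_shift_operator(caln.calib, pn, axis="ky")
    rng = np.random.default_rng(seed + 2)
    fr0n = acquire_frame(ph.grid[[0, p.n_groups]], coils, FieldState(), pn,
                         "physics", rng=rng)
    gn = ghost_params_from_nav(fr0n.nav, fr0n.nav_polarity)
    nav_refn = correct_nav_ghost(fr0n.nav, fr0n.nav_polarity, gn)
    derr = []
    for _ in range(n_noisy):
        dky = float(rng.uniform(-0.5, 0.5))
        fs = FieldState.from_kspace(float(rng.uniform(-1, 1)),
                                    float(rng.uniform(-0.5, 0.5)), dky, p.te)
        fr = acquire_frame(ph.grid[[0, p.n_groups]], coils, fs, pn,
                           "translate", rng=rng)
        est = estimate_frame(fr, nav_refn, opn, pn)
        derr.append(est.dky - dky)
    return {
        "recovery_max_abs_err_phi0": float(max_err[0]),
        "recovery_max_abs_err_dkx": float(max_err[1]),
        "recovery_max_abs_err_dky": float(max_err[2]),
        "recovery_rmse_dky_snr30": float(np.sqrt(np.mean(np.square(derr)))),
    }


def zero_perturbation_safety(seed: int = 0, T: int = 8) -> float:
    """Relative difference between arms on a zero-timeline, noiseless,
    static-object session (the correction must be an exact no-op)."""
    p = Protocol(sigma=0.0)
    ph = make_phantom(p.n, p.n_slices, seed=seed, activation_amplitude=0.0)
    coils = make_coil_maps(p.n_coils, p.n, seed=seed)
    ev = make_task_events(5, 0.8, seed=seed)
    tl = make_field_timeline(T, (0.0, 0.0, 0.0), "smooth", seed=seed)
    ses = acquire_session(ph, coils, tl, ev, p, seed=seed, mode="physics")
    ops = train_operators(ses.calibration.calib, p)
    ests = estimate_session(ses, ops)
    rc = reconstruct_session(ses, ops, ests, "corrected")
    ru = reconstruct_session(ses, ops, ests, "uncorrected")
    return float(np.linalg.norm(rc.data - ru.data) / np.linalg.norm(ru.data))


def glm_validity(seed: int = 0, n_null: int = 30000, T: int = 300) -> dict:
    """Type-I error at z > 3.1, beta recovery bias and whitening quality."""
    from .task import HRFParams

    rng = np.random.default_rng(seed)
    ev = make_task_events(30, 0.8, seed=seed)
    tr = 1.282
    design = build_design(ev, T, tr, HRFParams())
    X = design.matrix

    # null voxels: white Gaussian noise
    Y = rng.standard_normal((T, n_null))
    res = fit_glm(Y.reshape(T, 1, 1, n_null), design)
    z = np.stack([res.zmaps[nm].ravel() for nm in design.names[1:]])
    fp = float(np.mean(z > 3.1))

    # beta recovery at high SNR
    beta_true = np.array([100.0, 2.0, 1.5, 1.0, 1.2])
    Y2 = X @ beta_true[:, None] + 0.01 * rng.standard_normal((T, 200))
    res2 = fit_glm(Y2.reshape(T, 1, 1, -1), design)
    bias = [abs(np.mean(res2.betas[nm]) - bt) / bt
            for nm, bt in zip(design.names[1:], beta_true[1:])]

    # AR(1) noise, whitened residual autocorrelation
    phi = 0.4
    e = rng.standard_normal((T, 500))
    for t in range(1, T):
        e[t] += phi * e[t - 1]
    ac = whitened_residual_autocorr(e.reshape(T, 1, 1, -1), design)
    return {
        "glm_type1_rate_z31": fp,
        "glm_type1_nominal": float(stats.norm.sf(3.1)),
        "glm_beta_recovery_max_bias": float(max(bias)),
        "glm_whitened_lag1_autocorr": float(abs(ac)),
    }


# ---------------------------------------------------------------------------
# Full study: simulate sessions, reconstruct both arms, compare
# ---------------------------------------------------------------------------

@dataclass
class SessionMetrics:
    """Everything retained per simulated session (maps dropped to save memory)."""

    seed: int
    estimates: pd.DataFrame
    dky_rmse_vs_truth: float
    bias_median: dict = field(default_factory=dict)      # arm -> median |bias|
    cov_median: dict = field(default_factory=dict)       # arm -> median CoV
    leakage: dict = field(default_factory=dict)          # arm -> alias energy
    tsnr_roi: dict = field(default_factory=dict)         # arm -> DataFrame
    n_supra: dict = field(default_factory=dict)          # arm -> int
    median_z_act: dict = field(default_factory=dict)     # arm -> float
    betas: dict = field(default_factory=dict)            # arm -> {reg: map}


@dataclass
class StudyResult:
    config: RunConfig
    sessions: list[SessionMetrics]
    masks: dict
    activation_regions: dict
    support: np.ndarray


def _leakage_footprint(support: np.ndarray, protocol: Protocol) -> np.ndarray:
    """Voxels where residual slice aliasing of the partner slice lands."""
    S = protocol.n_slices
    shift = protocol.n // (protocol.mb * protocol.r)
    foot = np.zeros_like(support)
    for g in protocol.slice_groups():
        for j, s in enumerate(g):
            partner = [q for q in g if q != s]
            for q in partner:
                for sh in (shift, -shift):
                    foot[s] |= np.roll(support[q], sh, axis=0)
    return foot & ~support


def run_study(config: RunConfig | None = None, n_sessions: int = 10,
              seed: int = 0, mode: str = "physics",
              progress: bool = False) -> StudyResult:
    """Simulate ``n_sessions`` perturbed runs and compare the two arms.

    One phantom/coil setup (one "animal") is shared; events, field
    timelines and noise differ per session.
    """
    cfg = config or default_config(seed)
    p = cfg.protocol
    ph = make_phantom(p.n, p.n_slices, seed=seed,
                      activation_amplitude=cfg.activation_amplitude)
    coils = make_coil_maps(p.n_coils, p.n, seed=seed)
    sigma = sigma_for_snr(ph, coils, p, cfg.snr)
    p = dataclasses.replace(p, sigma=sigma)
    amp = (cfg.amp_c0, cfg.amp_cx, cfg.amp_cy)
    seeds = _spawn_seeds(seed, 3 * n_sessions)

    truth_img = np.abs(ph.grid) * coils.rss()[None]
    support = ph.support
    foot = _leakage_footprint(support, p)
    masks = ph.tissue_masks

    from .task import HRFParams

    hrf = HRFParams(peak=cfg.hrf_peak, undershoot=cfg.hrf_undershoot,
                    ratio=cfg.hrf_ratio)
    sessions = []
    for i in range(n_sessions):
        s_ev, s_tl, s_ac = seeds[3 * i:3 * i + 3]
        events = make_task_events(cfg.n_trials, cfg.p_respond, seed=s_ev)
        timeline = make_field_timeline(cfg.n_frames, amp, cfg.field_model, seed=s_tl)
        ses = acquire_session(ph, coils, timeline, events, p, seed=s_ac, mode=mode,
                              hrf=hrf)
        ops = train_operators(ses.calibration.calib, p)
        ests = estimate_session(ses, ops, bound=cfg.dky_bound, tol=cfg.dky_tol)

        est_df = estimates_to_frame(ests)
        true_dky = np.repeat(timeline.as_array()[:, 2] * p.te, p.n_groups)
        dky_rmse = float(np.sqrt(np.mean((est_df["dky"].to_numpy() - true_dky) ** 2)))

        m = SessionMetrics(seed=s_ac, estimates=est_df, dky_rmse_vs_truth=dky_rmse)
        sb_ref = ses.calibration.sb_ref
        for arm in ARMS:
            series = reconstruct_session(ses, ops, ests, arm)
            b = bias_map(series, sb_ref, mask=support)
            cv = cov_map(series)
            ts = tsnr_map(series)
            m.bias_median[arm] = float(np.median(np.abs(b[support])))
            m.cov_median[arm] = float(np.median(cv[support][np.isfinite(cv[support])]))
            sq = np.mean(series.data.astype(float) ** 2, axis=0)
            m.leakage[arm] = float(sq[foot].mean() / (truth_img[support] ** 2).mean())
            m.tsnr_roi[arm] = roi_summary(ts, masks)

            pre = preprocess_series(series, cfg.highpass_cutoff_s, cfg.smooth_fwhm_mm)
            import warnings as _warnings

            with _warnings.catch_warnings():
                # trailing trial events past the scan end are expected here
                _warnings.simplefilter("ignore", UserWarning)
                design = build_design(events, cfg.n_frames, p.tr, hrf)
            res = fit_glm(pre, design)
            n_sup, med_z, betas = 0, [], {}
            for rname, (rmask, reg) in ph.activation_regions.items():
                z = res.zmaps[reg]
                n_sup += int(np.sum(z[support] > cfg.z_threshold))
                med_z.append(np.median(z[rmask]))
                betas[reg] = res.betas[reg]
            m.n_supra[arm] = n_sup
            m.median_z_act[arm] = float(np.mean(med_z))
            m.betas[arm] = betas
        sessions.append(m)
        if progress:
            print(f"session {i + 1}/{n_sessions}: "
                  f"bias {m.bias_median['corrected']:.4f}/{m.bias_median['uncorrected']:.4f} "
                  f"supra {m.n_supra['corrected']}/{m.n_supra['uncorrected']}")
    return StudyResult(config=cfg, sessions=sessions, masks=masks,
                       activation_regions=ph.activation_regions, support=support)


def activated_rois(result: StudyResult, regressor: str, min_voxels: int = 10) -> list[str]:
    """ROIs overlapping the true activation region of a regressor."""
    region = None
    for _, (mask, reg) in result.activation_regions.items():
        if reg == regressor:
            region = mask
    return [name for name, m in result.masks.items()
            if np.sum(m & region) >= min_voxels]


def study_metrics(result: StudyResult, reliability_seed: int = 0) -> dict:
    """Headline arm-comparison metrics of a study (the evaluation chain)."""
    ses = result.sessions
    S = len(ses)
    out: dict = {"n_sessions": S}

    # reconstruction fidelity (bias / CoV / leakage medians, per session)
    for key, attr in (("bias", "bias_median"), ("cov", "cov_median"),
                      ("leakage", "leakage")):
        c = np.array([getattr(m, attr)["corrected"] for m in ses])
        u = np.array([getattr(m, attr)["uncorrected"] for m in ses])
        out[f"{key}_median_corrected"] = float(np.median(c))
        out[f"{key}_median_uncorrected"] = float(np.median(u))
        out[f"{key}_fraction_sessions_improved"] = float(np.mean(c < u))

    # paired tSNR comparison across sessions, BH-FDR across ROIs
    comp = paired_compare([m.tsnr_roi["corrected"] for m in ses],
                          [m.tsnr_roi["uncorrected"] for m in ses])
    valid = comp[~comp["excluded"]]
    out["tsnr_fraction_rois_improved"] = float(np.mean(valid["delta"] > 0))
    out["tsnr_min_q"] = float(np.nanmin(valid["q"]))
    out["tsnr_n_rois_significant"] = int(np.sum(valid["significant"] & (valid["delta"] > 0)))

    # activation sensitivity ordering
    supra_ge = np.array([m.n_supra["corrected"] >= m.n_supra["uncorrected"] for m in ses])
    medz_ge = np.array([m.median_z_act["corrected"] >= m.median_z_act["uncorrected"]
                        for m in ses])
    out["activation_sessions_supra_ge"] = int(supra_ge.sum())
    out["activation_sessions_medianz_ge"] = int(medz_ge.sum())
    out["activation_sessions_both_ge"] = int((supra_ge & medz_ge).sum())
    out["estimate_dky_rmse_mean"] = float(np.mean([m.dky_rmse_vs_truth for m in ses]))
    return out


def reliability_metrics(result: StudyResult, n_folds: int = 10,
                        seed: int = 0) -> dict:
    """Split-half reliability of second-level activation, per arm, in the
    ROIs overlapping true activation."""
    out: dict = {}
    rs, biases = {a: [] for a in ARMS}, {a: [] for a in ARMS}
    for regressor in ("offer", "motor_response"):
        rois = activated_rois(result, regressor)
        masks = {k: result.masks[k] for k in rois}
        for arm in ARMS:
            maps = np.stack([m.betas[arm][regressor] for m in result.sessions])
            rel = split_half_reliability(maps, masks, n_folds=n_folds, seed=seed,
                                         z_thr=result.config.z_threshold)
            fm = rel.fold_mean()
            rs[arm].append(fm["r"].to_numpy())
            biases[arm].append(fm["bias"].to_numpy())
    for arm in ARMS:
        r = np.concatenate(rs[arm])
        b = np.concatenate(biases[arm])
        out[f"reliability_r_{arm}"] = float(np.nanmean(r))
        out[f"reliability_bias_{arm}"] = float(np.nanmean(b))
    out["reliability_r_delta"] = (out["reliability_r_corrected"]
                                  - out["reliability_r_uncorrected"])
    out["reliability_bias_delta"] = (out["reliability_bias_corrected"]
                                     - out["reliability_bias_uncorrected"])
    return out
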