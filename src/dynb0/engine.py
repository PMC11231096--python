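"""SMS-EPI acquisition simulation and the HDF5 session container.

Two field-effect modes are available per frame:

* ``"physics"`` — each EPI line n is the readout transform of the object
  modulated by ``exp(i*2*pi*df(x,y)*t_n)``, with t_n the line's acquisition
  time; the phase therefore accrues differently across the echo train.
* ``"translate"`` — the idealized model the estimator assumes: imaging lines
  receive the exact echo-time-referenced k-space translation
  ``(dkx, dky) = (cx, cy)*TE`` plus the global phase ``phi0 = 2*pi*c0*TE``;
  navigator lines receive the same translation scaled by ``t_nav/TE``
  (linear-in-time phase accrual, evaluated at the navigator time).

Both modes share CAIPI slice encoding, in-plane undersampling, even/odd
readout (Nyquist ghost) phases, and complex Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .fourier import cfft, cfft2, cifft, image_grids, translation_ramp
from .phantom import CoilSensitivities, FieldState, FieldTimeline, Phantom
from .protocol import Protocol
from .task import EventList, HRFParams, bold_timecourses

NAV_POLARITY = np.array([1, -1, 1])  # even, odd, even readout polarity


@dataclass
class KSpaceFrame:
    """One excitation's collapsed, in-plane-undersampled multi-coil k-space.

    data : (C, N_lines, N) complex, acquired ky lines only.
    nav : (C, 3, N) complex non-phase-encoded navigator lines.
    line_times / nav_times : seconds relative to excitation.
    """

    data: np.ndarray
    nav: np.ndarray
    line_times: np.ndarray
    nav_times: np.ndarray
    ky: np.ndarray                  # acquired ky, grid units
    line_polarity: np.ndarray       # +1 even, -1 odd readout
    nav_polarity: np.ndarray
    frame_index: int = 0
    group: int = 0
    applied_estimate: tuple | None = None

    def copy(self) -> "KSpaceFrame":
        return dataclasses.replace(
            self, data=self.data.copy(), nav=self.nav.copy(),
            line_times=self.line_times.copy(), nav_times=self.nav_times.copy(),
            ky=self.ky.copy(), line_polarity=self.line_polarity.copy(),
            nav_polarity=self.nav_polarity.copy(),
        )


@dataclass
class CalibrationSet:
    """Zero-field calibration products.

    calib : (S, C, N, N) fully sampled per-slice k-space.
    sb_ref_coils : (S, C, N, N) single-band EPI coil images.
    sb_ref : (S, N, N) RSS-combined single-band reference images.
    nav_ref : (G, C, 3, N) zero-field navigators per slice group.
    """

    calib: np.ndarray
    sb_ref_coils: np.ndarray
    sb_ref: np.ndarray
    nav_ref: np.ndarray


@dataclass
class SessionTruth:
    timeline: FieldTimeline
    phantom: Phantom
    events: EventList
    hrf: HRFParams
    mode: str
    seed: int


@dataclass
class Session:
    """A simulated run: frames[t][g] over T time-points and G slice groups."""

    frames: list[list[KSpaceFrame]]
    calibration: CalibrationSet
    protocol: Protocol
    truth: SessionTruth | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_groups(self) -> int:
        return len(self.frames[0])


def apply_ghost(lines: np.ndarray, polarity: np.ndarray, theta0: float,
                theta1: float, sign: float = 1.0) -> np.ndarray:
    """Multiply even/odd lines by exp(+-i*(theta0+theta1*x)/2) in hybrid space.

    ``sign=+1`` injects the corruption; ``sign=-1`` undoes it. ``theta1`` is
    in radians per readout sample measured from the center sample.
    """
    n = lines.shape[-1]
    phg = theta0 + theta1 * (np.arange(n) - n // 2)
    hyb = cifft(lines, axis=-1)
    rot = np.exp(1j * sign * 0.5 * np.outer(polarity, phg))  # (L, N)
    hyb = hyb * rot[None]
    return cfft(hyb, axis=-1)


def acquire_frame(
    obj_slices: np.ndarray,
    coils: CoilSensitivities,
    fieldstate: FieldState,
    protocol: Protocol,
    mode: str = "physics",
    rng: np.random.Generator | int | None = None,
    frame_index: int = 0,
    group: int = 0,
) -> KSpaceFrame:
    """Simulate one SMS-EPI excitation of ``obj_slices`` (MB slices)."""
    if mode not in ("physics", "translate"):
        raise ValueError(f"unknown acquisition mode: {mode!r}")
    if obj_slices.shape[0] != protocol.mb:
        raise ValueError("object slice count must equal the multiband factor")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n = protocol.n
    ky = protocol.acquired_ky
    rows = ky + n // 2
    t_lines = protocol.line_times()
    t_nav = protocol.nav_times()
    maps = coils.maps
    L = len(ky)
    C = coils.n_coils

    data = np.zeros((C, L, n), dtype=complex)
    nav = np.zeros((C, 3, n), dtype=complex)

    if mode == "physics":
        Y, X = image_grids(n)
        omega = 2.0 * np.pi * (fieldstate.c0 + fieldstate.cx * X + fieldstate.cy * Y)
        # centered-DFT row extraction: row ky of cfft2(img) equals the 1-D
        # centered FFT along x of sum_y img[y, x] * exp(-2i pi ky (y-N/2)/N)
        wy = np.exp(-2j * np.pi * np.outer(ky, (np.arange(n) - n // 2) / n))
        for j in range(protocol.mb):
            cimg = maps * obj_slices[j][None]  # (C, N, N)
            mod = np.exp(1j * omega[None] * t_lines[:, None, None])  # (L, N, N)
            proj = np.einsum("cyx,lyx->clx", cimg, mod * wy[:, :, None])
            lines = cfft(proj, axis=-1)
            lines *= protocol.caipi_phase(ky, j)[None, :, None]
            data += lines
            # navigators: non-phase-encoded (ky = 0), no CAIPI phase
            modn = np.exp(1j * omega[None] * t_nav[:, None, None])
            nav += cfft(np.einsum("cyx,lyx->clx", cimg, modn), axis=-1)
    else:  # translate
        phi0, dkx, dky = fieldstate.to_kspace(protocol.te)
        s = float(np.mean(t_nav)) / protocol.te
        ramp_img = translation_ramp(n, dkx, dky, phi0)
        ramp_nav = translation_ramp(n, dkx * s, dky * s, phi0 * s)
        for j in range(protocol.mb):
            cimg = maps * obj_slices[j][None]
            F = cfft2(cimg * ramp_img[None])
            lines = F[:, rows, :] * protocol.caipi_phase(ky, j)[None, :, None]
            data += lines
            Fn = cfft2(cimg * ramp_nav[None])
            nav += np.repeat(Fn[:, n // 2, :][:, None, :], 3, axis=1)

    line_pol = np.where(np.arange(L) % 2 == 0, 1, -1)
    data = apply_ghost(data, line_pol, protocol.ghost_theta0,
                       protocol.ghost_theta1, sign=+1.0)
    nav = apply_ghost(nav, NAV_POLARITY, protocol.ghost_theta0,
                      protocol.ghost_theta1, sign=+1.0)

    if protocol.sigma > 0:
        data = data + protocol.sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape))
        nav = nav + protocol.sigma * (
            rng.standard_normal(nav.shape) + 1j * rng.standard_normal(nav.shape))

    return KSpaceFrame(
        data=data, nav=nav, line_times=t_lines, nav_times=t_nav, ky=ky,
        line_polarity=line_pol, nav_polarity=NAV_POLARITY.copy(),
        frame_index=frame_index, group=group,
    )


def sigma_for_snr(phantom: Phantom, coils: CoilSensitivities, protocol: Protocol,
                  snr: float) -> float:
    """k-space noise sigma giving about the requested coil-combined image SNR.

    The centered inverse FFT scales k-space noise by 1/N per axis pair, so
    per-coil image noise is sigma/N; with unit-RSS maps the combined
    magnitude noise is about the same.
    """
    sbar = float(np.mean(np.abs(phantom.grid[0])[phantom.support[0]]))
    return sbar * protocol.n / snr


def acquire_calibration(
    phantom: Phantom,
    coils: CoilSensitivities,
    protocol: Protocol,
    seed: int = 0,
) -> CalibrationSet:
    """Zero-field calibration: fully sampled k-space, single-band EPI
    references (R-undersampled, GRAPPA-filled, RSS-combined), and reference
    navigators per slice group.

    The fully sampled calibration is modeled as a clean (segmented,
    ghost-free) acquisition; the single-band EPI reference goes through the
    same ghost/undersampling chain as the functional frames.
    """
    from .calib import train_inplane_kernel
    from .recon import coil_combine, inplane_fill, lines_to_grid, nyquist_correct_lines
    from .correct import ghost_params_from_nav
    from .fourier import cifft2

    rng = np.random.default_rng(seed)
    n, C, S = protocol.n, protocol.n_coils, protocol.n_slices
    calib = np.empty((S, C, n, n), dtype=complex)
    for s in range(S):
        F = cfft2(coils.maps * phantom.grid[s][None])
        if protocol.sigma > 0:
            F = F + protocol.sigma * (rng.standard_normal(F.shape)
                                      + 1j * rng.standard_normal(F.shape))
        calib[s] = F

    kernel = train_inplane_kernel(calib, protocol)

    sb_proto = dataclasses.replace(protocol, mb=1, n_slices=protocol.n_groups)
    sb_coils = np.empty((S, C, n, n), dtype=complex)
    sb_ref = np.empty((S, n, n))
    zero = FieldState()
    for s in range(S):
        fr = acquire_frame(phantom.grid[s][None], coils, zero, sb_proto,
                           mode="physics", rng=rng)
        ghost = ghost_params_from_nav(fr.nav, fr.nav_polarity)
        dat = nyquist_correct_lines(fr.data, fr.line_polarity, ghost)
        grid = lines_to_grid(dat, fr.ky, n)
        full = inplane_fill(grid, kernel, protocol)
        imgs = cifft2(full)
        sb_coils[s] = imgs
        sb_ref[s] = coil_combine(imgs)

    groups = protocol.slice_groups()
    nav_ref = np.empty((len(groups), C, 3, n), dtype=complex)
    for g, sl in enumerate(groups):
        fr = acquire_frame(phantom.grid[sl], coils, zero, protocol,
                           mode="physics", rng=rng, group=g)
        nav_ref[g] = fr.nav

    return CalibrationSet(calib=calib, sb_ref_coils=sb_coils, sb_ref=sb_ref,
                          nav_ref=nav_ref)


def acquire_session(
    phantom: Phantom,
    coils: CoilSensitivities,
    timeline: FieldTimeline,
    events: EventList,
    protocol: Protocol,
    seed: int = 0,
    hrf: HRFParams | None = None,
    mode: str = "physics",
) -> Session:
    """Simulate a full run: calibration plus T frames of all slice groups."""
    hrf = hrf or HRFParams()
    T = len(timeline)
    rng = np.random.default_rng(seed)
    calibration = acquire_calibration(phantom, coils, protocol,
                                      seed=int(rng.integers(2**31)))
    tcs = bold_timecourses(events, T, protocol.tr, hrf)
    groups = protocol.slice_groups()

    frames: list[list[KSpaceFrame]] = []
    mod = np.ones_like(phantom.activation_map)
    for t in range(T):
        mod.fill(1.0)
        for _, (mask, reg) in phantom.activation_regions.items():
            mod[mask] = 1.0 + phantom.activation_map[mask] * tcs[reg][t]
        obj_t = phantom.grid * mod
        row = []
        for g, sl in enumerate(groups):
            row.append(acquire_frame(obj_t[sl], coils, timeline[t], protocol,
                                     mode=mode, rng=rng, frame_index=t, group=g))
        frames.append(row)

    truth = SessionTruth(timeline=timeline, phantom=phantom, events=events,
                         hrf=hrf, mode=mode, seed=seed)
    return Session(frames=frames, calibration=calibration, protocol=protocol,
                   truth=truth)


# ---------------------------------------------------------------------------
# HDF5 persistence: complex arrays stored as paired float arrays (..., 2)
# ---------------------------------------------------------------------------

def _c2f(arr: np.ndarray) -> np.ndarray:
    return np.stack([arr.real, arr.imag], axis=-1)


def _f2c(arr: np.ndarray) -> np.ndarray:
    return arr[..., 0] + 1j * arr[..., 1]


def save_session(session: Session, path: str | Path) -> None:
    """Write the session to HDF5 (axes documented in attributes)."""
    with h5py.File(path, "w") as f:
        fg = f.create_group("frames")
        for t, row in enumerate(session.frames):
            for g, fr in enumerate(row):
                grp = fg.create_group(f"{t}/{g}")
                grp.create_dataset("data", data=_c2f(fr.data))
                grp.create_dataset("nav", data=_c2f(fr.nav))
                grp.create_dataset("line_times", data=fr.line_times)
                grp.create_dataset("nav_times", data=fr.nav_times)
                grp.create_dataset("ky", data=fr.ky)
                grp.create_dataset("line_polarity", data=fr.line_polarity)
                grp.create_dataset("nav_polarity", data=fr.nav_polarity)
                grp.attrs["axes"] = "coil, ky, kx (complex as trailing [re, im])"
        cg = f.create_group("calibration")
        cal = session.calibration
        cg.create_dataset("calib", data=_c2f(cal.calib))
        cg.create_dataset("sb_ref_coils", data=_c2f(cal.sb_ref_coils))
        cg.create_dataset("sb_ref", data=cal.sb_ref)
        cg.create_dataset("nav_ref", data=_c2f(cal.nav_ref))
        pg = f.create_group("protocol")
        for k, v in dataclasses.asdict(session.protocol).items():
            pg.attrs[k] = v
        if session.truth is not None:
            tg = f.create_group("truth")
            tr = session.truth
            tg.create_dataset("timeline", data=tr.timeline.as_array())
            tg.create_dataset("phantom_grid", data=_c2f(tr.phantom.grid))
            tg.create_dataset("activation_map", data=tr.phantom.activation_map)
            tg.create_dataset("support", data=tr.phantom.support)
            mg = tg.create_group("tissue_masks")
            for name, m in tr.phantom.tissue_masks.items():
                mg.create_dataset(name, data=m)
            ag = tg.create_group("activation_regions")
            for name, (m, reg) in tr.phantom.activation_regions.items():
                d = ag.create_dataset(name, data=m)
                d.attrs["regressor"] = reg
            eg = tg.create_group("events")
            ev = tr.events
            for k in ("offer", "gocue", "responded", "response", "outcome"):
                eg.create_dataset(k, data=getattr(ev, k))
            tg.attrs["mode"] = tr.mode
            tg.attrs["seed"] = tr.seed
            for k, v in dataclasses.asdict(tr.hrf).items():
                tg.attrs[f"hrf_{k}"] = v


def load_session(path: str | Path) -> Session:
    """Read a session written by :func:`save_session`."""
    from .phantom import Phantom

    with h5py.File(path, "r") as f:
        pattrs = dict(f["protocol"].attrs)
        pattrs = {k: (bool(v) if k == "caipi" else v) for k, v in pattrs.items()}
        pattrs["n"] = int(pattrs["n"])
        for k in ("n_slices", "n_coils", "mb", "r"):
            pattrs[k] = int(pattrs[k])
        protocol = Protocol(**pattrs)
        fg = f["frames"]
        T = len(fg)
        frames = []
        for t in range(T):
            row = []
            tg_ = fg[str(t)]
            for g in range(len(tg_)):
                grp = tg_[str(g)]
                row.append(KSpaceFrame(
                    data=_f2c(grp["data"][()]), nav=_f2c(grp["nav"][()]),
                    line_times=grp["line_times"][()], nav_times=grp["nav_times"][()],
                    ky=grp["ky"][()], line_polarity=grp["line_polarity"][()],
                    nav_polarity=grp["nav_polarity"][()], frame_index=t, group=g))
            frames.append(row)
        cg = f["calibration"]
        calibration = CalibrationSet(
            calib=_f2c(cg["calib"][()]), sb_ref_coils=_f2c(cg["sb_ref_coils"][()]),
            sb_ref=cg["sb_ref"][()], nav_ref=_f2c(cg["nav_ref"][()]))
        truth = None
        if "truth" in f:
            tg = f["truth"]
            masks = {k: tg["tissue_masks"][k][()].astype(bool)
                     for k in tg["tissue_masks"]}
            regions = {k: (tg["activation_regions"][k][()].astype(bool),
                           tg["activation_regions"][k].attrs["regressor"])
                       for k in tg["activation_regions"]}
            phantom = Phantom(grid=_f2c(tg["phantom_grid"][()]),
                              tissue_masks=masks,
                              activation_map=tg["activation_map"][()],
                              activation_regions=regions,
                              support=tg["support"][()].astype(bool))
            ev = EventList(*(tg["events"][k][()] for k in
                             ("offer", "gocue", "responded", "response", "outcome")))
            ev.responded = ev.responded.astype(bool)
            hrf = HRFParams(peak=float(tg.attrs["hrf_peak"]),
                            undershoot=float(tg.attrs["hrf_undershoot"]),
                            ratio=float(tg.attrs["hrf_ratio"]),
                            shape=float(tg.attrs["hrf_shape"]))
            truth = SessionTruth(
                timeline=FieldTimeline.from_array(tg["timeline"][()]),
                phantom=phantom, events=ev, hrf=hrf,
                mode=str(tg.attrs["mode"]), seed=int(tg.attrs["seed"]))
    return Session(frames=frames, calibration=calibration, protocol=protocol,
                   truth=truth)


def save_operators(path: str | Path, operators) -> None:
    """Store trained operators in the session HDF5 under /operators/*."""
    with h5py.File(path, "a") as f:
        if "operators" in f:
            del f["operators"]
        og = f.create_group("operators")
        ig = og.create_group("inplane")
        ig.create_dataset("weights", data=_c2f(operators.inplane.weights))
        ig.attrs["dys"] = operators.inplane.dys
        ig.attrs["dxs"] = operators.inplane.dxs
        ig.attrs["lam"] = operators.inplane.lam
        for g, sk in enumerate(operators.slices):
            sg = og.create_group(f"slices/{g}")
            for j, w in enumerate(sk.weights):
                sg.create_dataset(str(j), data=_c2f(w))
            sg.attrs["dys"] = sk.dys
            sg.attrs["dxs"] = sk.dxs
            sg.attrs["lam"] = sk.lam
            sg.attrs["caipi"] = sk.caipi
        kg = og.create_group("shift_ky")
        kg.create_dataset("Wx", data=_c2f(operators.shift_ky.Wx))
        kg.attrs["axis"] = operators.shift_ky.axis
        kg.attrs["lam"] = operators.shift_ky.lam
        kg.attrs["residual"] = operators.shift_ky.residual
        kg.attrs["w"] = -1 if operators.shift_ky.w is None else operators.shift_ky.w


def load_operators(path: str | Path):
    """Load operators written by :func:`save_operators`."""
    from .calib import GrappaKernel, OperatorSet, ShiftOperator, SliceKernels

    with h5py.File(path, "r") as f:
        og = f["operators"]
        ig = og["inplane"]
        inplane = GrappaKernel(weights=_f2c(ig["weights"][()]),
                               dys=tuple(ig.attrs["dys"]),
                               dxs=tuple(ig.attrs["dxs"]),
                               lam=float(ig.attrs["lam"]))
        slices = []
        for g in sorted(og["slices"], key=int):
            sg = og["slices"][g]
            weights = [_f2c(sg[str(j)][()]) for j in range(len(sg))]
            slices.append(SliceKernels(weights=weights, dys=tuple(sg.attrs["dys"]),
                                       dxs=tuple(sg.attrs["dxs"]),
                                       lam=float(sg.attrs["lam"]),
                                       caipi=bool(sg.attrs["caipi"])))
        kg = og["shift_ky"]
        Wx = _f2c(kg["Wx"][()])
        w = int(kg.attrs["w"])
        shift_ky = ShiftOperator(axis=str(kg.attrs["axis"]), Wx=Wx, n=Wx.shape[0],
                                 lam=float(kg.attrs["lam"]),
                                 residual=float(kg.attrs["residual"]),
                                 w=None if w < 0 else w)
    return OperatorSet(inplane=inplane, slices=slices, shift_ky=shift_ky)


def save_estimates(path: str | Path, estimates_df) -> None:
    """Store per-frame perturbation estimates under /estimates/* (one dataset
    per column of the tidy estimates table)."""
    with h5py.File(path, "a") as f:
        if "estimates" in f:
            del f["estimates"]
        eg = f.create_group("estimates")
        for col in estimates_df.columns:
            eg.create_dataset(col, data=estimates_df[col].to_numpy())


def load_estimates(path: str | Path):
    """Load the estimates table written by :func:`save_estimates`."""
    import pandas as pd

    with h5py.File(path, "r") as f:
        eg = f["estimates"]
        return pd.DataFrame({col: eg[col][()] for col in eg})
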