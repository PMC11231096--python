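"""Per-frame estimation of ghost parameters and dynamic off-resonance
(phi0, dkx, dky) from navigators, and application of the correction.

Estimation order: Nyquist ghost parameters -> zeroth order and readout
translation (phi0, dkx) by a weighted projection-phase fit -> phase-encode
translation dky by a 1-D search over fractional shift-operator powers.  Each
step conditions the next.

Navigators are acquired before the echo train, so they sense the linear
field at their own time t_nav rather than at the echo time.  Internally all
three quantities are fitted in navigator-time units and rescaled by
TE / mean(t_nav) to echo-time-referenced values, which is what the imaging
data correction needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calib import OperatorSet, ShiftOperator
from .engine import KSpaceFrame, Session, apply_ghost
from .fourier import cifft, cfft, coords
from .protocol import Protocol


@dataclass(frozen=True)
class GhostParams:
    """Even/odd readout phase model: theta0 (rad) + theta1 (rad/sample)."""

    theta0: float
    theta1: float


@dataclass
class PerturbationEstimate:
    """Echo-time-referenced perturbation of one frame / slice group.

    phi0 in radians; dkx, dky in grid units; ``objective`` is the final
    normalized dky-search objective (for QC); ``ambiguous`` flags a
    non-unimodal coarse search.
    """

    phi0: float = 0.0
    dkx: float = 0.0
    dky: float = 0.0
    objective: float = 0.0
    ambiguous: bool = False
    ghost: GhostParams | None = None

    def is_zero(self) -> bool:
        return self.phi0 == 0.0 and self.dkx == 0.0 and self.dky == 0.0


def ghost_params_from_nav(nav: np.ndarray, polarity: np.ndarray) -> GhostParams:
    """Estimate (theta0, theta1) from alternating-polarity navigator lines.

    Lines are transformed to projection (x) space; the magnitude-weighted
    linear phase of odd * conj(even) is fitted.  Even lines at times
    bracketing the odd line are averaged first so that any linear-in-time
    field phase cancels to first order.
    """
    nav = np.asarray(nav)
    if np.linalg.norm(nav) < 1e-30:
        raise ValueError("all-zero navigator")
    polarity = np.asarray(polarity)
    if not (np.any(polarity > 0) and np.any(polarity < 0)):
        raise ValueError("need navigator lines of both polarities")
    hyb = cifft(nav, axis=-1)  # (C, 3, N)
    p_even = hyb[:, polarity > 0].mean(axis=1)
    p_odd = hyb[:, polarity < 0].mean(axis=1)
    prod = np.sum(p_odd * np.conj(p_even), axis=0)  # (N,)
    w = np.abs(prod)
    n = prod.shape[-1]
    xs = np.arange(n) - n // 2
    # odd lines carry exp(-i*phi_g/2), even exp(+i*phi_g/2): phase = -phi_g
    phase = np.angle(prod)
    A = np.column_stack([np.ones(n), xs]) * np.sqrt(w)[:, None]
    b = phase * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return GhostParams(theta0=-float(coef[0]), theta1=-float(coef[1]))


def correct_nav_ghost(nav: np.ndarray, polarity: np.ndarray,
                      ghost: GhostParams) -> np.ndarray:
    """Undo the even/odd ghost phases on navigator lines."""
    return apply_ghost(nav, polarity, ghost.theta0, ghost.theta1, sign=-1.0)


def _mean_projection(nav: np.ndarray) -> np.ndarray:
    """Mean over navigator lines in projection (x) space: (C, N)."""
    return cifft(nav, axis=-1).mean(axis=1)


def estimate_phi0_dkx(nav_t: np.ndarray, nav_ref: np.ndarray) -> tuple[float, float]:
    """Fit phase(P_t conj(P_ref)) = phi0 + 2 pi dkx x over the object support.

    Both navigator sets must already be ghost-corrected.  Returns
    navigator-time (phi0, dkx); the caller rescales to echo time.
    """
    p_t = _mean_projection(np.asarray(nav_t))
    p_r = _mean_projection(np.asarray(nav_ref))
    if np.linalg.norm(p_r) < 1e-30:
        raise ValueError("reference navigator has no support")
    prod = np.sum(p_t * np.conj(p_r), axis=0)
    w = np.abs(prod)
    if w.max() <= 0:
        raise ValueError("no overlapping navigator support")
    n = prod.shape[-1]
    x = coords(n)
    A = np.column_stack([np.ones(n), 2 * np.pi * x]) * np.sqrt(w)[:, None]
    b = np.angle(prod) * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(coef[0]), float(coef[1])


def remove_phi0_dkx(nav: np.ndarray, phi0: float, dkx: float) -> np.ndarray:
    """Undo a global phase and readout translation on navigator lines."""
    hyb = cifft(nav, axis=-1)
    n = nav.shape[-1]
    x = coords(n)
    hyb = hyb * np.exp(-1j * (phi0 + 2 * np.pi * dkx * x))[None, None, :]
    return cfft(hyb, axis=-1)


def _golden_section(f, a: float, b: float, tol: float) -> tuple[float, float]:
    invphi = (np.sqrt(5) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = (a + b) / 2
    return x, f(x)


def estimate_dky(nav_t: np.ndarray, nav_ref: np.ndarray, op: ShiftOperator,
                 bound: float = 0.75, tol: float = 0.005,
                 coarse_step: float = 0.05) -> tuple[float, float, bool]:
    """Phase-encode translation by 1-D search over fractional shifts.

    Minimizes ``|| translate(nav_ref, delta) - nav_t ||^2 / ||nav_t||^2``
    on a coarse grid then refines by golden section.  ``nav_t`` must have
    ghost, phi0 and dkx effects removed first.  Returns
    (dky, objective, ambiguous-flag), all in navigator-time units.
    """
    line_t = np.asarray(nav_t).mean(axis=1)   # (C, N)
    line_r = np.asarray(nav_ref).mean(axis=1)
    norm = np.linalg.norm(line_t) ** 2
    if norm < 1e-30:
        raise ValueError("empty navigator")

    def objective(delta: float) -> float:
        diff = op.translate(line_r, delta) - line_t
        return float(np.linalg.norm(diff) ** 2 / norm)

    # symmetric coarse grid that always contains exactly 0
    pos = np.arange(coarse_step, bound + coarse_step / 2, coarse_step)
    grid = np.concatenate([-pos[::-1], [0.0], pos])
    vals = np.array([objective(d) for d in grid])
    i0 = int(np.argmin(vals))
    # identical navigators: the reference point is an exact zero
    if vals[i0] < 1e-20:
        return float(grid[i0]), float(vals[i0]), False
    # flag separated near-global minima (non-unimodal objective)
    local_min = np.where((np.r_[True, vals[1:] < vals[:-1]]
                          & np.r_[vals[:-1] < vals[1:], True]))[0]
    close = local_min[vals[local_min] < vals[i0] * 1.01 + 1e-12]
    ambiguous = bool(np.any(np.abs(close - i0) > 2))
    a = grid[max(i0 - 1, 0)]
    b = grid[min(i0 + 1, len(grid) - 1)]
    dky, obj = _golden_section(objective, a, b, tol)
    return float(dky), float(obj), ambiguous


def estimate_dkx_operator(nav_t: np.ndarray, nav_ref: np.ndarray,
                          op_kx: ShiftOperator, bound: float = 0.75,
                          tol: float = 0.005) -> tuple[float, float, bool]:
    """Readout translation by operator search instead of the projection-phase
    fit: the same 1-D objective as :func:`estimate_dky`, with a kx-axis shift
    operator (train with ``axis="kx"``, width 1 for single-line navigators).
    The global phase should be removed from ``nav_t`` first.
    """
    return estimate_dky(nav_t, nav_ref, op_kx, bound=bound, tol=tol)


def correct_frame(frame: KSpaceFrame, est: PerturbationEstimate,
                  op_ky: ShiftOperator, protocol: Protocol) -> KSpaceFrame:
    """Undo an estimated perturbation on a frame (data and navigators).

    Global phase exp(-i phi0); readout translation -dkx as an exact
    projection-space linear phase (readout is fully sampled); phase-encode
    translation -dky via fractional shift-operator powers on every line.
    """
    if not np.all(np.isfinite([est.phi0, est.dkx, est.dky])):
        raise ValueError("non-finite perturbation estimate")
    out = frame.copy()
    if est.is_zero():
        out.applied_estimate = (0.0, 0.0, 0.0)
        return out
    x = coords(protocol.n)
    ramp = np.exp(-1j * (est.phi0 + 2 * np.pi * est.dkx * x))
    for name in ("data", "nav"):
        arr = getattr(out, name)
        hyb = cifft(arr, axis=-1) * ramp[None, None, :]
        arr = cfft(hyb, axis=-1)
        if est.dky != 0.0:
            arr = op_ky.translate(arr, -est.dky)
        setattr(out, name, arr)
    out.applied_estimate = (est.phi0, est.dkx, est.dky)
    return out


def estimate_frame(frame: KSpaceFrame, nav_ref_corr: np.ndarray,
                   op_ky: ShiftOperator, protocol: Protocol,
                   bound: float = 0.75, tol: float = 0.005) -> PerturbationEstimate:
    """Full per-frame estimation chain against a ghost-corrected reference."""
    ghost = ghost_params_from_nav(frame.nav, frame.nav_polarity)
    nav_c = correct_nav_ghost(frame.nav, frame.nav_polarity, ghost)
    phi0_n, dkx_n = estimate_phi0_dkx(nav_c, nav_ref_corr)
    nav_c2 = remove_phi0_dkx(nav_c, phi0_n, dkx_n)
    scale = protocol.te / float(np.mean(protocol.nav_times()))
    # the search bound is specified in echo-time-referenced grid units;
    # navigators sense the shorter accrual time, hence the tighter raw bound
    dky_n, obj, amb = estimate_dky(nav_c2, nav_ref_corr, op_ky,
                                   bound=bound / scale, tol=tol)
    return PerturbationEstimate(phi0=phi0_n * scale, dkx=dkx_n * scale,
                                dky=dky_n * scale, objective=obj,
                                ambiguous=amb, ghost=ghost)


def reference_navigators(session: Session, use_calibration_nav: bool = False
                         ) -> list[np.ndarray]:
    """Ghost-corrected reference navigators per slice group.

    Default: frame 0's navigators (the zero-field reference frame); with
    ``use_calibration_nav`` the calibration-scan navigators are used instead.
    """
    refs = []
    for g in range(session.n_groups):
        if use_calibration_nav:
            nav = session.calibration.nav_ref[g]
            pol = session.frames[0][g].nav_polarity
        else:
            fr = session.frames[0][g]
            nav, pol = fr.nav, fr.nav_polarity
        ghost = ghost_params_from_nav(nav, pol)
        refs.append(correct_nav_ghost(nav, pol, ghost))
    return refs


def estimate_session(session: Session, operators: OperatorSet,
                     bound: float = 0.75, tol: float = 0.005,
                     use_calibration_nav: bool = False
                     ) -> list[list[PerturbationEstimate]]:
    """Per-frame, per-slice-group perturbation estimates for a session."""
    if session.calibration is None:
        raise ValueError("session has no calibration data")
    refs = reference_navigators(session, use_calibration_nav)
    out = []
    for row in session.frames:
        out.append([estimate_frame(fr, refs[fr.group], operators.shift_ky,
                                   session.protocol, bound=bound, tol=tol)
                    for fr in row])
    return out


def estimates_to_frame(estimates: list[list[PerturbationEstimate]]) -> pd.DataFrame:
    """Flatten estimates into a tidy table (one row per frame and group)."""
    rows = []
    for t, row in enumerate(estimates):
        for g, e in enumerate(row):
            rows.append(dict(frame=t, group=g, phi0=e.phi0, dkx=e.dkx,
                             dky=e.dky, objective=e.objective,
                             ambiguous=e.ambiguous,
                             theta0=e.ghost.theta0 if e.ghost else np.nan,
                             theta1=e.ghost.theta1 if e.ghost else np.nan))
    return pd.DataFrame(rows)
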