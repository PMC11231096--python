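"""Image reconstruction: Nyquist ghost correction, SMS unaliasing, in-plane
GRAPPA completion, coil combination, and NIfTI export.

The fixed order of operations per frame is: ghost correction -> (corrected
arm only: first-order off-resonance correction) -> zeroth-order (phi0)
correction on both arms -> SMS unaliasing -> in-plane fill -> inverse
transform -> root-sum-of-squares coil combination.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .calib import GrappaKernel, OperatorSet, SliceKernels, apply_kernel
from .correct import GhostParams, PerturbationEstimate, correct_frame
from .engine import KSpaceFrame, Session, apply_ghost
from .fourier import cifft2
from .protocol import Protocol


@dataclass
class ReconSeries:
    """4-D magnitude time series, indexed [t, z, y, x], with provenance."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    tr: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def to_nifti(self, path: str | Path | None = None) -> nib.Nifti1Image:
        """NIfTI with RAS affine from voxel size only; dims (x, y, z, t)."""
        vol = np.transpose(self.data, (3, 2, 1, 0)).astype(np.float32)
        affine = np.diag([*self.voxel_mm, 1.0])
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((*self.voxel_mm, self.tr))
        img.header.set_xyzt_units("mm", "sec")
        img.header["descrip"] = str(self.provenance.get("arm", ""))[:79].encode()
        if path is not None:
            nib.save(img, str(path))
        return img


def nyquist_correct_lines(lines: np.ndarray, polarity: np.ndarray,
                          ghost: GhostParams) -> np.ndarray:
    """Counter-rotate even/odd lines by -(theta0 + theta1 x)/2 in projection space."""
    return apply_ghost(lines, polarity, ghost.theta0, ghost.theta1, sign=-1.0)


def nyquist_correct(frame: KSpaceFrame, ghost: GhostParams) -> KSpaceFrame:
    """Ghost-correct a frame's imaging lines and navigators."""
    out = frame.copy()
    out.data = nyquist_correct_lines(frame.data, frame.line_polarity, ghost)
    out.nav = nyquist_correct_lines(frame.nav, frame.nav_polarity, ghost)
    return out


def lines_to_grid(lines: np.ndarray, ky: np.ndarray, n: int) -> np.ndarray:
    """Embed acquired lines (C, L, N) into a zero-filled (C, N, N) grid."""
    grid = np.zeros((lines.shape[0], n, n), dtype=complex)
    grid[:, np.asarray(ky) + n // 2, :] = lines
    return grid


def sms_unalias(grid: np.ndarray, kernels: SliceKernels, protocol: Protocol
                ) -> np.ndarray:
    """Separate collapsed SMS k-space into per-slice k-space.

    grid : (C, N, N) zero-filled collapsed k-space (acquired rows present).
    Returns (MB, C, N, N) with the CAIPI phase removed; acquired rows only.
    """
    if kernels.caipi != protocol.caipi:
        raise ValueError("slice kernels were trained with a different CAIPI setting")
    mb = len(kernels.weights)
    if mb == 1:
        return grid[None].copy()
    n = protocol.n
    rows = protocol.acquired_ky + n // 2
    ky_full = np.arange(n) - n // 2
    out = np.zeros((mb, grid.shape[0], n, n), dtype=complex)
    for j in range(mb):
        est = apply_kernel(grid, kernels.weights[j], kernels.dys, kernels.dxs)
        ph = protocol.caipi_phase(ky_full, j)
        out[j][:, rows, :] = est[:, rows, :] / ph[rows][None, :, None]
    return out


def inplane_fill(grid: np.ndarray, kernel: GrappaKernel, protocol: Protocol
                 ) -> np.ndarray:
    """Synthesize missing ky lines with the GRAPPA kernel.

    grid : (C, N, N) zero-filled undersampled k-space. Acquired lines are
    left untouched.
    """
    n = protocol.n
    rows = protocol.acquired_ky + n // 2
    acquired = np.zeros(n, dtype=bool)
    acquired[rows] = True
    if acquired.all():
        return grid.copy()
    if np.linalg.norm(grid[:, ~acquired, :]) > 0:
        raise ValueError("sampling pattern does not match kernel geometry")
    est = apply_kernel(grid, kernel.weights, kernel.dys, kernel.dxs)
    out = grid.copy()
    out[:, ~acquired, :] = est[:, ~acquired, :]
    return out


def coil_combine(images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares over the leading coil axis."""
    images = np.asarray(images)
    if images.ndim == 2:
        return np.abs(images)
    return np.sqrt(np.sum(np.abs(images) ** 2, axis=0))


def reconstruct_frame(frame: KSpaceFrame, operators: OperatorSet,
                      est: PerturbationEstimate, protocol: Protocol,
                      arm: str) -> np.ndarray:
    """Reconstruct one frame's slice group -> (MB, N, N) magnitude slices."""
    fr = nyquist_correct(frame, est.ghost) if est.ghost else frame
    if arm == "corrected":
        fr = correct_frame(fr, est, operators.shift_ky, protocol)
    else:
        # zeroth-order-only correction
        zero_est = dataclasses.replace(est, dkx=0.0, dky=0.0)
        fr = correct_frame(fr, zero_est, operators.shift_ky, protocol)
    grid = lines_to_grid(fr.data, fr.ky, protocol.n)
    per_slice = sms_unalias(grid, operators.slices[frame.group], protocol)
    imgs = np.empty((per_slice.shape[0], protocol.n, protocol.n))
    for j in range(per_slice.shape[0]):
        full = inplane_fill(per_slice[j], operators.inplane, protocol)
        imgs[j] = coil_combine(cifft2(full))
    return imgs


def reconstruct_session(session: Session, operators: OperatorSet,
                        estimates: list[list[PerturbationEstimate]],
                        arm: str = "corrected",
                        out_nifti: str | Path | None = None) -> ReconSeries:
    """Reconstruct a full session into a 4-D magnitude series.

    Both arms receive ghost correction and the dynamic zeroth-order (phi0)
    correction; only ``arm="corrected"`` applies the first-order k-space
    translation correction.
    """
    if arm not in ("corrected", "uncorrected"):
        raise ValueError("arm must be 'corrected' or 'uncorrected'")
    if estimates is None or len(estimates) != session.n_frames:
        raise ValueError("need one estimate per frame (run estimate_session first)")
    p = session.protocol
    groups = p.slice_groups()
    T = session.n_frames
    data = np.zeros((T, p.n_slices, p.n, p.n), dtype=np.float32)
    for t in range(T):
        for g, sl in enumerate(groups):
            imgs = reconstruct_frame(session.frames[t][g], operators,
                                     estimates[t][g], p, arm)
            data[t, sl] = imgs
    series = ReconSeries(
        data=data,
        voxel_mm=(p.voxel_mm, p.voxel_mm, p.slice_mm),
        tr=p.tr,
        provenance={"arm": arm, "software": "dynb0"},
    )
    if out_nifti is not None:
        series.to_nifti(out_nifti)
    return series
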