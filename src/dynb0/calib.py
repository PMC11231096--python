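"""Parallel-imaging calibration: GRAPPA kernels, split-slice SMS kernels,
and GRAPPA shift operators with fractional powers.

The shift operator is the package's estimation workhorse: a coil-coupling
relation ``d(k+1) = W d(k)`` trained on fully sampled calibration data,
whose fractional (eigendecomposition) powers realize sub-grid k-space
translations of multi-coil data without knowing the underlying image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import cfft, cifft, coords
from .protocol import Protocol


def _ridge_solve(A: np.ndarray, B: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Tikhonov least squares W = (A^H A + lam_hat I)^-1 A^H B.

    lam is relative to trace(A^H A)/n_unknowns. Returns (W, relative residual).
    """
    AhA = A.conj().T @ A
    n_unk = AhA.shape[0]
    if A.shape[0] < n_unk:
        raise ValueError(
            f"underdetermined fit: {A.shape[0]} equations for {n_unk} unknowns")
    lam_hat = lam * np.trace(AhA).real / n_unk
    W = np.linalg.solve(AhA + lam_hat * np.eye(n_unk), A.conj().T @ B)
    resid = np.linalg.norm(A @ W - B) / max(np.linalg.norm(B), 1e-30)
    return W, float(resid)


def _shifted_stack(grid: np.ndarray, dys: tuple, dxs: tuple) -> np.ndarray:
    """Stack np.roll-shifted copies: out[c, i_dy, i_dx, m, k] = grid[c, m+dy, k+dx]."""
    out = np.empty((grid.shape[0], len(dys), len(dxs)) + grid.shape[-2:], dtype=grid.dtype)
    for i, dy in enumerate(dys):
        for j, dx in enumerate(dxs):
            out[:, i, j] = np.roll(grid, (-dy, -dx), axis=(-2, -1))
    return out


# ---------------------------------------------------------------------------
# In-plane GRAPPA
# ---------------------------------------------------------------------------

@dataclass
class GrappaKernel:
    """Weights synthesizing a missing ky line from neighboring acquired lines.

    weights : (C*2*3, C) mapping the source neighborhood (coils x ky offsets
    {-1,+1} x kx offsets {-1,0,1}) to the missing-line target per coil.
    """

    weights: np.ndarray
    dys: tuple = (-1, 1)
    dxs: tuple = (-1, 0, 1)
    lam: float = 1e-4
    residual: float = 0.0


def train_inplane_kernel(calib: np.ndarray, protocol: Protocol,
                         lam: float = 1e-4) -> GrappaKernel:
    """Fit the R=2 GRAPPA kernel on fully sampled calibration data.

    calib : (S, C, N, N) per-slice fully sampled k-space.
    """
    if calib.ndim == 3:
        calib = calib[None]
    C = calib.shape[1]
    if C < 2:
        raise ValueError("in-plane GRAPPA requires at least 2 coils")
    dys, dxs = (-1, 1), (-1, 0, 1)
    rows = slice(1, calib.shape[-2] - 1)
    cols = slice(1, calib.shape[-1] - 1)
    A_parts, B_parts = [], []
    for s in range(calib.shape[0]):
        src = _shifted_stack(calib[s], dys, dxs)[..., rows, cols]
        A_parts.append(src.reshape(C * len(dys) * len(dxs), -1).T)
        B_parts.append(calib[s][:, rows, cols].reshape(C, -1).T)
    A = np.concatenate(A_parts)
    B = np.concatenate(B_parts)
    W, resid = _ridge_solve(A, B, lam)
    return GrappaKernel(weights=W, dys=dys, dxs=dxs, lam=lam, residual=resid)


def apply_kernel(grid: np.ndarray, weights: np.ndarray, dys: tuple,
                 dxs: tuple) -> np.ndarray:
    """Evaluate a k-space convolution kernel at every (ky, kx) position.

    grid : (C, N, N); returns (C_target, N, N). Edges wrap (periodic k-space).
    """
    C = grid.shape[0]
    src = _shifted_stack(grid, dys, dxs).reshape(C * len(dys) * len(dxs), *grid.shape[-2:])
    return np.einsum("st,s...->t...", weights, src)


# ---------------------------------------------------------------------------
# Split-slice SMS kernels
# ---------------------------------------------------------------------------

@dataclass
class SliceKernels:
    """Per-slice kernels separating CAIPI-collapsed SMS k-space.

    weights[j] maps the collapsed data to the CAIPI-phased k-space of slice
    j within its group (the known CAIPI phase is divided out afterwards).
    Trained with the split-slice (leak-block) objective by default.
    """

    weights: list  # per slice-in-group: (C*3*3, C)
    dys: tuple
    dxs: tuple = (-1, 0, 1)
    lam: float = 1e-5
    caipi: bool = True
    residuals: list = field(default_factory=list)


def train_slice_kernels(calib: np.ndarray, group_slices: list[int],
                        protocol: Protocol, lam: float = 1e-5,
                        leak_block: bool = True) -> SliceKernels:
    """Fit SMS separation kernels for one slice group.

    calib : (S, C, N, N) fully sampled per-slice k-space for all slices.
    With ``leak_block`` the kernel for slice j is also required to map the
    other slices' (CAIPI-phased) contributions to zero, penalizing
    inter-slice leakage directly.
    """
    n, C = protocol.n, calib.shape[1]
    mb = len(group_slices)
    ky_full = np.arange(n) - n // 2
    dys = (-protocol.r, 0, protocol.r)
    dxs = (-1, 0, 1)
    if mb == 1:
        # degenerate: identity kernel
        W = np.zeros((C * 9, C), dtype=complex)
        for c in range(C):
            W[c * 9 + 4, c] = 1.0  # dy=0, dx=0 position
        return SliceKernels(weights=[W], dys=dys, dxs=dxs, lam=lam,
                            caipi=protocol.caipi, residuals=[0.0])

    m = protocol.r
    rows = slice(m, n - m)
    cols = slice(1, n - 1)
    D = []
    for j, s in enumerate(group_slices):
        ph = protocol.caipi_phase(ky_full, j)
        D.append(calib[s] * ph[None, :, None])

    srcs = []
    for j in range(mb):
        src = _shifted_stack(D[j], dys, dxs)[..., rows, cols]
        srcs.append(src.reshape(C * 9, -1).T)

    weights, residuals = [], []
    for j in range(mb):
        if leak_block:
            A = np.concatenate(srcs)
            B = np.concatenate([
                D[i][:, rows, cols].reshape(C, -1).T if i == j
                else np.zeros_like(srcs[i][:, :C])
                for i in range(mb)])
        else:
            A = sum(srcs)
            B = D[j][:, rows, cols].reshape(C, -1).T
        W, resid = _ridge_solve(A, B, lam)
        weights.append(W)
        residuals.append(resid)
    return SliceKernels(weights=weights, dys=dys, dxs=dxs, lam=lam,
                        caipi=protocol.caipi, residuals=residuals)


# ---------------------------------------------------------------------------
# GRAPPA shift operator
# ---------------------------------------------------------------------------

@dataclass
class ShiftOperator:
    """Unit k-space shift as a coil-coupling operator, with fractional powers.

    In the hybrid domain (image space along the fully sampled orthogonal
    axis, k-space along the shift axis) the unit shift is an independent
    C x C coil-coupling matrix W(x) per position, fitted by ridge regression
    over all adjacent line pairs of the calibration data; positions without
    signal are regularized toward the identity (no information -> no-op).
    Fractional powers come from the eigendecomposition
    ``W(x)^delta = V Lambda^delta V^-1`` with the principal branch of the
    logarithm.

    A compact k-space convolution form (``w`` taps over the orthogonal axis,
    ``W(x) = sum_j W_j exp(-2i pi j x)``) is available via ``w=<odd int>``;
    the default full per-position fit corresponds to ``w = n``.
    """

    axis: str                    # "ky" or "kx"
    Wx: np.ndarray               # (n, C, C) hybrid per-position, target x source
    n: int
    lam: float
    residual: float
    w: int | None = None         # None: full per-position fit
    _eigvals: np.ndarray = field(default=None, repr=False)  # (n, C)
    _eigvecs: np.ndarray = field(default=None, repr=False)
    _eiginv: np.ndarray = field(default=None, repr=False)

    def hybrid_matrices(self) -> np.ndarray:
        """(n, C, C) per-position coil-coupling matrices W(x)."""
        return self.Wx

    def _ensure_eig(self) -> None:
        if self._eigvals is None:
            vals, vecs = np.linalg.eig(self.Wx)
            self._eigvals = vals
            self._eigvecs = vecs
            self._eiginv = np.linalg.inv(vecs)

    def fractional_power(self, delta: float) -> np.ndarray:
        """(n, C, C) matrices realizing a shift of the sampling position by
        ``delta`` grid units (out(k) ~ in(k + delta))."""
        if abs(delta) > 1.5:
            raise ValueError("fractional shift outside validity range |delta| <= 1.5")
        self._ensure_eig()
        vals = self._eigvals
        if np.any(np.abs(vals) < 1e-8):
            raise np.linalg.LinAlgError(
                "shift operator has near-zero eigenvalues; "
                "retrain with higher Tikhonov regularization lam")
        # clamp eigenvalue moduli into [0.15, 1]: a k-space shift cannot gain
        # energy, and tiny moduli (positions with weak coil information)
        # would otherwise amplify noise without bound for negative powers
        mod = np.abs(vals)
        vals = vals / mod * np.clip(mod, 0.15, 1.0)
        powd = np.exp(delta * np.log(vals))  # principal branch
        return np.einsum("xab,xb,xbc->xac", self._eigvecs, powd, self._eiginv)

    def apply_power(self, arr: np.ndarray, delta: float) -> np.ndarray:
        """Apply W^delta to k-space lines along the operator axis.

        arr : (C, N) single line or (C, L, N) lines; the last axis is the
        orthogonal (fully sampled) k-space axis.  Returns the same shape,
        with every line mapped to the data sampled ``delta`` further along
        the operator axis.
        """
        M = self.fractional_power(delta)
        single = arr.ndim == 2
        if single:
            arr = arr[:, None, :]
        hyb = cifft(arr, axis=-1)
        out = np.einsum("xab,blx->alx", M, hyb)
        out = cfft(out, axis=-1)
        return out[:, 0, :] if single else out

    def translate(self, arr: np.ndarray, shift: float) -> np.ndarray:
        """Translate the k-space *content* of ``arr`` by ``shift`` grid units."""
        return self.apply_power(arr, -shift)


def train_shift_operator(calib: np.ndarray, protocol: Protocol,
                         axis: str = "ky", w: int | None = None,
                         lam: float = 1e-6) -> ShiftOperator:
    """Train the unit-shift operator on fully sampled calibration data.

    calib : (S, C, N, N) indexed [slice, coil, ky, kx]; all slices enter the
    fit jointly so one operator serves collapsed SMS data.  With ``w=None``
    (default) a C x C matrix is fitted per orthogonal hybrid position; an
    integer ``w`` fits a w-tap k-space convolution kernel instead.
    """
    if axis not in ("ky", "kx"):
        raise ValueError("axis must be 'ky' or 'kx'")
    if calib.ndim == 3:
        calib = calib[None]
    data = calib if axis == "ky" else calib.transpose(0, 1, 3, 2)
    S, C, n_sh, n_ortho = data.shape

    if w is None:
        H = cifft(data, axis=-1)  # (S, C, shift axis, orthogonal position)
        if S * (n_sh - 1) < C:
            raise np.linalg.LinAlgError(
                f"rank-deficient shift-operator fit along {axis}: "
                f"{S * (n_sh - 1)} line pairs for {C} coils")
        Wx = np.empty((n_ortho, C, C), dtype=complex)
        traces = np.empty(n_ortho)
        AhA_all, AhB_all = [], []
        for x in range(n_ortho):
            A = H[:, :, :-1, x].transpose(0, 2, 1).reshape(-1, C)
            B = H[:, :, 1:, x].transpose(0, 2, 1).reshape(-1, C)
            AhA_all.append(A.conj().T @ A)
            AhB_all.append(A.conj().T @ B)
            traces[x] = np.trace(AhA_all[-1]).real
        # global regularization floor pulls empty positions toward identity
        floor = 1e-3 * traces.max()
        resid_num = resid_den = 0.0
        for x in range(n_ortho):
            lam_hat = lam * max(traces[x], floor) / C
            Wx[x] = np.linalg.solve(AhA_all[x] + lam_hat * np.eye(C),
                                    AhB_all[x] + lam_hat * np.eye(C)).T
        pred = np.einsum("xab,sblx->salx", Wx,
                         H[:, :, :-1, :].transpose(0, 1, 2, 3))
        resid = np.linalg.norm(pred - H[:, :, 1:, :].transpose(0, 1, 2, 3)) / \
            np.linalg.norm(H[:, :, 1:, :])
        return ShiftOperator(axis=axis, Wx=Wx, n=n_ortho, lam=lam,
                             residual=float(resid), w=None)

    offs = np.arange(w) - w // 2
    A_parts, B_parts = [], []
    qs = slice(w // 2, n_ortho - w // 2) if w > 1 else slice(None)
    for s in range(S):
        d = data[s]
        src = np.empty((C, w, n_sh - 1, len(range(*qs.indices(n_ortho)))), dtype=complex)
        for i, j in enumerate(offs):
            src[:, i] = np.roll(d, -j, axis=-1)[:, :-1, qs]
        A_parts.append(src.reshape(C * w, -1).T)
        B_parts.append(d[:, 1:, qs].reshape(C, -1).T)
    A = np.concatenate(A_parts)
    B = np.concatenate(B_parts)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError(f"rank-deficient shift-operator fit along {axis}")
    Wflat, resid = _ridge_solve(A, B, lam)
    Wj = Wflat.reshape(C, w, C).transpose(1, 2, 0)  # (w, target, source)
    x = coords(n_ortho)
    phase = np.exp(-2j * np.pi * np.outer(x, offs))  # (n, w)
    Wx = np.einsum("xj,jab->xab", phase, Wj)
    return ShiftOperator(axis=axis, Wx=Wx, n=n_ortho, lam=lam,
                         residual=resid, w=w)


@dataclass
class OperatorSet:
    """Everything trained from one calibration set."""

    inplane: GrappaKernel
    slices: list            # SliceKernels per slice group
    shift_ky: ShiftOperator
    shift_kx: ShiftOperator | None = None


def train_operators(calib: np.ndarray, protocol: Protocol,
                    lam_kernel: float = 1e-4, lam_shift: float = 1e-6,
                    leak_block: bool = True) -> OperatorSet:
    """Train all reconstruction/estimation operators from calibration data."""
    inplane = train_inplane_kernel(calib, protocol, lam=lam_kernel)
    slices = [train_slice_kernels(calib, grp, protocol, leak_block=leak_block)
              for grp in protocol.slice_groups()]
    shift_ky = train_shift_operator(calib, protocol, axis="ky", lam=lam_shift)
    return OperatorSet(inplane=inplane, slices=slices, shift_ky=shift_ky)
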