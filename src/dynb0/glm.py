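"""First-level GLM with AR(1) prewhitening, cluster thresholding, a simple
second-level (one-sample t across sessions), and split-half reliability.

The task model is
``BOLD = b0 + b1*offer + b2*action_onset + b3*motor_response + b4*outcome``
with every task regressor a 0.1-s boxcar convolved with the HRF: *offer*
time-locked to trial onset, *action_onset* and *motor_response* to the
go-cue (the latter only on responded trials), *outcome* to reward delivery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .task import REGRESSOR_NAMES, EventList, HRFParams, convolve_events

Z_CAP = 8.2  # |z| cap where the t -> z transform saturates numerically


@dataclass
class DesignMatrix:
    """Columns: intercept + the four task regressors, sampled at the TR."""

    matrix: np.ndarray
    names: list[str]
    tr: float
    hrf: HRFParams

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=self.names).to_csv(
            path, sep="\t", index=False)


def build_design(events: EventList, T: int, tr: float,
                 hrf: HRFParams | None = None, duration: float = 0.1) -> DesignMatrix:
    """Convolve task events into a (T, 5) design matrix.

    Events beyond the end of the scan are dropped with a warning.
    """
    hrf = hrf or HRFParams()
    t_eval = np.arange(T) * tr
    t_end = T * tr
    cols = [np.ones(T)]
    names = ["intercept"]
    for name in REGRESSOR_NAMES:
        onsets = events.onsets(name)
        onsets = onsets[np.isfinite(onsets)]
        if np.any(onsets > t_end):
            warnings.warn(f"{name}: dropping {int(np.sum(onsets > t_end))} "
                          "event(s) beyond scan end", stacklevel=2)
            onsets = onsets[onsets <= t_end]
        cols.append(convolve_events(onsets, t_eval, hrf, duration=duration))
        names.append(name)
    return DesignMatrix(matrix=np.column_stack(cols), names=names, tr=tr, hrf=hrf)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def dct_highpass_basis(T: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis with frequencies below 1/cutoff Hz."""
    order = int(np.floor(2.0 * T * tr / cutoff_s))
    t = np.arange(T)
    basis = [np.cos(np.pi * k * (2 * t + 1) / (2 * T)) for k in range(1, order + 1)]
    return np.column_stack(basis) if basis else np.zeros((T, 0))


def preprocess_series(series, highpass_cutoff_s: float = 100.0,
                      fwhm_mm: float = 3.0, tr: float | None = None,
                      voxel_mm: float | None = None):
    """Gaussian in-plane smoothing followed by DCT-basis high-pass filtering.

    The temporal mean is re-added after filtering.  Works on a ReconSeries
    (returns a new one) or a raw (T, Z, Y, X) array.
    """
    is_series = hasattr(series, "voxel_mm")  # ReconSeries, not a bare array
    data = np.asarray(series.data if is_series else series, dtype=float)
    tr = series.tr if is_series and tr is None else tr
    voxel_mm = (series.voxel_mm[0] if is_series and voxel_mm is None else voxel_mm)
    if tr is None or voxel_mm is None:
        raise ValueError("tr and voxel_mm required for raw arrays")
    if highpass_cutoff_s <= 2 * tr:
        raise ValueError("high-pass cutoff must exceed 2*TR")

    out = data.copy()
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm
        out = ndimage.gaussian_filter(out, sigma=(0, 0, sigma_vox, sigma_vox))

    T = out.shape[0]
    basis = dct_highpass_basis(T, tr, highpass_cutoff_s)
    if basis.shape[1] > 0:
        Y = out.reshape(T, -1)
        mean = Y.mean(axis=0, keepdims=True)
        Yc = Y - mean
        coef, *_ = np.linalg.lstsq(basis, Yc, rcond=None)
        out = (Yc - basis @ coef + mean).reshape(out.shape)

    if is_series:
        import dataclasses

        return dataclasses.replace(series, data=out.astype(series.data.dtype))
    return out


# ---------------------------------------------------------------------------
# First-level GLM
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    """Per-voxel beta and z maps per regressor, plus the AR(1) map."""

    betas: dict[str, np.ndarray]
    zmaps: dict[str, np.ndarray]
    rho: np.ndarray
    dof: int
    names: list[str] = field(default_factory=list)


def t_to_z(tvals: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to z scores through matched tail probabilities."""
    tvals = np.asarray(tvals, dtype=float)
    z = np.sign(tvals) * stats.norm.isf(stats.t.sf(np.abs(tvals), dof))
    return np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP),
                   -Z_CAP, Z_CAP)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-10 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_glm(series, design: DesignMatrix, rho_bin: float = 0.01) -> GLMResult:
    """Voxelwise GLM with Cochrane-Orcutt AR(1) prewhitening.

    AR(1) coefficients are estimated from OLS residuals, binned, and voxels
    sharing a bin are whitened and refit together. z = beta/SE through the
    t -> z transform with T - p residual dof.
    """
    data = np.asarray(series.data if hasattr(series, "voxel_mm") else series, dtype=float)
    T = data.shape[0]
    X = design.matrix
    p = X.shape[1]
    if T <= p + 10:
        raise ValueError("too few time-points for the design")
    _check_rank(X, design.names)

    shape = data.shape[1:]
    Y = data.reshape(T, -1)
    V = Y.shape[1]

    B0 = np.linalg.pinv(X) @ Y
    R = Y - X @ B0
    denom = np.sum(R * R, axis=0)
    denom[denom == 0] = 1.0
    rho = np.sum(R[1:] * R[:-1], axis=0) / denom
    rho = np.clip(rho, -0.95, 0.95)
    rho_b = np.round(rho / rho_bin) * rho_bin

    betas = np.empty((p, V))
    tvals = np.empty((p, V))
    dof = T - p
    for r in np.unique(rho_b):
        idx = np.where(rho_b == r)[0]
        w0 = np.sqrt(1.0 - r * r)
        Xw = np.vstack([X[:1] * w0, X[1:] - r * X[:-1]])
        Yw = np.vstack([Y[:1, idx] * w0, Y[1:, idx] - r * Y[:-1, idx]])
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        pinv = XtX_inv @ Xw.T
        b = pinv @ Yw
        resid = Yw - Xw @ b
        sigma2 = np.sum(resid * resid, axis=0) / dof
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        se[se == 0] = np.inf
        betas[:, idx] = b
        tvals[:, idx] = b / se

    names = design.names
    return GLMResult(
        betas={nm: betas[i].reshape(shape) for i, nm in enumerate(names)},
        zmaps={nm: t_to_z(tvals[i], dof).reshape(shape) for i, nm in enumerate(names)},
        rho=rho.reshape(shape), dof=dof, names=list(names))


def whitened_residual_autocorr(series, design: DesignMatrix) -> float:
    """Mean lag-1 autocorrelation of prewhitened residuals (diagnostic)."""
    data = np.asarray(series.data if hasattr(series, "voxel_mm") else series, dtype=float)
    T = data.shape[0]
    X = design.matrix
    Y = data.reshape(T, -1)
    B0 = np.linalg.pinv(X) @ Y
    R = Y - X @ B0
    denom = np.sum(R * R, axis=0)
    denom[denom == 0] = 1.0
    rho = np.clip(np.sum(R[1:] * R[:-1], axis=0) / denom, -0.95, 0.95)
    out = np.empty(Y.shape[1])
    for v in range(Y.shape[1]):
        r = rho[v]
        w0 = np.sqrt(1 - r * r)
        Xw = np.vstack([X[:1] * w0, X[1:] - r * X[:-1]])
        Yw = np.concatenate([Y[:1, v] * w0, Y[1:, v] - r * Y[:-1, v]])
        b, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        res = Yw - Xw @ b
        out[v] = np.sum(res[1:] * res[:-1]) / max(np.sum(res * res), 1e-30)
    return float(np.mean(out))


# ---------------------------------------------------------------------------
# Cluster thresholding
# ---------------------------------------------------------------------------

def cluster_threshold(zmap: np.ndarray, z_thr: float = 3.1,
                      min_extent: int = 0) -> pd.DataFrame:
    """Face-connected clusters of z > z_thr, dropping small clusters.

    Returns a table with size, peak z and peak location per cluster.
    """
    zmap = np.asarray(zmap)
    structure = ndimage.generate_binary_structure(zmap.ndim, 1)
    labels, n = ndimage.label(zmap > z_thr, structure=structure)
    rows = []
    for lab in range(1, n + 1):
        m = labels == lab
        size = int(m.sum())
        if size < min_extent:
            continue
        zm = np.where(m, zmap, -np.inf)
        peak = np.unravel_index(np.argmax(zm), zmap.shape)
        rows.append(dict(size=size, peak_z=float(zmap[peak]),
                         peak_location=tuple(int(i) for i in peak)))
    rows.sort(key=lambda d: -d["size"])
    return pd.DataFrame(rows, columns=["size", "peak_z", "peak_location"])


def calibrate_cluster_extent(shape: tuple, fwhm_vox: float, z_thr: float = 3.1,
                             alpha: float = 0.05, n_sims: int = 200,
                             seed: int = 0) -> int:
    """Null-simulation cluster-extent threshold (in place of GRF p-values).

    Smoothed unit-variance Gaussian null maps are thresholded at z_thr; the
    returned extent is exceeded by the max null cluster with probability
    <= alpha.
    """
    rng = np.random.default_rng(seed)
    sigma = fwhm_vox / (2 * np.sqrt(2 * np.log(2)))
    maxima = np.empty(n_sims)
    structure = ndimage.generate_binary_structure(len(shape), 1)
    for i in range(n_sims):
        noise = rng.standard_normal(shape)
        if sigma > 0:
            sm = ndimage.gaussian_filter(noise, sigma=(0, sigma, sigma))
            sm /= sm.std()
        else:
            sm = noise
        labels, n = ndimage.label(sm > z_thr, structure=structure)
        maxima[i] = np.max(np.bincount(labels.ravel())[1:]) if n else 0
    return int(np.quantile(maxima, 1 - alpha)) + 1


# ---------------------------------------------------------------------------
# Second level and reliability
# ---------------------------------------------------------------------------

def second_level(maps: np.ndarray | list) -> np.ndarray:
    """One-sample t across sessions per voxel, mapped to z (capped at ±8.2).

    Zero-variance voxels with a nonzero mean are set to ±Z_CAP.
    """
    arr = np.asarray(maps, dtype=float)
    S = arr.shape[0]
    if S < 3:
        raise ValueError("need at least 3 sessions for the second level")
    mean = arr.mean(axis=0)
    std = arr.std(axis=0, ddof=1)
    z = np.zeros_like(mean)
    nz = std > 0
    t = np.zeros_like(mean)
    t[nz] = mean[nz] / (std[nz] / np.sqrt(S))
    z[nz] = t_to_z(t[nz], S - 1)
    z[~nz] = np.sign(mean[~nz]) * Z_CAP
    return z


@dataclass
class ReliabilityResult:
    """Per-fold, per-ROI split-half correlation and baseline bias."""

    table: pd.DataFrame  # columns: fold, roi, r, bias, n_voxels

    def fold_mean(self) -> pd.DataFrame:
        return (self.table.groupby("roi", sort=False)[["r", "bias"]]
                .mean().reset_index())


def split_half_reliability(session_maps: np.ndarray | list,
                           masks: dict[str, np.ndarray],
                           n_folds: int = 10, seed: int = 0,
                           z_thr: float = 3.1) -> ReliabilityResult:
    """Split-half reliability of second-level activation across sessions.

    Per fold, sessions are randomly split into two halves and a second-level
    z map computed per half.  Per ROI, reliability r is the voxelwise
    correlation of the thresholded (below-threshold voxels zeroed) z values,
    and baseline bias the absolute difference of the ROI-mean z.
    """
    arr = np.asarray(session_maps, dtype=float)
    S = arr.shape[0]
    if S < 4:
        raise ValueError("need at least 4 sessions")
    if not masks:
        raise ValueError("need at least one ROI mask")
    rng = np.random.default_rng(seed)
    rows = []
    for fold in range(n_folds):
        perm = rng.permutation(S)
        h1, h2 = perm[: S // 2], perm[S // 2:]
        z1, z2 = second_level(arr[h1]), second_level(arr[h2])
        z1t = np.where(z1 > z_thr, z1, 0.0)
        z2t = np.where(z2 > z_thr, z2, 0.0)
        for name, m in masks.items():
            m = m.astype(bool)
            v1, v2 = z1t[m], z2t[m]
            if v1.std() == 0 or v2.std() == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(v1, v2)[0])
            bias = float(abs(z1[m].mean() - z2[m].mean()))
            rows.append(dict(fold=fold, roi=name, r=r, bias=bias,
                             n_voxels=int(m.sum())))
    return ReliabilityResult(table=pd.DataFrame(rows))


def compare_reliability(rel_a: ReliabilityResult, rel_b: ReliabilityResult,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-ROI comparison of split-half r between two arms across folds."""
    rows = []
    for roi in rel_a.table["roi"].unique():
        ra = rel_a.table.query("roi == @roi")["r"].to_numpy()
        rb = rel_b.table.query("roi == @roi")["r"].to_numpy()
        ok = np.isfinite(ra) & np.isfinite(rb)
        d = ra[ok] - rb[ok]
        if d.size < 2 or np.allclose(d, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(d).pvalue)
        rows.append(dict(roi=roi, delta_r=float(np.nanmean(d)) if d.size else np.nan,
                         p=p))
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["q"] < alpha
    return df
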