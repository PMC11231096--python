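"""Image-quality quantification: bias vs the single-band reference, temporal
coefficient of variation, tSNR maps, ROI summaries, histograms, and paired
across-session comparison with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bias_map(series, sb_ref: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel temporal-mean difference to the single-band reference.

    Normalized by the mean reference intensity over the object (fraction).
    series may be a ReconSeries or a (T, Z, Y, X) array; sb_ref is (Z, Y, X).
    """
    data = np.asarray(series.data if hasattr(series, "voxel_mm") else series)
    if data.shape[1:] != sb_ref.shape:
        raise ValueError("series and reference grids do not match")
    if mask is None:
        mask = sb_ref > 0.1 * sb_ref.max()
    norm = float(np.mean(sb_ref[mask]))
    return (data.mean(axis=0) - sb_ref) / norm


def cov_map(series, floor: float = 1e-6) -> np.ndarray:
    """Temporal coefficient of variation std/mean; low-mean voxels -> NaN."""
    data = np.asarray(series.data if hasattr(series, "voxel_mm") else series)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time-points")
    mean = data.mean(axis=0)
    std = data.std(axis=0, ddof=1)
    out = np.full(mean.shape, np.nan)
    valid = mean > floor * np.nanmax(mean)
    out[valid] = std[valid] / mean[valid]
    return out


def tsnr_map(series, floor: float = 1e-6) -> np.ndarray:
    """Temporal SNR mean/std; constant (zero-std) voxels -> NaN (flagged)."""
    cov = cov_map(series, floor=floor)
    out = np.full(cov.shape, np.nan)
    valid = np.isfinite(cov) & (cov > 0)
    out[valid] = 1.0 / cov[valid]
    return out


def roi_summary(vmap: np.ndarray, masks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean, SEM and voxel count of a map within each named ROI."""
    rows = []
    for name, m in masks.items():
        vals = vmap[m.astype(bool)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append(dict(roi=name, mean=np.nan, sem=np.nan, n_voxels=0))
        else:
            rows.append(dict(roi=name, mean=float(vals.mean()),
                             sem=float(vals.std(ddof=1) / np.sqrt(vals.size))
                             if vals.size > 1 else np.nan,
                             n_voxels=int(vals.size)))
    return pd.DataFrame(rows)


def paired_compare(tables_a: list[pd.DataFrame], tables_b: list[pd.DataFrame],
                   test: str = "wilcoxon", alpha: float = 0.05) -> pd.DataFrame:
    """Paired per-ROI comparison of per-session ROI means (arm a minus arm b).

    Empty ROIs are flagged and excluded from the FDR correction.  Returns
    per-ROI delta (mean difference), p, q (BH) and a significance flag.
    """
    if len(tables_a) != len(tables_b) or len(tables_a) < 2:
        raise ValueError("need >= 2 paired sessions")
    rois = list(tables_a[0]["roi"])
    a = np.array([[t.set_index("roi").loc[r, "mean"] for t in tables_a] for r in rois])
    b = np.array([[t.set_index("roi").loc[r, "mean"] for t in tables_b] for r in rois])
    rows = []
    for i, r in enumerate(rois):
        xa, xb = a[i], b[i]
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < 2:
            rows.append(dict(roi=r, delta=np.nan, p=np.nan, excluded=True))
            continue
        d = xa[ok] - xb[ok]
        if np.allclose(d, 0):
            p = 1.0
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(d).pvalue)
        elif test == "ttest":
            p = float(stats.ttest_1samp(d, 0.0).pvalue)
        else:
            raise ValueError(f"unknown test: {test!r}")
        rows.append(dict(roi=r, delta=float(d.mean()), p=p, excluded=False))
    df = pd.DataFrame(rows)
    valid = ~df["excluded"] & np.isfinite(df["p"])
    df["q"] = np.nan
    if valid.any():
        df.loc[valid, "q"] = multipletests(df.loc[valid, "p"], method="fdr_bh")[1]
    df["significant"] = df["q"] < alpha
    return df


def histogram(vmap: np.ndarray, mask: np.ndarray, bins: int = 60,
              rng: tuple[float, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(bin edges, counts) of a map over object voxels; counts sum to the
    number of finite in-mask voxels."""
    vals = vmap[mask.astype(bool)]
    vals = vals[np.isfinite(vals)]
    counts, edges = np.histogram(vals, bins=bins, range=rng)
    return edges, counts


@dataclass
class QCReport:
    """Per-arm maps and summaries plus the paired arm comparison."""

    bias: dict[str, np.ndarray]
    cov: dict[str, np.ndarray]
    tsnr: dict[str, np.ndarray]
    roi_tables: dict[str, pd.DataFrame]
    comparison: pd.DataFrame | None = None
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def save(self, out_dir: str | Path, voxel_mm: tuple | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import nibabel as nib

        vox = voxel_mm or (1.0, 1.0, 1.0)
        affine = np.diag([*vox, 1.0])
        for kind, maps in (("bias", self.bias), ("cov", self.cov),
                           ("tsnr", self.tsnr)):
            for arm, vmap in maps.items():
                vol = np.transpose(vmap, (2, 1, 0)).astype(np.float32)
                nib.save(nib.Nifti1Image(vol, affine),
                         str(out / f"{kind}_{arm}.nii.gz"))
        for arm, tab in self.roi_tables.items():
            tab.to_csv(out / f"roi_tsnr_{arm}.csv", index=False)
        if self.comparison is not None:
            self.comparison.to_csv(out / "paired_comparison.csv", index=False)
        for name, (edges, counts) in self.histograms.items():
            pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                          "count": counts}).to_csv(out / f"hist_{name}.csv", index=False)


def qc_report(series_by_arm: dict, sb_ref: np.ndarray,
              masks: dict[str, np.ndarray], mask: np.ndarray | None = None) -> QCReport:
    """Assemble the QC report for one session's two reconstruction arms."""
    if mask is None:
        mask = sb_ref > 0.1 * sb_ref.max()
    bias, cov, tsnr, tables, hists = {}, {}, {}, {}, {}
    for arm, series in series_by_arm.items():
        bias[arm] = bias_map(series, sb_ref, mask)
        cov[arm] = cov_map(series)
        tsnr[arm] = tsnr_map(series)
        tables[arm] = roi_summary(tsnr[arm], masks)
        hists[f"bias_{arm}"] = histogram(bias[arm], mask, rng=(-0.5, 0.5))
        hists[f"cov_{arm}"] = histogram(cov[arm], mask, rng=(0.0, 0.5))
    return QCReport(bias=bias, cov=cov, tsnr=tsnr, roi_tables=tables,
                    histograms=hists)
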