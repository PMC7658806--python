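"""Vasculature-related corrections for gradient-echo laminar BOLD.

Gradient-echo EPI is biased toward the pial surface: large ascending and
pial veins inflate signal amplitude in superficial depths and smear
deeper signal upward. Four corrections are provided, in the order the
pipeline applies them:

1. tSNR screening (:func:`compute_tsnr`) — voxels near large veins have
   high variance and low intensity, hence low temporal SNR.
2. Joint exclusion (:func:`exclude_vascular`) — voxels with tSNR below a
   low percentile OR a stimulation-GLM t-score above the 90th percentile
   of the within-ROI t distribution are removed.
3. Per-run voxel-wise z-scoring (:func:`zscore_timecourse`) — equalizes
   signal strength and variance across depths while preserving condition
   differences.
4. Nearest-neighbor spatial regression (:func:`spatial_regression`) —
   regresses each superficial voxel's time course on the mean time course
   of the matched nearest middle-layer voxels, unmixing drained signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .containers import BoldRun, LaminarVolume
from .geometry import layer_mask


@dataclass
class VoxelQuality:
    """Per-voxel quality measures and exclusion flags for one ROI."""

    tsnr: np.ndarray
    t_stat: np.ndarray
    excluded_low_tsnr: np.ndarray
    excluded_high_t: np.ndarray

    @property
    def excluded(self) -> np.ndarray:
        return self.excluded_low_tsnr | self.excluded_high_t

    @property
    def kept(self) -> np.ndarray:
        return ~self.excluded


def compute_tsnr(run: BoldRun) -> np.ndarray:
    """Temporal signal-to-noise ratio: temporal mean / temporal SD per voxel.

    Constant (zero-SD) time courses yield NaN, which downstream exclusion
    treats as excluded.
    """
    if run.n_trs < 2:
        raise ValueError("tSNR needs at least two timepoints")
    mean = run.data.mean(axis=1)
    sd = run.data.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / sd, np.nan)
    return tsnr


def mean_tsnr(runs) -> np.ndarray:
    """tSNR averaged over runs (NaN if undefined in any run)."""
    return np.mean([compute_tsnr(r) for r in runs], axis=0)


def exclude_vascular(tsnr: np.ndarray, t_stat: np.ndarray,
                     tsnr_percentile: float = 10.0,
                     t_percentile: float = 90.0,
                     roi_name: str = "ROI") -> VoxelQuality:
    """Flag vasculature-confounded voxels within one ROI.

    A voxel is excluded if its tSNR falls below the ``tsnr_percentile`` of
    the within-ROI tSNR distribution (NaN tSNR always excluded) or its
    GLM t-score lies above the ``t_percentile`` of the within-ROI t
    distribution. Percentiles use NumPy's default linear interpolation;
    comparisons are strict (<, >), so with t-scores 1..100 and the 90th
    percentile, exactly the 10 largest are flagged.

    Raises if nothing survives, naming the ROI.
    """
    tsnr = np.asarray(tsnr, dtype=float)
    t_stat = np.asarray(t_stat, dtype=float)
    undefined = ~np.isfinite(tsnr)
    finite = tsnr[~undefined]
    if tsnr_percentile > 0 and finite.size:
        lo = np.percentile(finite, tsnr_percentile)
        low_tsnr = undefined | (tsnr < lo)
    else:
        low_tsnr = undefined.copy()
    hi = np.percentile(t_stat, t_percentile)
    high_t = t_stat > hi
    q = VoxelQuality(tsnr=tsnr, t_stat=t_stat,
                     excluded_low_tsnr=low_tsnr, excluded_high_t=high_t)
    if not q.kept.any():
        raise ValueError(f"no voxels survive vascular exclusion in {roi_name}")
    return q


def zscore_timecourse(run: BoldRun, ddof: int = 0) -> BoldRun:
    """Z-score every voxel's time course within the run.

    Population SD (``ddof=0``) is the pinned convention: a two-timepoint
    series [1, 3] maps to [-1, 1]. Constant voxels are left at zero (they
    carry no signal and are excluded upstream), never divided by zero.
    """
    mean = run.data.mean(axis=1, keepdims=True)
    sd = run.data.std(axis=1, ddof=ddof, keepdims=True)
    safe = np.where(sd > 0, sd, 1.0)
    z = (run.data - mean) / safe
    z[sd[:, 0] == 0] = 0.0
    return run.with_data(z)


def nearest_middle_donors(volume: LaminarVolume,
                          superficial_idx: np.ndarray,
                          middle_idx: np.ndarray) -> np.ndarray:
    """For each superficial voxel, the nearest middle-layer voxel.

    Euclidean distance in mm between voxel centers; ties resolved to the
    lowest voxel index (deterministic). Many superficial voxels may share
    a donor. Returns indices into ``middle_idx``.
    """
    if middle_idx.size == 0:
        raise ValueError("no middle-layer voxels available for spatial regression")
    coords = volume.gray_coords_mm()
    tree = cKDTree(coords[middle_idx])
    _, nn = tree.query(coords[superficial_idx], k=1)
    return np.asarray(nn, dtype=int)


def regress_out(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS-residualize rows of ``y`` on a single regressor ``x`` plus
    intercept. Returns residuals with the same shape as ``y``."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = xc @ xc
    yc = y - y.mean(axis=1, keepdims=True)
    if denom == 0:
        return yc
    beta = (yc @ xc) / denom
    return yc - beta[:, None] * xc[None, :]


def spatial_regression(run: BoldRun, volume: LaminarVolume,
                       kept: np.ndarray | None = None) -> BoldRun:
    """Unmix drained signal from superficial voxels.

    For each superficial gray voxel, its nearest middle-layer voxel is
    found (Euclidean distance in voxel space); the mean time course of
    these matched middle voxels is regressed out (single regressor plus
    intercept, per run) of every superficial voxel's time course, and the
    residuals replace the superficial time courses. Other layers are
    untouched. ``kept`` (boolean over gray voxels) restricts the matching
    and regression to non-excluded voxels.
    """
    if volume.layer_labels is None:
        raise ValueError("layer labels required; run assign_layers first")
    keep = np.ones(volume.n_gray, dtype=bool) if kept is None else kept
    sup = np.flatnonzero(layer_mask(volume, "superficial") & keep)
    mid = np.flatnonzero(layer_mask(volume, "middle") & keep)
    if sup.size == 0:
        return run
    nn = nearest_middle_donors(volume, sup, mid)
    donors = np.unique(mid[nn])
    regressor = run.data[donors].mean(axis=0)
    data = run.data.copy()
    data[sup] = regress_out(run.data[sup], regressor)
    return run.with_data(data)
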