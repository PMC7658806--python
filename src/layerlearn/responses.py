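"""Block GLM fitting and peak-window pattern extraction.

The GLM serves voxel ranking only: HRF-convolved condition boxcars plus
nuisance columns and an intercept, fit by OLS per voxel, with a contrast
t-score per voxel. Two localizer contrasts are used, mirroring the two
ROI rules: lateralized regions (visual cortex) use left-vs-right stimulus
location; bilateral decision regions (IPS) use all-stimuli-vs-fixation.

Patterns are extracted without deconvolution: for each condition block
the per-voxel mean of the z-scored signal over the 4th-8th TR after block
onset (1-based; 6.18-14.42 s at TR 2.06 s — the hemodynamic peak window)
forms one row of the pattern matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import BlockDesign, BoldRun, PatternDataset
from .synth import double_gamma_hrf

logger = logging.getLogger(__name__)

#: 1-based TR window after block onset ("4th to 8th TR" inclusive).
PEAK_WINDOW = (4, 8)


@dataclass
class GlmResult:
    """Per-voxel OLS estimates for one run (or concatenated runs)."""

    betas: np.ndarray          # (n_regressors, n_voxels)
    t_stat: np.ndarray         # (n_voxels,) for the requested contrast
    regressor_names: list
    contrast: np.ndarray


def condition_design_matrix(design: BlockDesign) -> tuple[np.ndarray, list]:
    """HRF-convolved boxcar per condition (not per block), (n_trs, n_cond)."""
    hrf = double_gamma_hrf(design.tr_s)
    names = design.conditions()
    X = np.zeros((design.n_trs, len(names)))
    for j, name in enumerate(names):
        box = np.zeros(design.n_trs)
        for _, ev in design.events[design.events["trial_type"] == name].iterrows():
            t0 = design.onset_tr(ev["onset"])
            t1 = min(t0 + int(round(ev["duration"] / design.tr_s)), design.n_trs)
            box[t0:t1] = 1.0
        X[:, j] = np.convolve(box, hrf)[: design.n_trs]
    return X, names


def localizer_contrast(names: list, kind: str) -> np.ndarray:
    """Contrast vector over condition regressors.

    ``kind='left_vs_right'``: +1 on left-location conditions, -1 on right
    (visual-cortex rule). ``kind='all_vs_fixation'``: +1 on every
    condition (fixation is the implicit baseline; IPS rule).
    """
    c = np.zeros(len(names))
    if kind == "left_vs_right":
        for j, n in enumerate(names):
            if n.endswith("_left"):
                c[j] = 1.0
            elif n.endswith("_right"):
                c[j] = -1.0
        if not c.any():
            raise ValueError("no lateralized conditions found for left_vs_right contrast")
    elif kind == "all_vs_fixation":
        c[:] = 1.0
    else:
        raise ValueError(f"unknown contrast kind {kind!r}")
    return c


def fit_block_glm(runs, contrast_kind: str = "left_vs_right",
                  nuisance: np.ndarray | None = None) -> GlmResult:
    """OLS block GLM over one or several runs, with a contrast t per voxel.

    Runs are concatenated in time with run-specific intercepts. Nuisance
    columns (e.g. six head-motion parameters) are appended per run when
    given as a list of (n_trs, k) arrays, or shared when a single array.

    Raises on a rank-deficient design, naming the offending columns.
    """
    if isinstance(runs, BoldRun):
        runs = [runs]
    X_parts, Y_parts, names = [], [], None
    nuis_list = None
    if nuisance is not None:
        nuis_list = nuisance if isinstance(nuisance, (list, tuple)) else [nuisance] * len(runs)
    n_cond = None
    for i, run in enumerate(runs):
        Xc, nm = condition_design_matrix(run.design)
        if names is None:
            names, n_cond = nm, Xc.shape[1]
        elif nm != names:
            raise ValueError("runs have inconsistent condition sets")
        cols = [Xc]
        if nuis_list is not None:
            cols.append(np.asarray(nuis_list[i], dtype=float))
        X_parts.append(np.hstack(cols))
        Y_parts.append(run.data.T)
    X = np.vstack(X_parts)
    # run-specific intercepts
    n_extra = X.shape[1] - n_cond
    icpt = np.zeros((X.shape[0], len(runs)))
    row = 0
    for i, run in enumerate(runs):
        icpt[row:row + run.n_trs, i] = 1.0
        row += run.n_trs
    X = np.hstack([X, icpt])
    Y = np.vstack(Y_parts)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by pivoted QR
        _, _, piv = scipy.linalg.qr(X, pivoting=True)
        bad = sorted(piv[rank:])
        all_names = (names + [f"nuisance_{k}" for k in range(n_extra)]
                     + [f"intercept_run{r}" for r in range(len(runs))])
        raise np.linalg.LinAlgError(
            f"rank-deficient design matrix; collinear columns: "
            f"{[all_names[b] for b in bad]}"
        )

    XtX_inv = np.linalg.inv(X.T @ X)
    betas = XtX_inv @ X.T @ Y                       # (p, n_voxels)
    resid = Y - X @ betas
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof

    c_full = np.zeros(X.shape[1])
    c_cond = localizer_contrast(names, contrast_kind)
    c_full[:n_cond] = c_cond
    var_c = c_full @ XtX_inv @ c_full
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c_full @ betas) / np.sqrt(sigma2 * var_c)
    return GlmResult(betas=betas, t_stat=t, regressor_names=names, contrast=c_full)


def extract_block_patterns(run: BoldRun, window: tuple = PEAK_WINDOW,
                           roi: str = "", layer: str = "",
                           voxel_indices: np.ndarray | None = None) -> PatternDataset:
    """One pattern row per condition block: the per-voxel mean over the
    peak TR window after block onset.

    ``window`` is 1-based inclusive TR ordinals after onset; the default
    (4, 8) averages offsets +3..+7, i.e. 6.18-14.42 s at TR 2.06 s.
    Blocks whose window extends past the run end are dropped with a
    warning.
    """
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError("window must be 1-based inclusive ordinals with lo <= hi")
    data = run.data if voxel_indices is None else run.data[voxel_indices]
    rows, oris, locs, runs_, blocks = [], [], [], [], []
    for _, ev in run.design.condition_events.iterrows():
        t0 = run.design.onset_tr(ev["onset"])
        a, b = t0 + lo - 1, t0 + hi  # python slice, inclusive ordinals
        if b > run.n_trs:
            logger.warning("block %d extends past run end; dropped", ev["block"])
            continue
        rows.append(data[:, a:b].mean(axis=1))
        oris.append(ev["orientation"])
        locs.append(ev["location"])
        runs_.append(run.run_id)
        blocks.append(ev["block"])
    return PatternDataset(
        X=np.array(rows),
        orientation=np.array(oris),
        location=np.array(locs),
        runs=np.array(runs_, dtype=int),
        blocks=np.array(blocks, dtype=int),
        session=run.session,
        roi=roi,
        layer=layer,
        voxel_indices=voxel_indices,
    )


def concat_patterns(datasets) -> PatternDataset:
    """Stack pattern datasets from several runs of one (ROI, layer, session)."""
    first = datasets[0]
    return PatternDataset(
        X=np.vstack([d.X for d in datasets]),
        orientation=np.concatenate([d.orientation for d in datasets]),
        location=np.concatenate([d.location for d in datasets]),
        runs=np.concatenate([d.runs for d in datasets]),
        blocks=np.concatenate([d.blocks for d in datasets]),
        session=first.session,
        roi=first.roi,
        layer=first.layer,
        voxel_indices=first.voxel_indices,
    )


def univariate_profile(datasets) -> pd.DataFrame:
    """Mean normalized response per condition x layer x session.

    Averages each dataset's pattern matrix over voxels and blocks (the
    time-point average is already folded into the pattern rows) and
    tabulates one scalar per (session, roi, layer, orientation, location).
    """
    rows = []
    for d in datasets:
        df = pd.DataFrame({
            "orientation": d.orientation,
            "location": d.location,
            "response": d.X.mean(axis=1),
        })
        g = df.groupby(["orientation", "location"], as_index=False)["response"].mean()
        g.insert(0, "layer", d.layer)
        g.insert(0, "roi", d.roi)
        g.insert(0, "session", d.session)
        rows.append(g)
    return pd.concat(rows, ignore_index=True)
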