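"""Layer-to-layer informational connectivity.

Pattern discriminability is tracked block by block as the signed distance
of each held-out test pattern from the trained classifier's hyperplane;
concatenating held-out folds yields one distance series per (ROI, layer,
session, task). Within each ROI, a layer's series is residualized on the
other two layers' series (OLS with intercept), and connectivity between
two regions is the partial Spearman correlation of the residual series,
Fisher z-transformed for inference.

Two anatomically motivated pathways are contrasted: feedforward
(sensory-region superficial layers to decision-region middle layers) and
feedback (deeper layers to deeper layers). The superficial-to-deeper pair
is deliberately not analyzed, since it mixes feedforward and feedback
contributions. Learning-dependent change is the Fisher-z difference
post-minus-pre per pathway and condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import PatternDataset
from .mvpa import DecodingResult, fisher_z

#: pathway name -> (sensory-region layer, decision-region layer)
PATHWAYS = {
    "feedforward": ("superficial", "middle"),
    "feedback": ("deeper", "deeper"),
}


@dataclass
class DistanceSeries:
    """Block-ordered signed hyperplane distances for one (ROI, layer,
    session, task). ``blocks`` holds (run, block) keys so series from
    different layers of the same ROI/session align exactly."""

    values: np.ndarray
    runs: np.ndarray
    blocks: np.ndarray
    roi: str = ""
    layer: str = ""
    session: str = ""
    task: tuple = ("", "")

    def __len__(self):
        return len(self.values)


def hyperplane_distances(result: DecodingResult, dataset: PatternDataset) -> DistanceSeries:
    """Signed distance to the decision hyperplane for every held-out block.

    For each cross-validation fold, the fold's trained classifier is
    applied to its held-out run's patterns: distance =
    ``(w @ x + b) / ||w||``, then signed toward the correct class (positive
    = the pattern lies on its own class's side, i.e. larger = more
    discriminable). Folds are concatenated in run/block order.
    """
    ds = dataset.task_subset(*result.task)
    class_a = result.task[0]
    vals, runs_, blocks = [], [], []
    for clf in result.classifiers:
        test = ds.runs == clf.fold
        X, y = ds.X[test], ds.orientation[test]
        wnorm = np.linalg.norm(clf.weights)
        if wnorm == 0:
            raise ValueError("zero weight vector; distances undefined")
        d = clf.decision(X) / wnorm
        sign = np.where(y == class_a, 1.0, -1.0)
        vals.append(d * sign)
        runs_.append(ds.runs[test])
        blocks.append(ds.blocks[test])
    values = np.concatenate(vals)
    runs_ = np.concatenate(runs_)
    blocks = np.concatenate(blocks)
    order = np.lexsort((blocks, runs_))
    return DistanceSeries(values=values[order], runs=runs_[order],
                          blocks=blocks[order], roi=ds.roi, layer=ds.layer,
                          session=ds.session, task=result.task)


def residualize(target: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """OLS residuals of ``target`` on columns of ``controls`` plus intercept."""
    y = np.asarray(target, dtype=float)
    Z = np.atleast_2d(np.asarray(controls, dtype=float))
    if Z.shape[0] == y.size and Z.ndim == 2:
        X = Z
    else:
        X = Z.T
    if X.shape[0] != y.size:
        raise ValueError("length mismatch between target and controls")
    X = np.column_stack([np.ones(y.size), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def residualize_within_roi(series: DistanceSeries, others) -> DistanceSeries:
    """Regress the other layers' distance series out of a layer's series."""
    for o in others:
        if len(o) != len(series):
            raise ValueError("distance series have mismatched lengths")
        if not (np.array_equal(o.runs, series.runs) and np.array_equal(o.blocks, series.blocks)):
            raise ValueError("distance series are not block-aligned")
    controls = np.column_stack([o.values for o in others])
    res = residualize(series.values, controls)
    return DistanceSeries(values=res, runs=series.runs, blocks=series.blocks,
                          roi=series.roi, layer=series.layer,
                          session=series.session, task=series.task)


def partial_spearman(a: np.ndarray, b: np.ndarray,
                     controls_a: np.ndarray | None = None,
                     controls_b: np.ndarray | None = None) -> tuple[float, float]:
    """Partial Spearman correlation and its Fisher z.

    All series are rank-transformed (average ranks for ties); the ranks
    of ``a`` are residualized on the ranks of ``controls_a``, likewise
    ``b`` on ``controls_b`` (intercept included), and the Pearson
    correlation of the rank residuals is returned — the standard
    partial-Spearman construction. With no controls this reduces to the
    ordinary Spearman correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 aligned observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant series; correlation undefined")
    ra, rb = rankdata(a), rankdata(b)
    if controls_a is not None and np.size(controls_a):
        Za = np.atleast_2d(np.asarray(controls_a, dtype=float))
        Za = Za if Za.shape[0] == a.size else Za.T
        ra = residualize(ra, np.column_stack([rankdata(z) for z in Za.T]))
    else:
        ra = ra - ra.mean()
    if controls_b is not None and np.size(controls_b):
        Zb = np.atleast_2d(np.asarray(controls_b, dtype=float))
        Zb = Zb if Zb.shape[0] == b.size else Zb.T
        rb = residualize(rb, np.column_stack([rankdata(z) for z in Zb.T]))
    else:
        rb = rb - rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        raise ValueError("degenerate residual series; correlation undefined")
    rho = float((ra @ rb) / denom)
    return rho, float(fisher_z(rho))


def layer_pair_connectivity(series_a: dict, series_b: dict,
                            layer_a: str, layer_b: str) -> tuple[float, float]:
    """Partial Spearman between one layer of each region.

    ``series_a``/``series_b`` map layer name -> :class:`DistanceSeries`
    for a region; the control series for each side are the region's other
    two layers (within-ROI residualization on ranks).
    """
    sa = series_a[layer_a]
    sb = series_b[layer_b]
    ctrl_a = np.column_stack([series_a[l].values for l in series_a if l != layer_a])
    ctrl_b = np.column_stack([series_b[l].values for l in series_b if l != layer_b])
    return partial_spearman(sa.values, sb.values, ctrl_a, ctrl_b)


def pathway_connectivity(series_a: dict, series_b: dict) -> pd.DataFrame:
    """Feedforward and feedback pathway connectivity for one session/task."""
    rows = []
    for pathway, (la, lb) in PATHWAYS.items():
        rho, z = layer_pair_connectivity(series_a, series_b, la, lb)
        rows.append(dict(pathway=pathway, layer_a=la, layer_b=lb, rho=rho, z=z))
    return pd.DataFrame(rows)


def pathway_contrast(table: pd.DataFrame) -> pd.DataFrame:
    """Learning-dependent connectivity change (Fisher z post minus pre).

    ``table`` must hold one row per (pathway, condition, session) with a
    ``z`` column and both sessions present for every (pathway, condition);
    missing cells raise an error listing the combinations.
    """
    piv = table.pivot_table(index=["pathway", "condition"], columns="session",
                            values="z", aggfunc="mean")
    missing = [idx for idx in piv.index
               if "pre" not in piv.columns or "post" not in piv.columns
               or pd.isna(piv.loc[idx]).any()]
    if "pre" not in piv.columns or "post" not in piv.columns or missing:
        raise ValueError(f"missing session cells for: {missing or 'all'}")
    out = piv.reset_index()
    out["delta_z"] = out["post"] - out["pre"]
    return out[["pathway", "condition", "pre", "post", "delta_z"]]
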