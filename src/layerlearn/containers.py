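"""Core in-memory containers shared across the pipeline.

The pipeline operates on a small set of plain dataclasses:

``LaminarVolume``
    A voxel grid with a gray-matter mask, per-voxel cortical depth in
    [0, 1] (0 = white-matter boundary, 1 = pial surface), a column id per
    voxel, and per-column thickness/curvature maps.

``BlockDesign``
    A block-design event table (BIDS-events-like) plus the TR, backed by a
    :class:`pandas.DataFrame`.

``BoldRun``
    A voxels x timepoints matrix restricted to gray-matter voxels, with
    run/session identifiers and its attached :class:`BlockDesign`.

``PatternDataset``
    A blocks x voxels response matrix with orientation/location labels and
    run ids, for one (ROI, layer, session) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Cortical compartments in depth order (index 0 borders white matter).
LAYERS = ("deeper", "middle", "superficial")

#: Orientation conditions used throughout.
ORIENTATIONS = ("trained", "untrained", "control")

#: Stimulus locations (visual hemifields).
LOCATIONS = ("left", "right")

#: Integer codes used in layer-label arrays.
LAYER_CODES = {name: i for i, name in enumerate(LAYERS)}
NON_GRAY = -1


@dataclass
class LaminarVolume:
    """Voxel grid of a cortical patch with depth and column bookkeeping.

    Attributes
    ----------
    shape : tuple of int
        Grid shape (nx, ny, nz).
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm.
    gm_mask : ndarray of bool, shape ``shape``
        True for gray-matter voxels.
    depth : ndarray of float, shape ``shape``
        Cortical depth per voxel in [0, 1]; NaN outside the gray matter.
        Convention: 0 = white-matter boundary, 1 = pial surface.
    column_id : ndarray of int, shape ``shape``
        Cortical-column index per voxel; -1 outside the gray matter.
    thickness_mm : ndarray of float, shape (n_columns,)
        Cortical thickness per column.
    curvature : ndarray of float, shape (n_columns,)
        Signed curvature per column in 1/mm. Positive curvature means the
        local cross-sectional area of the sheet grows toward the pial
        surface (a gyral crown seen from white matter).
    layer_labels : ndarray of int, shape ``shape``, optional
        Compartment code per voxel (see :data:`LAYER_CODES`); -1 outside
        gray matter. Filled in by layer assignment.
    vein_mask : ndarray of bool, shape ``shape``, optional
        Ground-truth large-vein voxels (synthetic data only).
    """

    shape: tuple
    voxel_size_mm: tuple
    gm_mask: np.ndarray
    depth: np.ndarray
    column_id: np.ndarray
    thickness_mm: np.ndarray
    curvature: np.ndarray
    layer_labels: np.ndarray | None = None
    vein_mask: np.ndarray | None = None

    @property
    def n_gray(self) -> int:
        return int(self.gm_mask.sum())

    @property
    def n_columns(self) -> int:
        return len(self.thickness_mm)

    def gray_indices(self) -> np.ndarray:
        """Flat voxel coordinates (N, 3) of gray-matter voxels, in a fixed
        C order used consistently by every module that flattens the grid."""
        return np.argwhere(self.gm_mask)

    def gray_coords_mm(self) -> np.ndarray:
        """Gray-matter voxel centers in mm, same ordering as
        :meth:`gray_indices`."""
        return self.gray_indices() * np.asarray(self.voxel_size_mm)

    def gray_values(self, arr: np.ndarray) -> np.ndarray:
        """Extract a per-gray-voxel vector from a full-grid array."""
        return arr[self.gm_mask]


class BlockDesign:
    """Block-design event table with TR bookkeeping.

    Parameters
    ----------
    events : DataFrame
        Columns: ``onset`` (s), ``duration`` (s), ``trial_type`` (str,
        ``"fixation"`` or ``"<orientation>_<location>"``), ``orientation``,
        ``location``, ``block`` (0-based index among condition blocks;
        -1 for fixation).
    tr_s : float
        Repetition time in seconds.
    n_trs : int
        Number of volumes in the run.
    """

    def __init__(self, events: pd.DataFrame, tr_s: float, n_trs: int):
        required = {"onset", "duration", "trial_type", "orientation", "location", "block"}
        missing = required - set(events.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        if not events["onset"].is_monotonic_increasing:
            raise ValueError("event onsets must be sorted")
        self.events = events.reset_index(drop=True)
        self.tr_s = float(tr_s)
        self.n_trs = int(n_trs)

    @property
    def condition_events(self) -> pd.DataFrame:
        return self.events[self.events["trial_type"] != "fixation"]

    @property
    def n_condition_blocks(self) -> int:
        return len(self.condition_events)

    def onset_tr(self, onset_s: float) -> int:
        """Map an onset in seconds to a TR index by the nearest-TR rule."""
        return int(round(onset_s / self.tr_s))

    def conditions(self) -> list[str]:
        return sorted(self.condition_events["trial_type"].unique())


@dataclass
class BoldRun:
    """One run of laminar BOLD data over the gray-matter voxels.

    ``data`` has shape (n_gray_voxels, n_trs) and is aligned with
    ``LaminarVolume.gray_indices()`` row order.
    """

    data: np.ndarray
    tr_s: float
    run_id: int
    session: str
    design: BlockDesign

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("BoldRun.data must be 2-D (voxels x timepoints)")
        if self.data.shape[1] != self.design.n_trs:
            raise ValueError(
                f"data has {self.data.shape[1]} timepoints but design expects "
                f"{self.design.n_trs}"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)


@dataclass
class PatternDataset:
    """Blocks x voxels response patterns for one (ROI, layer, session).

    Attributes
    ----------
    X : ndarray, shape (n_blocks, n_voxels)
        Mean z-scored responses in the peak window, one row per block.
    orientation : ndarray of str
        Orientation label per block (trained/untrained/control).
    location : ndarray of str
        Stimulus location per block.
    runs : ndarray of int
        Run id per block (cross-validation grouping).
    blocks : ndarray of int
        Within-run condition-block index per row (ordering key).
    session : str
    roi : str
    layer : str
    voxel_indices : ndarray of int
        Indices into the run's gray-voxel axis for each column of ``X``.
    """

    X: np.ndarray
    orientation: np.ndarray
    location: np.ndarray
    runs: np.ndarray
    blocks: np.ndarray
    session: str = ""
    roi: str = ""
    layer: str = ""
    voxel_indices: np.ndarray | None = None

    def __post_init__(self):
        n = self.X.shape[0]
        for name in ("orientation", "location", "runs", "blocks"):
            v = getattr(self, name)
            if len(v) != n:
                raise ValueError(f"{name} has length {len(v)}, expected {n}")

    @property
    def n_blocks(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def subset_blocks(self, mask: np.ndarray) -> "PatternDataset":
        return PatternDataset(
            X=self.X[mask],
            orientation=self.orientation[mask],
            location=self.location[mask],
            runs=self.runs[mask],
            blocks=self.blocks[mask],
            session=self.session,
            roi=self.roi,
            layer=self.layer,
            voxel_indices=self.voxel_indices,
        )

    def subset_voxels(self, idx: np.ndarray) -> "PatternDataset":
        vi = None if self.voxel_indices is None else self.voxel_indices[idx]
        return PatternDataset(
            X=self.X[:, idx],
            orientation=self.orientation,
            location=self.location,
            runs=self.runs,
            blocks=self.blocks,
            session=self.session,
            roi=self.roi,
            layer=self.layer,
            voxel_indices=vi,
        )

    def task_subset(self, class_a: str, class_b: str, location: str | None = None) -> "PatternDataset":
        """Restrict to a two-class decoding task (e.g. trained vs control),
        optionally at a single stimulus location."""
        mask = np.isin(self.orientation, [class_a, class_b])
        if location is not None:
            mask &= self.location == location
        return self.subset_blocks(mask)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X)
        df.insert(0, "block", self.blocks)
        df.insert(0, "run", self.runs)
        df.insert(0, "location", self.location)
        df.insert(0, "orientation", self.orientation)
        return df


@dataclass
class StaircaseTrace:
    """Full log of one adaptive-staircase run.

    ``levels[i]`` is the stimulus level (degrees) presented on trial ``i``;
    ``correct[i]`` the observer's response; ``reversal[i]`` flags trials on
    which the direction of level change flipped.
    """

    levels: np.ndarray
    correct: np.ndarray
    reversal: np.ndarray
    threshold_deg: float | None = None

    @property
    def n_trials(self) -> int:
        return len(self.levels)

    @property
    def n_reversals(self) -> int:
        return int(self.reversal.sum())

    def reversal_levels(self) -> np.ndarray:
        return self.levels[self.reversal.astype(bool)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "level_deg": self.levels,
                "correct": self.correct.astype(int),
                "reversal": self.reversal.astype(int),
            }
        )
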