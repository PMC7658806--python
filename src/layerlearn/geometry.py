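"""Equi-volume cortical depth grids and layer assignment.

Cortical gray matter is modeled per column: a straight segment from the
white-matter boundary (depth 0) to the pial surface (depth 1) with a local
thickness ``T`` (mm) and a signed curvature ``c`` (1/mm). The equi-volume
construction places ``n_grids`` intermediate surfaces so that the tissue
volume between consecutive surfaces is equal, compensating for cortical
folding: in a gyrus, where the sheet's cross-sectional area widens toward
the pial surface, an equi-volume grid sits deeper than the corresponding
equidistant grid, and vice versa in a sulcus.

Area model
----------
The cross-sectional area of the sheet at distance ``x`` mm from the
white-matter boundary is taken to vary linearly::

    A(x) = A0 * (1 + c * x),   0 <= x <= T

which is exact for a cylindrically folded sheet (c = 1/R with R the
white-matter radius of curvature) and first-order correct in general. The
cumulative volume is then ``V(x) = A0 * (x + c * x**2 / 2)`` and the
equi-volume depth of grid k solves ``V(x_k) = (k / (n-1)) * V(T)`` in
closed form. With zero curvature the construction reduces exactly to
equidistant grids.

Voxels are assigned to one of three compartments (deeper, middle,
superficial) by Euclidean distance to the grid surfaces: the two nearest
grids bound the compartment the voxel belongs to. A voxel equidistant from
two compartment boundaries is assigned to the deeper compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import LAYER_CODES, LAYERS, NON_GRAY, LaminarVolume

logger = logging.getLogger(__name__)


@dataclass
class DepthGrids:
    """Per-column equi-volume grid depths.

    ``depth_fractions`` has shape (n_grids, n_columns); row k holds the
    normalized depth (0 = white matter, 1 = pial) of grid k in every
    column. Rows are strictly increasing from 0 to 1.
    """

    depth_fractions: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depth_fractions, dtype=float)
        if d.ndim != 2:
            raise ValueError("depth_fractions must be 2-D (n_grids, n_columns)")
        self.depth_fractions = d

    @property
    def n_grids(self) -> int:
        return self.depth_fractions.shape[0]

    @property
    def n_columns(self) -> int:
        return self.depth_fractions.shape[1]


def equivolume_depth(volume_fraction, thickness_mm, curvature):
    """Depth (mm from white matter) enclosing a given tissue-volume fraction.

    Solves ``x + c x^2/2 = f (T + c T^2/2)`` for ``x``; broadcasting over
    array inputs. With ``c == 0`` this is simply ``f * T``.
    """
    f = np.asarray(volume_fraction, dtype=float)
    T = np.asarray(thickness_mm, dtype=float)
    c = np.asarray(curvature, dtype=float)
    target = f * (T + 0.5 * c * T**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_curved = (np.sqrt(1.0 + 2.0 * c * target) - 1.0) / c
    x_flat = target
    return np.where(np.abs(c) < 1e-12, x_flat, x_curved)


def equivolume_grids(thickness_mm, curvature, n_grids: int = 4) -> DepthGrids:
    """Compute per-column equi-volume grid depths.

    Parameters
    ----------
    thickness_mm : array-like, shape (n_columns,)
        Cortical thickness per column; must be strictly positive.
    curvature : array-like, shape (n_columns,)
        Signed curvature per column (1/mm); positive when the sheet's
        cross-sectional area grows toward the pial surface. Must satisfy
        ``1 + c*T > 0`` so that the area stays positive through the ribbon.
    n_grids : int
        Number of grid surfaces (>= 2). The outermost grids coincide with
        the white-matter and pial surfaces; ``n_grids - 1`` equal-volume
        compartments lie between them.

    Returns
    -------
    DepthGrids
        Normalized grid depths, shape (n_grids, n_columns).
    """
    T = np.atleast_1d(np.asarray(thickness_mm, dtype=float))
    c = np.atleast_1d(np.asarray(curvature, dtype=float))
    if T.shape != c.shape:
        raise ValueError("thickness and curvature must have the same shape")
    if n_grids < 2:
        raise ValueError("n_grids must be at least 2")
    if np.any(~np.isfinite(T)) or np.any(T <= 0):
        raise ValueError("thickness must be positive and finite everywhere")
    if np.any(~np.isfinite(c)):
        raise ValueError("curvature must be finite")
    if np.any(1.0 + c * T <= 0):
        raise ValueError("curvature too negative: area vanishes inside the ribbon")

    fractions = np.linspace(0.0, 1.0, n_grids)
    depths = np.empty((n_grids, T.size))
    for k, f in enumerate(fractions):
        depths[k] = equivolume_depth(f, T, c) / T
    # endpoints are exact by construction; enforce against round-off
    depths[0] = 0.0
    depths[-1] = 1.0
    return DepthGrids(depth_fractions=depths)


def assign_layers(volume: LaminarVolume, grids: DepthGrids) -> np.ndarray:
    """Assign gray-matter voxels to compartments by distance to the grids.

    Each gray voxel's Euclidean distance to every grid surface is computed
    along its column (|voxel depth - grid depth| x column thickness, in
    mm); the two nearest grids bound the compartment the voxel is assigned
    to. Ties (a voxel exactly on an interior grid) go to the deeper
    compartment. With four grids the three compartments map onto
    (deeper, middle, superficial).

    Returns the label array (full grid shape, int codes per
    :data:`layerlearn.containers.LAYER_CODES`, -1 outside gray matter) and
    stores it on ``volume.layer_labels``.
    """
    if grids.n_columns != volume.n_columns:
        raise ValueError(
            f"grids cover {grids.n_columns} columns, volume has {volume.n_columns}"
        )
    n_compartments = grids.n_grids - 1
    if n_compartments != len(LAYERS):
        raise ValueError(
            f"layer naming requires {len(LAYERS) + 1} grids, got {grids.n_grids}"
        )

    labels = np.full(volume.shape, NON_GRAY, dtype=np.int8)
    idx = volume.gray_indices()
    depths = volume.depth[volume.gm_mask]
    cols = volume.column_id[volume.gm_mask]
    thick = volume.thickness_mm[cols]

    out_of_range = (depths < 0) | (depths > 1)
    if np.any(out_of_range):
        logger.warning(
            "%d gray voxels fall outside the grid span; assigned to the nearest compartment",
            int(out_of_range.sum()),
        )

    # distances to every grid, (n_gray, n_grids), in mm along the column
    grid_d = grids.depth_fractions[:, cols].T
    dist = np.abs(depths[:, None] - grid_d) * thick[:, None]

    # two nearest grids bound the compartment; stable argsort makes the
    # lower-index grid win ties, which lands boundary voxels in the deeper
    # compartment
    order = np.argsort(dist, axis=1, kind="stable")
    compartment = np.minimum(order[:, 0], order[:, 1])
    compartment = np.clip(compartment, 0, n_compartments - 1)

    labels[tuple(idx.T)] = compartment
    volume.layer_labels = labels
    return labels


def layer_mask(volume: LaminarVolume, layer: str) -> np.ndarray:
    """Boolean vector over gray voxels selecting one compartment."""
    if volume.layer_labels is None:
        raise ValueError("volume has no layer labels; run assign_layers first")
    return volume.layer_labels[volume.gm_mask] == LAYER_CODES[layer]
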