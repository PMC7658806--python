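"""Synthetic laminar BOLD generator.

Forward model producing everything the analysis modules consume, with
known ground truth: a cortical patch with three depth compartments, a
block design (six stimulus conditions plus fixation), laminar BOLD with a
draining-vein / superficial-bias confound, condition-specific multivoxel
pattern signal injected at chosen depths, and block-to-block fluctuations
of pattern discriminability that can be shared between two regions to
create ground-truth informational connectivity. A stochastic psychometric
observer drives the adaptive-staircase module.

Signal model (per gray voxel v, TR t)
-------------------------------------
::

    y_v(t) = B_v + bias_v * [ act_v(t) + pat_v(t) + drain_v(t) ] + eps_v(t)

* ``B_v``: baseline 100 (x ``vein_mean_factor`` for vein voxels).
* ``act_v(t)``: stimulus-evoked response, one boxcar per condition block
  convolved with a double-gamma canonical HRF, scaled by the activation
  amplitude (% signal change) and the voxel's location gain (lateralized
  regions prefer one hemifield, which gives the left-vs-right localizer
  contrast its ground truth).
* ``pat_v(t)``: condition-specific multivoxel pattern (a fixed N(0,1)
  voxel weight per condition, drawn from ``pattern_seed``), present only
  at the configured depths, scaled by the pattern amplitude, the session
  gain (models learning) and a latent block-wise fluctuation series.
* ``bias_v = 1 + (superficial_gain - 1) * depth_v``: the superficial
  amplitude bias of gradient-echo BOLD.
* ``drain_v(t)``: for superficial voxels, ``drainage_lambda`` times the
  mean clean signal of same-column voxels at middle/deeper depths —
  ascending-vein drainage mixing.
* ``eps_v(t)``: AR(1) Gaussian noise (sd ``noise_sd``, lag-1 coefficient
  ``noise_ar1``); vein voxels have their noise sd doubled (variance x 4).

The latent fluctuation series is block-wise multiplicative amplitude
jitter, ``g_b = max(0, 1 + sd * z_b)`` with ``z`` standard normal;
:func:`simulate_two_regions` draws ``z`` jointly for a designated pair of
layers so the two regions' pattern discriminability covaries at a chosen
correlation on the coupled condition's blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .containers import (
    LAYERS,
    LOCATIONS,
    ORIENTATIONS,
    BlockDesign,
    BoldRun,
    LaminarVolume,
)

__all__ = [
    "PatchSpec",
    "DesignSpec",
    "EffectSpec",
    "VascularSpec",
    "ObserverSpec",
    "Observer",
    "GroundTruth",
    "generate_patch",
    "generate_design",
    "generate_session_designs",
    "simulate_bold",
    "simulate_two_regions",
    "simulate_observer_response",
    "double_gamma_hrf",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class PatchSpec:
    """Geometry of a synthetic cortical patch.

    ``curvature`` = 0 builds a flat slab (columns along x, y; depth along
    z). A nonzero uniform curvature builds a cylindrically curved wedge
    with white-matter radius ``1/curvature``, where the analysis's linear
    area model is exact.
    """

    grid_shape: tuple = (10, 10, 12)
    voxel_size_mm: tuple = (0.8, 0.8, 0.8)
    thickness_mm: float = 2.4
    curvature: float = 0.0
    thickness_jitter_sd: float = 0.0  # per-column mm jitter, seeded

    def validate(self):
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive counts")
        if not np.isfinite(self.curvature):
            raise ValueError("curvature must be finite")


@dataclass
class DesignSpec:
    """Block-design parameters (TR 2.06 s, 12.36-s blocks by default).

    Six stimulus conditions (three orientations x two locations) plus
    fixation. Each run opens with a fixation block and then repeats
    (six condition blocks + fixation) ``repeats_per_run`` times, with
    orientation order randomized and location alternating between blocks.
    """

    tr_s: float = 2.06
    block_s: float = 12.36
    orientations: tuple = ORIENTATIONS
    locations: tuple = LOCATIONS
    repeats_per_run: int = 4
    n_runs: int = 8
    trials_per_block: int = 5

    def validate(self):
        if self.repeats_per_run < 1:
            raise ValueError("repeats_per_run must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.tr_s <= 0 or self.block_s <= 0:
            raise ValueError("tr_s and block_s must be positive")

    @property
    def block_trs(self) -> int:
        """Block length on the TR grid by the nearest-TR rounding rule
        (12.36 s = exactly 6 TR at 2.06 s)."""
        return int(round(self.block_s / self.tr_s))

    @property
    def n_conditions(self) -> int:
        return len(self.orientations) * len(self.locations)


@dataclass
class EffectSpec:
    """Pattern-signal ground truth for one region.

    ``pattern_amplitude`` is the sd of the condition-specific voxel
    pattern in % signal change; it is injected at ``target_layer`` (or at
    every layer listed in ``layer_amplitudes``). ``session_gain`` maps
    session name to a multiplier on the target layer's pattern for the
    ``gain_orientation`` condition only — learning is specific to the
    trained stimulus. ``coupled_fluctuation_sd`` sets the block-wise
    amplitude jitter; :func:`simulate_two_regions` correlates that jitter
    across regions.
    """

    target_layer: str = "middle"
    pattern_amplitude: float = 1.0
    pattern_seed: int = 0
    session_gain: Mapping[str, float] = field(default_factory=lambda: {"pre": 1.0, "post": 1.0})
    gain_orientation: str = "trained"
    coupled_fluctuation_sd: float = 0.3
    coupling_rho: float = 0.0
    activation_amplitude: float = 2.0
    lateralized: bool = True
    layer_amplitudes: Mapping[str, float] | None = None

    def validate(self):
        if self.pattern_amplitude < 0:
            raise ValueError("pattern_amplitude must be >= 0")
        if abs(self.coupling_rho) > 1:
            raise ValueError("|coupling_rho| must be <= 1")
        if self.target_layer not in LAYERS:
            raise ValueError(f"unknown layer {self.target_layer!r}")

    def amplitudes(self) -> dict:
        """Per-layer pattern amplitude (zero where no signal)."""
        if self.layer_amplitudes is not None:
            return {lay: float(self.layer_amplitudes.get(lay, 0.0)) for lay in LAYERS}
        return {lay: (self.pattern_amplitude if lay == self.target_layer else 0.0) for lay in LAYERS}


@dataclass
class VascularSpec:
    """Vascular confound ground truth.

    ``superficial_gain`` >= 1 multiplies signal amplitude linearly in
    depth (1 at the white-matter boundary, ``superficial_gain`` at the
    pial surface). ``drainage_lambda`` in [0, 1] is the fraction of the
    mean middle/deeper clean signal mixed into each superficial voxel.
    ``vein_fraction`` of voxels are marked as large veins: noise variance
    x ``vein_var_factor``, baseline intensity x ``vein_mean_factor`` —
    giving tSNR-based exclusion a ground truth.
    """

    superficial_gain: float = 2.0
    drainage_lambda: float = 0.3
    vein_fraction: float = 0.1
    vein_var_factor: float = 4.0
    vein_mean_factor: float = 0.6

    def validate(self):
        if not (0.0 <= self.drainage_lambda <= 1.0):
            raise ValueError("drainage_lambda must be in [0, 1]")
        if not (0.0 <= self.vein_fraction < 1.0):
            raise ValueError("vein_fraction must be in [0, 1)")
        if self.superficial_gain < 1.0:
            raise ValueError("superficial_gain must be >= 1")


@dataclass
class ObserverSpec:
    """Stochastic psychometric observer for a 2AFC discrimination task.

    ``psychometric_family`` selects the shape of the percent-correct
    function of the stimulus level x (degrees):

    * ``cumulative-gaussian``:
      ``p(x) = 0.5 + (0.5 - lapse) * Phi((x - threshold) / (threshold/slope))``;
      the defining criterion is ``p(threshold) = 0.75 - lapse/2``.
    * ``weibull``:
      ``p(x) = 0.5 + (0.5 - lapse) * (1 - exp(-(x/threshold)**slope))``;
      the defining criterion is ``p(threshold) = 0.5 + (0.5 - lapse)*(1 - 1/e)``.

    Both families are monotone non-decreasing in x, start at 0.5 (guess
    rate) near x = 0 and asymptote at ``1 - lapse``.
    """

    psychometric_family: str = "cumulative-gaussian"
    threshold_deg: float = 2.0
    slope: float = 3.0
    lapse_rate: float = 0.01
    seed: int = 0

    def validate(self):
        if self.psychometric_family not in ("cumulative-gaussian", "weibull"):
            raise ValueError(f"unknown family {self.psychometric_family!r}")
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must be in [0, 0.1]")
        if self.threshold_deg <= 0 or self.slope <= 0:
            raise ValueError("threshold and slope must be positive")


class Observer:
    """Stateful observer: draws Bernoulli responses from its psychometric
    function with a private seeded generator."""

    def __init__(self, spec: ObserverSpec):
        spec.validate()
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)

    def percent_correct(self, level_deg) -> np.ndarray:
        """True probability of a correct response at a stimulus level."""
        x = np.asarray(level_deg, dtype=float)
        if np.any(x < 0):
            raise ValueError("stimulus level must be >= 0")
        s = self.spec
        if s.psychometric_family == "cumulative-gaussian":
            core = norm.cdf((x - s.threshold_deg) / (s.threshold_deg / s.slope))
        else:
            core = 1.0 - np.exp(-((x / s.threshold_deg) ** s.slope))
        return 0.5 + (0.5 - s.lapse_rate) * core

    def respond(self, level_deg: float) -> bool:
        """One Bernoulli trial at the given level."""
        return bool(self.rng.random() < self.percent_correct(level_deg))


def simulate_observer_response(observer: Observer, level_deg: float) -> bool:
    """Draw a correct/incorrect response from a seeded observer."""
    return observer.respond(level_deg)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def generate_patch(spec: PatchSpec, seed: int = 0) -> LaminarVolume:
    """Build a cortical patch with known per-voxel depth.

    Flat mode (curvature 0): columns are (x, y) positions, the gray
    matter spans z in [0, thickness], and depth varies linearly with z.
    Curved mode (uniform curvature c > 0): a cylindrical wedge with
    white-matter radius 1/c in the x-z plane; depth follows the radial
    formula ``(r - R_wm) / thickness``.

    Deterministic given the seed (the seed only matters when
    ``thickness_jitter_sd`` > 0).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size_mm

    if abs(spec.curvature) < 1e-12:
        n_columns = nx * ny
        thickness = np.full(n_columns, spec.thickness_mm)
        if spec.thickness_jitter_sd > 0:
            thickness = thickness + rng.normal(0, spec.thickness_jitter_sd, n_columns)
            thickness = np.clip(thickness, 0.5 * spec.thickness_mm, None)
        curvature = np.zeros(n_columns)

        iz = (np.arange(nz) + 0.5) * dz
        col = (np.arange(nx)[:, None] * ny + np.arange(ny)[None, :])  # (nx, ny)
        column_id = np.repeat(col[:, :, None], nz, axis=2)
        depth = iz[None, None, :] / thickness[col][:, :, None]
        gm = (depth >= 0.0) & (depth <= 1.0)
    else:
        if spec.curvature < 0:
            raise ValueError("curved patches use positive curvature (1/R of the white surface)")
        r_wm = 1.0 / spec.curvature
        T = spec.thickness_mm
        # radial sheet in the x-z plane, cylinder axis along y
        x = (np.arange(nx) + 0.5) * dx
        z = r_wm - 0.5 * T + (np.arange(nz) + 0.5) * dz  # window around the ribbon
        xx, zz = np.meshgrid(x, z, indexing="ij")
        r = np.sqrt(xx**2 + zz**2)
        theta = np.arctan2(xx, zz)
        depth_xz = (r - r_wm) / T
        gm_xz = (depth_xz >= 0.0) & (depth_xz <= 1.0)
        # columns: angular bins x y-slices
        n_theta = nx
        t_edges = np.linspace(theta.min() - 1e-9, theta.max() + 1e-9, n_theta + 1)
        t_bin = np.digitize(theta, t_edges) - 1
        n_columns = n_theta * ny
        depth = np.repeat(depth_xz[:, None, :], ny, axis=1)
        gm = np.repeat(gm_xz[:, None, :], ny, axis=1)
        column_id = (
            t_bin[:, None, :] * ny + np.arange(ny)[None, :, None]
        )
        thickness = np.full(n_columns, T)
        curvature = np.full(n_columns, spec.curvature)

    depth = np.where(gm, depth, np.nan)
    column_id = np.where(gm, column_id, -1).astype(int)
    if not gm.any():
        raise ValueError("patch contains no gray-matter voxels; enlarge the grid")
    return LaminarVolume(
        shape=(nx, ny, nz),
        voxel_size_mm=(dx, dy, dz),
        gm_mask=gm,
        depth=depth,
        column_id=column_id,
        thickness_mm=thickness,
        curvature=curvature,
    )


def assign_veins(volume: LaminarVolume, vein_fraction: float, seed: int) -> np.ndarray:
    """Mark a random fraction of gray voxels as large-vein voxels.

    Vein probability doubles with depth (pial surface drains more), but
    any gray voxel may be a vein. Stored on ``volume.vein_mask``.
    """
    rng = np.random.default_rng(seed)
    depth = volume.depth[volume.gm_mask]
    n = volume.n_gray
    k = int(round(vein_fraction * n))
    mask = np.zeros(volume.shape, dtype=bool)
    if k > 0:
        w = 1.0 + depth  # mild superficial preference
        p = w / w.sum()
        pick = rng.choice(n, size=k, replace=False, p=p)
        idx = volume.gray_indices()[pick]
        mask[tuple(idx.T)] = True
    volume.vein_mask = mask
    return mask


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def generate_design(spec: DesignSpec, seed: int = 0) -> BlockDesign:
    """Generate one run's block design.

    The run opens with a fixation block; each of ``repeats_per_run``
    repeats presents the six conditions (three orientations at two
    locations) in blocks with randomized orientation order and the
    stimulus location alternating between consecutive blocks, followed by
    a fixation block.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n_ori = len(spec.orientations)
    rows = []
    onset = 0.0
    block_idx = 0

    def fixation_row(onset):
        return dict(onset=onset, duration=spec.block_s, trial_type="fixation",
                    orientation="none", location="none", block=-1)

    rows.append(fixation_row(onset))
    onset += spec.block_s
    for _ in range(spec.repeats_per_run):
        start_loc = int(rng.integers(2))
        # orientation order randomized independently for the two
        # alternating location slots -> each condition appears once
        order_a = rng.permutation(n_ori)
        order_b = rng.permutation(n_ori)
        for i in range(2 * n_ori):
            loc = spec.locations[(start_loc + i) % 2]
            ori = spec.orientations[(order_a if (start_loc + i) % 2 == start_loc % 2 else order_b)[i // 2]]
            rows.append(dict(onset=onset, duration=spec.block_s,
                             trial_type=f"{ori}_{loc}", orientation=ori,
                             location=loc, block=block_idx))
            onset += spec.block_s
            block_idx += 1
        rows.append(fixation_row(onset))
        onset += spec.block_s

    events = pd.DataFrame(rows)
    n_trs = int(round(onset / spec.tr_s))
    return BlockDesign(events=events, tr_s=spec.tr_s, n_trs=n_trs)


def generate_session_designs(spec: DesignSpec, seed: int = 0) -> list[BlockDesign]:
    """One design per run, with run-specific randomization."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(spec.n_runs)
    return [generate_design(spec, int(s % (2**31))) for s in seeds]


# --------------------------------------------------------------------------
# HRF and BOLD
# --------------------------------------------------------------------------

def double_gamma_hrf(tr_s: float, duration_s: float = 30.0,
                     peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled on the TR grid.

    Difference of two gamma densities (peak around 5-6 s, undershoot
    around 15-16 s), normalized to unit peak so amplitudes stay in %
    signal change.
    """
    t = np.arange(0, duration_s, tr_s)
    peak = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - undershoot_ratio * under
    return h / h.max()


def block_regressors(design: BlockDesign) -> np.ndarray:
    """One HRF-convolved boxcar per condition block, (n_blocks, n_trs)."""
    hrf = double_gamma_hrf(design.tr_s)
    cond = design.condition_events
    out = np.zeros((len(cond), design.n_trs))
    block_trs = None
    for i, (_, ev) in enumerate(cond.iterrows()):
        t0 = design.onset_tr(ev["onset"])
        block_trs = int(round(ev["duration"] / design.tr_s))
        box = np.zeros(design.n_trs)
        box[t0:min(t0 + block_trs, design.n_trs)] = 1.0
        out[i] = np.convolve(box, hrf)[: design.n_trs]
    return out


@dataclass
class GroundTruth:
    """Sidecar ground truth from one simulated run/session."""

    depth: np.ndarray                 # per gray voxel
    layer_of_voxel: np.ndarray        # depth-tercile layer index per gray voxel
    vein_mask: np.ndarray             # per gray voxel, bool
    patterns: dict                    # (orientation, location) -> voxel pattern
    latents: list                     # per run: dict layer -> per-block gain series
    location_gain: np.ndarray         # per gray voxel x 2 locations


def _depth_tercile(depth: np.ndarray) -> np.ndarray:
    """Ground-truth layer index from true depth (terciles of [0, 1])."""
    lay = np.minimum((depth * 3).astype(int), 2)
    return lay


def _latent_gains(rng, n_blocks: int, sd: float) -> dict:
    return {lay: np.maximum(0.0, 1.0 + sd * rng.standard_normal(n_blocks)) for lay in LAYERS}


def _simulate_run(volume, design, effect, vascular, noise_sd, rng, session,
                  latents, patterns, loc_gain):
    """Core forward model for one run; latents/patterns/loc_gain fixed."""
    depth = volume.depth[volume.gm_mask]
    cols = volume.column_id[volume.gm_mask]
    veins = volume.vein_mask[volume.gm_mask]
    lay_idx = _depth_tercile(depth)
    n_vox = volume.n_gray
    n_trs = design.n_trs

    regs = block_regressors(design)            # (n_blocks, n_trs)
    cond = design.condition_events
    amps = effect.amplitudes()
    gain = float(effect.session_gain.get(session, 1.0))

    loc_code = {loc: i for i, loc in enumerate(LOCATIONS)}

    clean = np.zeros((n_vox, n_trs))
    for b, (_, ev) in enumerate(cond.iterrows()):
        ori, loc = ev["orientation"], ev["location"]
        g_act = loc_gain[:, loc_code.get(loc, 0)]
        amp_vec = effect.activation_amplitude * g_act
        pat = patterns[(ori, loc)]
        for li, lay in enumerate(LAYERS):
            a = amps[lay]
            if a == 0:
                continue
            if lay == effect.target_layer and ori == effect.gain_orientation:
                a = a * gain
            sel = lay_idx == li
            amp_vec = amp_vec.copy()
            amp_vec[sel] = amp_vec[sel] + a * latents[lay][b] * pat[sel]
        clean += amp_vec[:, None] * regs[b][None, :]

    # superficial amplitude bias
    bias = 1.0 + (vascular.superficial_gain - 1.0) * depth
    clean = clean * bias[:, None]

    # ascending-vein drainage: superficial voxels inherit a fraction of the
    # mean clean signal of middle/deeper voxels in the same column
    if vascular.drainage_lambda > 0:
        sup = lay_idx == 2
        donors = ~sup
        n_cols = volume.n_columns
        donor_sum = np.zeros((n_cols, n_trs))
        donor_cnt = np.zeros(n_cols)
        np.add.at(donor_sum, cols[donors], clean[donors])
        np.add.at(donor_cnt, cols[donors], 1)
        ok = donor_cnt > 0
        donor_mean = np.zeros_like(donor_sum)
        donor_mean[ok] = donor_sum[ok] / donor_cnt[ok, None]
        has_donor = ok[cols] & sup
        clean[has_donor] += vascular.drainage_lambda * donor_mean[cols[has_donor]]

    # baseline and noise
    baseline = np.full(n_vox, 100.0)
    baseline[veins] *= vascular.vein_mean_factor
    sd = np.full(n_vox, noise_sd)
    sd[veins] *= np.sqrt(vascular.vein_var_factor)

    phi = 0.3
    eps = rng.standard_normal((n_vox, n_trs))
    noise = np.empty_like(eps)
    noise[:, 0] = eps[:, 0]
    for t in range(1, n_trs):
        noise[:, t] = phi * noise[:, t - 1] + np.sqrt(1 - phi**2) * eps[:, t]
    noise *= sd[:, None]

    data = baseline[:, None] + clean + noise
    return data


def _condition_patterns(rng, n_vox, orientations, locations):
    return {(o, l): rng.standard_normal(n_vox) for o in orientations for l in locations}


def _location_gain(rng, n_vox, lateralized):
    if not lateralized:
        return np.ones((n_vox, 2))
    pref = rng.integers(0, 2, n_vox)
    g = np.full((n_vox, 2), 0.5)
    g[np.arange(n_vox), pref] = 1.5
    return g


def simulate_bold(volume: LaminarVolume, designs: Sequence[BlockDesign],
                  effect: EffectSpec, vascular: VascularSpec,
                  noise_sd: float = 1.0, seed: int = 0, session: str = "pre",
                  latents: list | None = None) -> tuple[list[BoldRun], GroundTruth]:
    """Simulate one session's runs for one region.

    Voxel-stable structure (condition patterns, location gains, vein mask)
    is derived from ``effect.pattern_seed`` so it is identical across
    sessions and runs; the per-run noise and latent fluctuation draws come
    from ``seed``. Pass precomputed ``latents`` (one dict per run mapping
    layer -> per-block gain) to share or couple fluctuations across
    regions.
    """
    effect.validate()
    vascular.validate()
    struct_rng = np.random.default_rng(effect.pattern_seed)
    patterns = _condition_patterns(struct_rng, volume.n_gray,
                                   ORIENTATIONS, LOCATIONS)
    loc_gain = _location_gain(struct_rng, volume.n_gray, effect.lateralized)
    if volume.vein_mask is None:
        assign_veins(volume, vascular.vein_fraction,
                     seed=effect.pattern_seed + 7919)

    rng = np.random.default_rng(seed)
    runs = []
    used_latents = []
    for r, design in enumerate(designs):
        n_blocks = design.n_condition_blocks
        lat = latents[r] if latents is not None else _latent_gains(
            rng, n_blocks, effect.coupled_fluctuation_sd)
        used_latents.append(lat)
        data = _simulate_run(volume, design, effect, vascular, noise_sd,
                             rng, session, lat, patterns, loc_gain)
        runs.append(BoldRun(data=data, tr_s=design.tr_s, run_id=r,
                            session=session, design=design))

    depth = volume.depth[volume.gm_mask]
    gt = GroundTruth(
        depth=depth,
        layer_of_voxel=_depth_tercile(depth),
        vein_mask=volume.vein_mask[volume.gm_mask],
        patterns=patterns,
        latents=used_latents,
        location_gain=loc_gain,
    )
    return runs, gt


def coupled_latents(designs: Sequence[BlockDesign], effect_a: EffectSpec,
                    effect_b: EffectSpec, coupling_rho: float, seed: int,
                    coupled_orientation: str = "trained") -> tuple[list, list]:
    """Draw block-wise fluctuation gains for two regions.

    The series of ``effect_a.target_layer`` in region A and of
    ``effect_b.target_layer`` in region B are drawn from a bivariate
    standard normal with correlation ``coupling_rho`` on blocks whose
    orientation matches ``coupled_orientation`` (independent on other
    blocks); all other layer series are independent.
    """
    if abs(coupling_rho) > 1:
        raise ValueError("|coupling_rho| must be <= 1")
    rng = np.random.default_rng(seed)
    lat_a, lat_b = [], []
    for design in designs:
        cond = design.condition_events
        n_blocks = len(cond)
        za = {lay: rng.standard_normal(n_blocks) for lay in LAYERS}
        zb = {lay: rng.standard_normal(n_blocks) for lay in LAYERS}
        coupled = (cond["orientation"] == coupled_orientation).to_numpy()
        la, lb = effect_a.target_layer, effect_b.target_layer
        # correlate on coupled blocks: zb = rho*za + sqrt(1-rho^2)*zb
        zb[lb] = np.where(
            coupled,
            coupling_rho * za[la] + np.sqrt(1 - coupling_rho**2) * zb[lb],
            zb[lb],
        )
        sa, sb = effect_a.coupled_fluctuation_sd, effect_b.coupled_fluctuation_sd
        lat_a.append({lay: np.maximum(0.0, 1.0 + sa * za[lay]) for lay in LAYERS})
        lat_b.append({lay: np.maximum(0.0, 1.0 + sb * zb[lay]) for lay in LAYERS})
    return lat_a, lat_b


def simulate_two_regions(volume_a: LaminarVolume, volume_b: LaminarVolume,
                         designs: Sequence[BlockDesign],
                         effect_a: EffectSpec, effect_b: EffectSpec,
                         vascular: VascularSpec, coupling_rho: float,
                         noise_sd: float = 1.0, seed: int = 0,
                         session: str = "pre",
                         coupled_orientation: str = "trained"):
    """Simulate a sensory and a decision region driven by the same design.

    The block-wise discriminability fluctuations of
    ``effect_a.target_layer`` and ``effect_b.target_layer`` are correlated
    at ``coupling_rho`` on the coupled condition's blocks; every other
    layer pair is uncoupled. Returns ``(runs_a, gt_a), (runs_b, gt_b)``.
    """
    lat_a, lat_b = coupled_latents(designs, effect_a, effect_b, coupling_rho,
                                   seed=seed, coupled_orientation=coupled_orientation)
    ss = np.random.SeedSequence(seed)
    s_a, s_b = (int(s % (2**31)) for s in ss.generate_state(2))
    out_a = simulate_bold(volume_a, designs, effect_a, vascular,
                          noise_sd=noise_sd, seed=s_a, session=session,
                          latents=lat_a)
    out_b = simulate_bold(volume_b, designs, effect_b, vascular,
                          noise_sd=noise_sd, seed=s_b, session=session,
                          latents=lat_b)
    return out_a, out_b
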