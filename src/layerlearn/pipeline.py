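"""End-to-end orchestration: simulate -> layers -> clean -> extract ->
decode -> connect -> staircase -> report.

The pipeline runs a cohort of simulated subjects through the full laminar
analysis with explicit seeds at every stochastic stage, and writes tidy
CSV tables plus a provenance manifest. Rerunning with the same config
reproduces every table bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as ic
from . import geometry, mvpa, responses, staircase, stats, vascular
from .containers import LAYERS, LaminarVolume
from .synth import (
    DesignSpec,
    EffectSpec,
    Observer,
    ObserverSpec,
    PatchSpec,
    VascularSpec,
    generate_patch,
    generate_session_designs,
    simulate_bold,
    simulate_two_regions,
)

logger = logging.getLogger(__name__)

SESSIONS = ("pre", "post")
TASKS = (("trained", "control"), ("untrained", "control"))


@dataclass
class AnalysisConfig:
    """Analysis-stage parameters (voxel counts per region pool, exclusion
    percentiles, peak window, permutations)."""

    n_voxels_visual: int = 500
    n_voxels_ips: int = 200
    n_voxels_connectivity: int = 200
    tsnr_percentile: float = 10.0
    t_percentile: float = 90.0
    window: tuple = responses.PEAK_WINDOW
    n_perm: int = 1000
    spatial_regression: bool = False
    svm_c: float = 1.0
    trained_location: str = "left"


@dataclass
class StaircaseConfig:
    start_level_deg: float = 5.0
    stop_reversals: int = 15
    step_factor: float = 1.2
    n_runs_per_condition: int = 2


@dataclass
class RunConfig:
    """Top-level reproducible run configuration."""

    seed: int = 0
    n_subjects: int = 12
    output_dir: str = "results"
    patch: PatchSpec = field(default_factory=lambda: PatchSpec(
        grid_shape=(15, 15, 3), voxel_size_mm=(0.8, 0.8, 0.8), thickness_mm=2.4))
    design: DesignSpec = field(default_factory=DesignSpec)
    effect_v1: EffectSpec = field(default_factory=lambda: EffectSpec(
        target_layer="superficial", pattern_amplitude=0.04,
        layer_amplitudes={"deeper": 0.04, "middle": 0.04, "superficial": 0.04},
        session_gain={"pre": 1.0, "post": 4.0}, lateralized=True,
        coupled_fluctuation_sd=0.6))
    effect_ips: EffectSpec = field(default_factory=lambda: EffectSpec(
        target_layer="middle", pattern_amplitude=0.04,
        layer_amplitudes={"deeper": 0.04, "middle": 0.04, "superficial": 0.04},
        session_gain={"pre": 1.0, "post": 4.0}, lateralized=False,
        coupled_fluctuation_sd=0.6))
    vascular: VascularSpec = field(default_factory=VascularSpec)
    noise_sd: float = 3.0
    coupling_rho: dict = field(default_factory=lambda: {"pre": 0.0, "post": 0.8})
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    observer: ObserverSpec = field(default_factory=lambda: ObserverSpec(
        threshold_deg=2.5, slope=3.0, lapse_rate=0.01))
    observer_post_threshold_deg: float = 1.7


_NESTED = {
    "patch": PatchSpec, "design": DesignSpec, "effect_v1": EffectSpec,
    "effect_ips": EffectSpec, "vascular": VascularSpec,
    "analysis": AnalysisConfig, "staircase": StaircaseConfig,
    "observer": ObserverSpec,
}


def _build(cls, payload: dict, path: str):
    names = {f.name for f in fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under '{path}': {sorted(unknown)}")
    kwargs = {}
    for key, val in payload.items():
        if key in _NESTED and isinstance(val, dict):
            kwargs[key] = _build(_NESTED[key], val, f"{path}.{key}")
        elif key == "grid_shape" or key == "voxel_size_mm" or key == "window":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def validate_config(source) -> RunConfig:
    """Load and schema-check a YAML config (path, file object or dict).

    Unknown keys are rejected by name; missing keys take documented
    defaults. The result round-trips losslessly through
    :func:`config_to_yaml`.
    """
    if isinstance(source, dict):
        payload = source
    else:
        text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
        payload = yaml.safe_load(text) or {}
    return _build(RunConfig, payload, "config")


def config_to_yaml(config: RunConfig, path=None) -> str:
    text = yaml.safe_dump(asdict(config), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config_to_yaml(config).encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# per-subject analysis
# --------------------------------------------------------------------------

def prepare_volume(volume: LaminarVolume) -> None:
    """Equi-volume grids + layer assignment, in place."""
    grids = geometry.equivolume_grids(volume.thickness_mm, volume.curvature)
    geometry.assign_layers(volume, grids)


def clean_and_extract(runs, volume: LaminarVolume, contrast_kind: str,
                      cfg: AnalysisConfig, roi: str):
    """Vascular cleanup and per-layer pattern extraction for one session.

    Returns ``(datasets, quality, glm)`` where ``datasets`` maps layer ->
    concatenated :class:`PatternDataset` over runs (voxels restricted to
    the layer's top-t pool after exclusion).
    """
    glm = responses.fit_block_glm(runs, contrast_kind=contrast_kind)
    tsnr = vascular.mean_tsnr(runs)
    quality = vascular.exclude_vascular(
        tsnr, glm.t_stat, tsnr_percentile=cfg.tsnr_percentile,
        t_percentile=cfg.t_percentile, roi_name=roi)
    zruns = [vascular.zscore_timecourse(r) for r in runs]
    if cfg.spatial_regression:
        zruns = [vascular.spatial_regression(r, volume, kept=quality.kept)
                 for r in zruns]

    n_sel = cfg.n_voxels_visual if contrast_kind == "left_vs_right" else cfg.n_voxels_ips
    datasets = {}
    for layer in LAYERS:
        pool = np.flatnonzero(geometry.layer_mask(volume, layer) & quality.kept)
        if pool.size == 0:
            raise ValueError(f"no voxels left in {roi}/{layer}")
        top = mvpa.select_voxels(glm.t_stat[pool], min(n_sel, pool.size))
        vox = pool[top]
        per_run = [responses.extract_block_patterns(r, window=cfg.window,
                                                    roi=roi, layer=layer,
                                                    voxel_indices=vox)
                   for r in zruns]
        datasets[layer] = responses.concat_patterns(per_run)
    return datasets, quality, glm


def decode_session(datasets: dict, cfg: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    """Leave-one-run-out decoding for both tasks in every layer.

    Patterns are restricted to the trained location (the primary
    learning question compares orientations at the trained location). Returns a
    tidy accuracy table and the fitted :class:`DecodingResult` objects
    keyed by (layer, task) for downstream connectivity.
    """
    rows, results = [], {}
    for layer, ds in datasets.items():
        loc_ds = ds.subset_blocks(ds.location == cfg.trained_location)
        for task in TASKS:
            res = mvpa.loro_cv(loc_ds, *task, C=cfg.svm_c)
            results[(layer, task)] = (res, loc_ds)
            rows.append(dict(session=ds.session, roi=ds.roi, layer=layer,
                             task=task[0], accuracy=res.mean_accuracy))
    return pd.DataFrame(rows), results


def subject_decoding(volume, designs, effect, vasc, noise_sd, cfg, seed,
                     roi="V1"):
    """Simulate and decode one subject's two sessions for one region.

    Returns ``(accuracy_table, mpi_table)``; MPI is the decoding
    improvement index per (layer, task).
    """
    contrast = "left_vs_right" if effect.lateralized else "all_vs_fixation"
    acc = []
    for s_i, session in enumerate(SESSIONS):
        runs, _ = simulate_bold(volume, designs, effect, vasc,
                                noise_sd=noise_sd, seed=seed + 1000 * s_i,
                                session=session)
        datasets, _, _ = clean_and_extract(runs, volume, contrast, cfg, roi)
        table, _ = decode_session(datasets, cfg)
        acc.append(table)
    acc = pd.concat(acc, ignore_index=True)
    piv = acc.pivot_table(index=["roi", "layer", "task"], columns="session",
                          values="accuracy").reset_index()
    piv["mpi"] = [mvpa.decoding_mpi(pre, post)
                  for pre, post in zip(piv["pre"], piv["post"])]
    return acc, piv


def connectivity_tables(results_a: dict, results_b: dict) -> pd.DataFrame:
    """Pathway connectivity rows from two regions' decoding results."""
    rows = []
    for task in TASKS:
        series_a = {}
        series_b = {}
        for layer in LAYERS:
            res, ds = results_a[(layer, task)]
            series_a[layer] = ic.hyperplane_distances(res, ds)
            res, ds = results_b[(layer, task)]
            series_b[layer] = ic.hyperplane_distances(res, ds)
        tab = ic.pathway_connectivity(series_a, series_b)
        tab["condition"] = task[0]
        tab["session"] = series_a["superficial"].session
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def subject_connectivity(volume_a, volume_b, designs, effect_a, effect_b,
                         vasc, noise_sd, coupling_rho: dict, cfg, seed):
    """Two-region simulation and layer-to-layer informational connectivity
    for both sessions; returns (connectivity table, delta-z contrast)."""
    cfg_conn = AnalysisConfig(**{**asdict(cfg),
                                 "n_voxels_visual": cfg.n_voxels_connectivity,
                                 "n_voxels_ips": cfg.n_voxels_connectivity})
    cfg_conn.window = tuple(cfg.window)
    tables = []
    for s_i, session in enumerate(SESSIONS):
        (runs_a, _), (runs_b, _) = simulate_two_regions(
            volume_a, volume_b, designs, effect_a, effect_b, vasc,
            coupling_rho=float(coupling_rho.get(session, 0.0)),
            noise_sd=noise_sd, seed=seed + 1000 * s_i, session=session,
            coupled_orientation="trained")
        ca = "left_vs_right" if effect_a.lateralized else "all_vs_fixation"
        cb = "left_vs_right" if effect_b.lateralized else "all_vs_fixation"
        ds_a, _, _ = clean_and_extract(runs_a, volume_a, ca, cfg_conn, "V1")
        ds_b, _, _ = clean_and_extract(runs_b, volume_b, cb, cfg_conn, "IPS")
        _, res_a = decode_session(ds_a, cfg_conn)
        _, res_b = decode_session(ds_b, cfg_conn)
        tables.append(connectivity_tables(res_a, res_b))
    table = pd.concat(tables, ignore_index=True)
    return table, ic.pathway_contrast(table)


def subject_behavior(config: RunConfig, seed: int) -> pd.DataFrame:
    """Simulated pre/post staircase thresholds and behavioral MPI.

    The post-training observer has a lower true threshold for the trained
    condition only; each condition runs the configured number of
    staircases and thresholds are averaged across runs before the MPI.
    """
    sc = config.staircase
    conditions = {"trained": (config.observer.threshold_deg,
                              config.observer_post_threshold_deg),
                  "untrained": (config.observer.threshold_deg,
                                config.observer.threshold_deg)}
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(conditions) * 2 * sc.n_runs_per_condition))
    pre_t, post_t = {}, {}
    for cond, (thr_pre, thr_post) in conditions.items():
        for store, thr in ((pre_t, thr_pre), (post_t, thr_post)):
            runs = []
            for _ in range(sc.n_runs_per_condition):
                obs = Observer(ObserverSpec(
                    psychometric_family=config.observer.psychometric_family,
                    threshold_deg=thr, slope=config.observer.slope,
                    lapse_rate=config.observer.lapse_rate,
                    seed=int(next(seeds) % (2**31))))
                trace = staircase.run_staircase(
                    obs, start_level_deg=sc.start_level_deg,
                    stop_reversals=sc.stop_reversals,
                    step_factor=sc.step_factor)
                runs.append(trace.threshold_deg)
            store[cond] = runs
    return staircase.behavioral_mpi(pre_t, post_t)


# --------------------------------------------------------------------------
# cohort run
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, progress: bool = False) -> dict:
    """Execute the full pipeline for a simulated cohort.

    Writes decoding, MPI, connectivity, behavioral and ANOVA tables plus
    a provenance manifest under ``config.output_dir`` and returns them.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    subject_seeds = [int(s % (2**31)) for s in ss.generate_state(config.n_subjects)]

    volume_v1 = generate_patch(config.patch, seed=config.seed)
    volume_ips = generate_patch(config.patch, seed=config.seed + 1)
    prepare_volume(volume_v1)
    prepare_volume(volume_ips)

    acc_rows, mpi_rows, conn_rows, dz_rows, beh_rows = [], [], [], [], []
    for i, s_seed in enumerate(subject_seeds):
        if progress:
            logger.info("subject %d/%d", i + 1, config.n_subjects)
        eff_v1 = EffectSpec(**{**asdict(config.effect_v1),
                               "pattern_seed": config.effect_v1.pattern_seed + 13 * i})
        eff_ips = EffectSpec(**{**asdict(config.effect_ips),
                                "pattern_seed": config.effect_ips.pattern_seed + 13 * i + 7})
        designs = generate_session_designs(config.design, seed=s_seed)
        acc, mpi = subject_decoding(volume_v1, designs, eff_v1, config.vascular,
                                    config.noise_sd, config.analysis, s_seed)
        acc["subject"], mpi["subject"] = i, i
        acc_rows.append(acc)
        mpi_rows.append(mpi)
        conn, dz = subject_connectivity(volume_v1, volume_ips, designs,
                                        eff_v1, eff_ips, config.vascular,
                                        config.noise_sd, config.coupling_rho,
                                        config.analysis, s_seed + 5)
        conn["subject"], dz["subject"] = i, i
        conn_rows.append(conn)
        dz_rows.append(dz)
        beh = subject_behavior(config, s_seed + 11)
        beh["subject"] = i
        beh_rows.append(beh)

    tables = {
        "decoding": pd.concat(acc_rows, ignore_index=True),
        "decoding_mpi": pd.concat(mpi_rows, ignore_index=True),
        "connectivity": pd.concat(conn_rows, ignore_index=True),
        "connectivity_contrast": pd.concat(dz_rows, ignore_index=True),
        "behavior": pd.concat(beh_rows, ignore_index=True),
    }

    # cohort-level inference
    anova_in = tables["decoding"].rename(columns={"task": "orientation"})
    tables["anova_decoding"] = stats.rm_anova(
        anova_in, dv="accuracy", within=["orientation", "session", "layer"],
        subject="subject")
    conn_in = tables["connectivity"]
    tables["anova_connectivity"] = stats.rm_anova(
        conn_in.rename(columns={"condition": "orientation"}),
        dv="z", within=["pathway", "orientation", "session"], subject="subject")

    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "tables": sorted(tables),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    tables["manifest"] = manifest
    return tables
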