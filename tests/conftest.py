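"""Shared fixtures: small prepared cortical patches and block designs.

Everything is generated programmatically at collection time; no data
files. Module/session scoping keeps the suite fast — fixtures are
treated as read-only by tests.
"""

import numpy as np
import pytest

from layerlearn import pipeline
from layerlearn.synth import (
    DesignSpec,
    EffectSpec,
    PatchSpec,
    VascularSpec,
    generate_patch,
    generate_session_designs,
)


@pytest.fixture()
def flat_volume():
    """15x15-column flat patch, one voxel per layer per column, with
    equi-volume layer labels assigned. Function-scoped: simulation may
    attach a vein mask to the volume."""
    vol = generate_patch(PatchSpec(grid_shape=(15, 15, 3), thickness_mm=2.4), seed=0)
    pipeline.prepare_volume(vol)
    return vol


@pytest.fixture(scope="session")
def design_spec():
    return DesignSpec()


@pytest.fixture(scope="session")
def short_designs():
    """Three short runs (2 repeats each) for fast end-to-end paths."""
    return generate_session_designs(
        DesignSpec(repeats_per_run=2, n_runs=3), seed=42)


@pytest.fixture(scope="session")
def session_designs(design_spec):
    """Full-size session: 8 runs x 24 condition blocks."""
    return generate_session_designs(design_spec, seed=7)


@pytest.fixture()
def default_effect():
    return EffectSpec(
        target_layer="superficial", pattern_amplitude=0.04,
        layer_amplitudes={"deeper": 0.04, "middle": 0.04, "superficial": 0.04},
        session_gain={"pre": 1.0, "post": 4.0}, coupled_fluctuation_sd=0.6)


@pytest.fixture()
def default_vascular():
    return VascularSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def long_means(vals):
    """(subjects x 2 x 2) array -> long-format ANOVA table."""
    import pandas as pd

    rows = []
    for s in range(vals.shape[0]):
        for a in range(2):
            for b in range(2):
                rows.append((s, f"a{a}", f"b{b}", vals[s, a, b]))
    return pd.DataFrame(rows, columns=["subject", "A", "B", "y"])


def make_dataset(n_runs=4, per_class=4, n_vox=30, amp=0.0, seed=0,
                 classes=("trained", "control")):
    """Random two-class PatternDataset; ``amp`` scales a fixed class
    pattern (0 -> pure null). Shared by MVPA and connectivity tests."""
    from layerlearn.containers import PatternDataset

    gen = np.random.default_rng(seed)
    pats = {c: gen.standard_normal(n_vox) for c in classes}
    X, y, runs, blocks = [], [], [], []
    b = 0
    for r in range(n_runs):
        for c in classes:
            for _ in range(per_class):
                X.append(amp * pats[c] + gen.standard_normal(n_vox))
                y.append(c)
                runs.append(r)
                blocks.append(b)
                b += 1
    return PatternDataset(X=np.array(X), orientation=np.array(y),
                          location=np.array(["left"] * len(y)),
                          runs=np.array(runs), blocks=np.array(blocks))
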