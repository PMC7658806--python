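"""Hyperplane distances, within-ROI residualization, partial Spearman,
and pathway contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from layerlearn.connectivity import (
    DistanceSeries,
    hyperplane_distances,
    layer_pair_connectivity,
    partial_spearman,
    pathway_contrast,
    residualize,
    residualize_within_roi,
)
from layerlearn.mvpa import TrainedClassifier, loro_cv
from conftest import make_dataset


class TestHyperplaneDistances:
    def test_hand_geometry(self):
        clf = TrainedClassifier(weights=np.array([3.0, 4.0]), bias=0.0,
                                classes=("trained", "control"), fold=0)
        x = np.array([[3.0, 4.0]])
        assert clf.decision(x)[0] / np.linalg.norm(clf.weights) == pytest.approx(5.0)

    def test_pattern_on_hyperplane_zero(self):
        clf = TrainedClassifier(weights=np.array([1.0, -1.0]), bias=0.0,
                                classes=("trained", "control"), fold=0)
        assert clf.decision(np.array([[2.0, 2.0]]))[0] == 0.0

    def test_matches_brute_force_recomputation(self):
        ds = make_dataset(n_runs=2, per_class=3, n_vox=8, amp=1.0, seed=2)
        res = loro_cv(ds, "trained", "control")
        series = hyperplane_distances(res, ds)
        # independent dot-product oracle from the stored weights
        for clf in res.classifiers:
            test = ds.runs == clf.fold
            for x, y_true, run, blk in zip(ds.X[test], ds.orientation[test],
                                           ds.runs[test], ds.blocks[test]):
                d = (clf.weights @ x + clf.bias) / np.sqrt(clf.weights @ clf.weights)
                if y_true != "trained":
                    d = -d
                i = np.flatnonzero((series.runs == run) & (series.blocks == blk))[0]
                assert series.values[i] == pytest.approx(d)

    def test_ordering_identical_across_layers(self):
        ds = make_dataset(n_runs=3, per_class=3, seed=3, amp=0.5)
        res = loro_cv(ds, "trained", "control")
        s1 = hyperplane_distances(res, ds)
        s2 = hyperplane_distances(res, ds)
        assert np.array_equal(s1.runs, s2.runs)
        assert np.array_equal(s1.blocks, s2.blocks)

    def test_zero_weight_vector_rejected(self):
        ds = make_dataset(n_runs=2, seed=1)
        res = loro_cv(ds, "trained", "control")
        res.classifiers[0].weights = np.zeros_like(res.classifiers[0].weights)
        with pytest.raises(ValueError, match="zero weight"):
            hyperplane_distances(res, ds)


class TestResidualize:
    def test_target_equals_regressor_residual_zero(self, rng):
        x = rng.standard_normal(30)
        assert np.allclose(residualize(x, x[:, None]), 0.0, atol=1e-10)

    def test_orthogonal_target_centered(self):
        t = np.arange(24)
        ctrl = np.sin(2 * np.pi * t / 12)
        y = np.cos(2 * np.pi * t / 12) + 5.0
        res = residualize(y, ctrl[:, None])
        assert np.allclose(res, y - y.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        # 3-layer toy series, length 12: hand-computed OLS via the normal
        # equations beta = (X'X)^-1 X'y
        y = rng.standard_normal(12)
        Z = rng.standard_normal((12, 2))
        X = np.column_stack([np.ones(12), Z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(residualize(y, Z), y - X @ beta, atol=1e-10)

    def test_within_roi_alignment_enforced(self):
        a = DistanceSeries(values=np.arange(6.0), runs=np.zeros(6, int),
                           blocks=np.arange(6))
        b = DistanceSeries(values=np.arange(6.0), runs=np.zeros(6, int),
                           blocks=np.arange(1, 7))
        with pytest.raises(ValueError, match="aligned"):
            residualize_within_roi(a, [b])


class TestPartialSpearman:
    def test_identical_series_rho_one_z_capped(self):
        a = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        rho, z = partial_spearman(a, a)
        assert rho == pytest.approx(1.0)
        assert np.isfinite(z)

    def test_no_controls_equals_ordinary_spearman(self, rng):
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        rho, _ = partial_spearman(a, b)
        assert rho == pytest.approx(spearmanr(a, b).statistic, abs=1e-12)

    def test_null_mean_within_three_se(self):
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(500):
            a, b = rng.standard_normal(100), rng.standard_normal(100)
            c = rng.standard_normal((100, 2))
            rhos.append(partial_spearman(a, b, c, c)[0])
        se = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * se

    def test_small_case_matches_recursion_oracle(self):
        # shared single control: the first-order partial-correlation
        # recursion on Spearman rhos is an independent closed form
        a = np.array([2.0, 4.0, 1.0, 3.0, 6.0, 5.0])
        b = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        c = np.array([6.0, 1.0, 5.0, 2.0, 4.0, 3.0])
        r_ab = spearmanr(a, b).statistic
        r_ac = spearmanr(a, c).statistic
        r_bc = spearmanr(b, c).statistic
        expected = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        rho, _ = partial_spearman(a, b, c[:, None], c[:, None])
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(6), np.arange(6.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            partial_spearman(np.arange(4.0), np.arange(4.0))

    def test_invariant_to_joint_block_permutation(self, rng):
        a, b = rng.standard_normal(40), rng.standard_normal(40)
        ca, cb = rng.standard_normal((40, 2)), rng.standard_normal((40, 2))
        rho1, _ = partial_spearman(a, b, ca, cb)
        perm = rng.permutation(40)
        rho2, _ = partial_spearman(a[perm], b[perm], ca[perm], cb[perm])
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestLayerPairRecovery:
    def _series(self, rng, latent, loading, n):
        return latent * loading + rng.standard_normal(n)

    def test_coupled_pair_has_largest_partial_z(self):
        # 200-block toy generative model: layer series = loading x latent
        # + noise; only (sup_a, mid_b) latents are correlated
        n, successes = 200, 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            z_shared = rng.standard_normal(n)
            lat_a = {"superficial": 0.9 * z_shared + 0.44 * rng.standard_normal(n),
                     "middle": rng.standard_normal(n),
                     "deeper": rng.standard_normal(n)}
            lat_b = {"middle": 0.9 * z_shared + 0.44 * rng.standard_normal(n),
                     "superficial": rng.standard_normal(n),
                     "deeper": rng.standard_normal(n)}
            mk = lambda lat: {k: DistanceSeries(
                values=self._series(rng, v, 1.0, n),
                runs=np.zeros(n, int), blocks=np.arange(n))
                for k, v in lat.items()}
            sa, sb = mk(lat_a), mk(lat_b)
            zs = {(la, lb): layer_pair_connectivity(sa, sb, la, lb)[1]
                  for la in lat_a for lb in lat_b}
            if max(zs, key=zs.get) == ("superficial", "middle"):
                successes += 1
        assert successes >= 18

    def test_partial_equals_plain_when_controls_uninformative(self, rng):
        n = 300
        latent = rng.standard_normal(n)
        a = latent + 0.5 * rng.standard_normal(n)
        b = latent + 0.5 * rng.standard_normal(n)
        ctrl_a = rng.standard_normal((n, 2))
        ctrl_b = rng.standard_normal((n, 2))
        rho_partial, _ = partial_spearman(a, b, ctrl_a, ctrl_b)
        rho_plain = spearmanr(a, b).statistic
        assert rho_partial == pytest.approx(rho_plain, abs=0.05)


class TestPathwayContrast:
    def _table(self, z):
        rows = []
        for pathway in ("feedforward", "feedback"):
            for cond in ("trained", "untrained"):
                for session in ("pre", "post"):
                    rows.append(dict(pathway=pathway, condition=cond,
                                     session=session,
                                     z=z[(pathway, cond, session)]))
        return pd.DataFrame(rows)

    def test_identical_sessions_zero_delta(self):
        z = {(p, c, s): 0.4 for p in ("feedforward", "feedback")
             for c in ("trained", "untrained") for s in ("pre", "post")}
        out = pathway_contrast(self._table(z))
        assert np.allclose(out["delta_z"], 0.0)

    def test_swapping_sessions_flips_sign(self):
        rng = np.random.default_rng(1)
        z = {(p, c, s): rng.standard_normal()
             for p in ("feedforward", "feedback")
             for c in ("trained", "untrained") for s in ("pre", "post")}
        out1 = pathway_contrast(self._table(z))
        swapped = {(p, c, {"pre": "post", "post": "pre"}[s]): v
                   for (p, c, s), v in z.items()}
        out2 = pathway_contrast(self._table(swapped))
        merged = out1.merge(out2, on=["pathway", "condition"])
        assert np.allclose(merged["delta_z_x"], -merged["delta_z_y"])

    def test_missing_cell_raises_listing_combination(self):
        z = {(p, c, s): 0.1 for p in ("feedforward", "feedback")
             for c in ("trained", "untrained") for s in ("pre", "post")}
        table = self._table(z)
        table = table[~((table.pathway == "feedback")
                        & (table.condition == "trained")
                        & (table.session == "post"))]
        with pytest.raises(ValueError, match="missing"):
            pathway_contrast(table)
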