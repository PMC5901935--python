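from collections import deque

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from voxelfc.inference import (build_design, cluster_fwe_permutation,
                               connectivity_strength_r2, fdr_bh,
                               fit_voxelwise_glm, form_clusters,
                               voxelwise_regression)


# ---------------------------------------------------------------- oracles

def bh_oracle(p, alpha=0.05):
    """Direct Benjamini-Hochberg step-up enumeration."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def flood_fill_oracle(mask):
    """BFS 26-connected components; returns list of frozensets of coords."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[a] < mask.shape[a] for a in range(3)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(frozenset(comp))
    return comps


def random_design(rng, n):
    return pd.DataFrame({
        "intercept": np.ones(n),
        "group": np.repeat([1.0, 0.0], n // 2),
        "age": rng.normal(35, 5, n),
        "gender": np.tile([0.0, 1.0], n // 2),
        "bdi": rng.normal(7, 4, n),
    })


# ---------------------------------------------------------------- GLM

class TestGlm:
    def test_matches_statsmodels_per_voxel(self):
        rng = np.random.default_rng(5)
        n, n_vox = 12, 5
        X = random_design(rng, n)
        maps = rng.standard_normal((n, n_vox))
        stat = fit_voxelwise_glm(maps, X, "group")
        for v in range(n_vox):
            fit = sm.OLS(maps[:, v], X.to_numpy()).fit()
            assert stat.t[v] == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert stat.p[v] == pytest.approx(fit.pvalues[1], abs=1e-10)
            assert stat.beta[v] == pytest.approx(fit.params[1], abs=1e-10)
        assert stat.df == n - X.shape[1]

    def test_collinear_design_named(self):
        rng = np.random.default_rng(6)
        X = random_design(rng, 10)
        X["dup"] = X["group"]
        with pytest.raises(ValueError, match="collinear"):
            fit_voxelwise_glm(rng.standard_normal((10, 3)), X, "group")

    def test_planted_group_shift_detected(self):
        rng = np.random.default_rng(7)
        n, n_vox = 34, 200
        block = np.arange(27)
        X = random_design(rng, n)
        maps = rng.standard_normal((n, n_vox))
        maps[np.ix_(X["group"] == 1.0, block)] += 1.0
        stat = fit_voxelwise_glm(maps, X, "group")
        inside = stat.t[block]
        outside = np.delete(stat.t, block)
        assert inside.mean() > 1.5
        assert np.abs(inside).mean() > np.abs(outside).mean()

    def test_build_design_full_rank_and_coding(self):
        cov = pd.DataFrame({
            "group": ["patient", "control"] * 6,
            "age": np.linspace(20, 45, 12),
            "gender": ["F", "F", "M", "M"] * 3,
            "bdi": [3, 9, 1, 7, 12, 5, 8, 2, 11, 4, 6, 10],
        })
        X = build_design(cov)
        assert list(X.columns) == ["intercept", "group", "age", "gender", "bdi"]
        assert set(X["group"]) == {0.0, 1.0}
        assert set(X["gender"]) == {0.0, 1.0}


class TestVoxelwiseRegression:
    def test_planted_block_confined(self):
        rng = np.random.default_rng(8)
        n, n_vox = 17, 200
        onset = rng.normal(29, 10, n)
        maps = rng.standard_normal((n, n_vox))
        block = np.arange(27)
        maps[:, block] += 0.3 * onset[:, None]
        stat = voxelwise_regression(maps, onset)
        reject, _ = fdr_bh(stat.p, 0.05)
        assert (stat.t[block] > 0).mean() == 1.0
        assert reject[block].sum() >= 20
        assert reject[np.delete(np.arange(n_vox), block)].sum() <= 3

    def test_matches_full_ols_with_covariates(self):
        rng = np.random.default_rng(9)
        n, n_vox = 20, 6
        maps = rng.standard_normal((n, n_vox))
        y = rng.standard_normal(n)
        covar = rng.standard_normal((n, 2))
        stat = voxelwise_regression(maps, y, covariates=covar)
        for v in range(n_vox):
            X = np.column_stack([np.ones(n), maps[:, v], covar])
            fit = sm.OLS(y, X).fit()
            assert stat.t[v] == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert stat.df == n - 4

    def test_null_calibration(self):
        rng = np.random.default_rng(10)
        n, n_vox = 30, 1000
        stat = voxelwise_regression(rng.standard_normal((n, n_vox)),
                                    rng.standard_normal(n))
        frac = (stat.p < 0.05).mean()
        assert abs(frac - 0.05) < 0.03

    def test_df_bookkeeping(self):
        rng = np.random.default_rng(11)
        stat = voxelwise_regression(rng.standard_normal((3, 2)),
                                    np.array([1.0, 2.0, 4.0]))
        assert stat.df == 1

    def test_constant_outcome_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="constant"):
            voxelwise_regression(rng.standard_normal((5, 3)), np.ones(5))


# ---------------------------------------------------------------- FDR

class TestFdrBh:
    def test_worked_example(self):
        reject, q = fdr_bh(np.array([0.001, 0.02, 0.03, 0.9]), alpha=0.05)
        assert reject.sum() == 3
        assert reject[:3].all() and not reject[3]

    def test_all_ones(self):
        reject, _ = fdr_bh(np.ones(10), alpha=0.05)
        assert reject.sum() == 0

    def test_single_p_reduces_to_raw_threshold(self):
        reject, _ = fdr_bh(np.array([0.04]), alpha=0.05)
        assert reject[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=300) ** 2
        reject, q = fdr_bh(p, alpha=0.05)
        assert np.array_equal(reject, bh_oracle(p, 0.05))
        assert (q >= p - 1e-12).all()
        # monotone q in p-order
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            fdr_bh(np.array([0.1, np.nan]))


# ---------------------------------------------------------------- clusters

class TestFormClusters:
    def test_two_separate_blobs(self):
        mask = np.zeros((10, 10, 8), bool)
        mask[1:2, 1:6, 1] = True          # 5 voxels
        mask[7, 7, 5:7] = True            # 2 voxels
        t = np.where(mask, 2.0, 0.0)
        clusters = form_clusters(mask, t, np.eye(4))
        assert sorted(c.k for c in clusters) == [2, 5]
        oracle = {len(c) for c in flood_fill_oracle(mask)}
        assert {c.k for c in clusters} == oracle

    def test_corner_touching_merges(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:3, 1:3, 1:3] = True
        mask[3, 3, 3] = True              # touches only at a corner
        t = np.ones_like(mask, float)
        clusters = form_clusters(mask, t, np.eye(4))
        assert len(clusters) == 1
        assert clusters[0].k == 9

    def test_single_voxel_peak_mm(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 3, 4] = True
        t = np.where(mask, -3.0, 0.0)
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-6, -6, -6]
        (c,) = form_clusters(mask, t, affine)
        assert c.k == 1
        assert c.direction == "decrease"
        assert c.peak_mm == (0.0, 3.0, 6.0)

    def test_sign_split(self):
        mask = np.zeros((8, 4, 4), bool)
        mask[1:7, 1, 1] = True
        t = np.zeros(mask.shape)
        t[1:4, 1, 1] = 2.0
        t[4:7, 1, 1] = -2.0
        clusters = form_clusters(mask, t, np.eye(4))
        assert len(clusters) == 2
        assert {c.direction for c in clusters} == {"increase", "decrease"}
        for c in clusters:
            assert (c.peak_t > 0) == (c.direction == "increase")

    def test_enumeration_order_invariance(self):
        rng = np.random.default_rng(20)
        mask = rng.uniform(size=(9, 9, 7)) < 0.25
        t = np.where(mask, 1.0, 0.0)
        sizes = sorted(c.k for c in form_clusters(mask, t, np.eye(4)))
        for flip in (0, 1, 2):
            flipped = np.flip(mask, axis=flip)
            tf = np.where(flipped, 1.0, 0.0)
            assert sorted(c.k for c in form_clusters(flipped, tf, np.eye(4))) \
                == sizes

    def test_empty_mask_empty_list(self):
        assert form_clusters(np.zeros((4, 4, 4), bool),
                             np.zeros((4, 4, 4)), np.eye(4)) == []


# ------------------------------------------------------- permutation FWE

def planted_maps(rng, n, mask_shape, block, effect):
    n_vox = int(np.prod(mask_shape))
    maps = rng.standard_normal((n, n_vox))
    group = np.repeat([1.0, 0.0], n // 2)
    flat = np.zeros(mask_shape, bool)
    flat[block] = True
    maps[:, flat.ravel()] += effect * group[:, None]
    return maps, group


class TestClusterFwe:
    def test_min_nperm_enforced(self):
        rng = np.random.default_rng(0)
        X = random_design(rng, 12)
        with pytest.raises(ValueError, match="n_perm"):
            cluster_fwe_permutation(rng.standard_normal((12, 8)), X, "group",
                                    n_perm=50, mask=np.ones((2, 2, 2), bool))

    def test_estimator_floor_1_over_nperm_plus_1(self):
        # a planted effect so strong that no null max-k reaches it
        rng = np.random.default_rng(1)
        shape = (8, 8, 6)
        maps, group = planted_maps(rng, 24, shape,
                                   (slice(2, 5), slice(2, 5), slice(2, 5)), 4.0)
        X = pd.DataFrame({"intercept": np.ones(24), "group": group})
        clusters, _ = cluster_fwe_permutation(
            maps, X, "group", n_perm=499, mask=np.ones(shape, bool),
            rng=np.random.default_rng(2))
        best = min(c.p_fwe_cluster for c in clusters)
        assert best == pytest.approx(1.0 / 500.0)

    def test_power_on_planted_effect(self):
        # 27-voxel block at d ~ 1.2, n=34: recovered with p_fwe < 0.05 in
        # >= 80% of replicates
        shape = (8, 8, 5)
        block = (slice(2, 5), slice(2, 5), slice(1, 4))
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            maps, group = planted_maps(rng, 34, shape, block, 1.2)
            X = pd.DataFrame({"intercept": np.ones(34), "group": group})
            clusters, _ = cluster_fwe_permutation(
                maps, X, "group", n_perm=500, mask=np.ones(shape, bool),
                rng=np.random.default_rng(rep))
            flat = np.zeros(shape, bool)
            flat[block] = True
            for c in clusters:
                if c.p_fwe_cluster < 0.05 and c.direction == "increase" \
                        and (c.mask & flat).sum() >= 10:
                    hits += 1
                    break
        assert hits >= int(0.8 * n_rep)

    def test_reported_clusters_pass_fdr(self):
        rng = np.random.default_rng(3)
        shape = (8, 8, 6)
        maps, group = planted_maps(rng, 24, shape,
                                   (slice(1, 4), slice(1, 4), slice(1, 4)), 2.0)
        X = pd.DataFrame({"intercept": np.ones(24), "group": group})
        clusters, stat = cluster_fwe_permutation(
            maps, X, "group", n_perm=100, mask=np.ones(shape, bool),
            rng=np.random.default_rng(4))
        reject, _ = fdr_bh(stat.p, 0.05)
        sig = np.zeros(shape, bool)
        sig.ravel()[reject] = True
        for c in clusters:
            assert sig[tuple(c.member_voxels.T)].all()


# ------------------------------------------------------- strength R^2

class TestStrengthR2:
    def test_exact_linear(self):
        y = np.linspace(20, 45, 10)
        s = -0.02 * y + 0.3
        r2, slope, _ = connectivity_strength_r2(s, y)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(-0.02)

    def test_independent_null(self):
        rng = np.random.default_rng(30)
        r2, _, _ = connectivity_strength_r2(rng.standard_normal(5000),
                                            rng.standard_normal(5000))
        assert r2 <= 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            connectivity_strength_r2(np.ones(5), np.arange(5.0))
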