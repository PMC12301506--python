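"""Correlation maps, Fisher z, clustering, correction, permutation test."""

import numpy as np
import pytest
from scipy import stats

from megdot import couplestats as cs


def _map(p, r=None, shape=(10, 10, 10), voxel_size=2.0, indices=None):
    p = np.asarray(p, dtype=float)
    if indices is None:
        indices = np.arange(p.size)
    return cs.VoxelStatMap(
        r=np.zeros_like(p) if r is None else np.asarray(r, dtype=float),
        p=p, method="method1", voxel_indices=np.asarray(indices),
        grid_shape=shape, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# Pearson and Fisher
# ---------------------------------------------------------------------------

def _pearson_oracle(x, y):
    """From-scratch Pearson formula with p from the t distribution."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / np.sqrt(sxx * syy)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def test_pearson_matches_oracle_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(4, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r, p = cs.pearson_rp(x, y)
        ro, po = _pearson_oracle(x, y)
        assert abs(r - ro) < 1e-12
        assert abs(p - po) < 1e-12
        rs, ps = stats.pearsonr(x, y)      # independent library route
        assert abs(r - rs) < 1e-10
        assert abs(p - ps) < 1e-10


def test_pearson_hand_computed_example():
    r, p = cs.pearson_rp(np.array([1.0, 3.0, 2.0]), np.array([1.0, 2.0, 3.0]))
    assert r == pytest.approx(0.5, abs=1e-12)


def test_pearson_affine_extremes():
    x = np.arange(10.0)
    r1, p1 = cs.pearson_rp(x, 2 * x + 1)
    rm, pm = cs.pearson_rp(x, -x)
    assert r1 == pytest.approx(1.0)
    assert rm == pytest.approx(-1.0)
    assert p1 == 0.0 and pm == 0.0


def test_pearson_zero_variance_is_nan():
    x = np.arange(6.0)
    Y = np.column_stack([np.ones(6), x])
    r, p = cs.pearson_rp(x, Y)
    assert np.isnan(r[0]) and np.isnan(p[0])
    assert r[1] == pytest.approx(1.0)


def test_fisher_transform_values():
    assert cs.fisher_z(0.0) == 0.0
    assert cs.fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)
    r = np.array([0.3, -0.3])
    z = cs.fisher_z(r)
    assert z[1] == pytest.approx(-z[0])
    np.testing.assert_allclose(cs.inverse_fisher_z(z), r, atol=1e-12)


def test_fisher_clips_perfect_correlation():
    with pytest.warns(UserWarning):
        z = cs.fisher_z(np.array([1.0]))
    assert np.isfinite(z).all()


# ---------------------------------------------------------------------------
# Method 2 and frequency correlation
# ---------------------------------------------------------------------------

def test_method2_null_p_values_uniform(rng):
    """Independent Gaussian samples give ~Uniform(0,1) voxel p values.

    The group t test on Fisher-z values is exact only asymptotically in
    the per-subject sample count, so uniformity is asserted as a
    sup-norm bound on the empirical CDF deviation rather than a KS
    p value, which would flag the known tiny non-normality at this
    voxel count.
    """
    n_subj, n_vox = 8, 10_000
    measured = rng.normal(size=(n_subj, 20, n_vox))
    predicted = rng.normal(size=(n_subj, 20))
    sm = cs.correlate_method2(measured, predicted, np.arange(n_vox),
                              (100, 10, 10), 2.0)
    ks = stats.kstest(sm.p, "uniform")
    assert ks.statistic < 0.03
    assert sm.subject_r.shape == (n_subj, n_vox)


def test_method2_r_is_inverse_fisher_of_mean_z(rng):
    measured = rng.normal(size=(5, 20, 10))
    predicted = rng.normal(size=(5, 20))
    sm = cs.correlate_method2(measured, predicted, np.arange(10), (10, 1, 1), 2.0)
    np.testing.assert_allclose(sm.r, np.tanh(sm.subject_z.mean(axis=0)), atol=1e-12)


def test_method2_needs_three_subjects(rng):
    with pytest.raises(ValueError):
        cs.correlate_method2(rng.normal(size=(2, 20, 4)), rng.normal(size=(2, 20)),
                             np.arange(4), (4, 1, 1), 2.0)


def test_frequency_correlation_extremes():
    freqs = np.array([0.5, 1.0, 2.0, 4.0] * 6)
    sm_pos = cs.correlate_frequency(freqs[:, None], freqs, np.arange(1), (1, 1, 1), 2.0)
    sm_neg = cs.correlate_frequency(-freqs[:, None], freqs, np.arange(1), (1, 1, 1), 2.0)
    assert sm_pos.r[0] == pytest.approx(1.0)
    assert sm_neg.r[0] == pytest.approx(-1.0)


def test_frequency_correlation_null_mean_r(rng):
    freqs = np.array([0.5, 1.0, 2.0, 4.0] * 10)
    Y = rng.normal(size=(40, 4000))
    sm = cs.correlate_frequency(Y, freqs, np.arange(4000), (20, 20, 10), 2.0)
    assert abs(np.nanmean(sm.r)) < 0.02


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _bfs_components(mask3d, connectivity=6):
    """Brute-force BFS connected components oracle."""
    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                if (i, j, k) != (0, 0, 0)]
    shape = mask3d.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for idx in np.argwhere(mask3d):
        idx = tuple(idx)
        if seen[idx]:
            continue
        queue, comp = [idx], []
        seen[idx] = True
        while queue:
            cur = queue.pop()
            comp.append(np.ravel_multi_index(cur, shape))
            for o in offs:
                nb = tuple(np.add(cur, o))
                if all(0 <= nb[d] < shape[d] for d in range(3)) \
                        and mask3d[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


@pytest.mark.parametrize("connectivity", [6, 26])
def test_components_match_bfs_oracle(rng, connectivity):
    shape = (10, 10, 10)
    for _ in range(100):
        mask = rng.random(shape) < 0.2
        p = np.where(mask.ravel(), 0.0, 1.0)
        sm = _map(p, shape=shape)
        got = {frozenset(c.tolist())
               for c in cs._components(sm, 0.5, connectivity)}
        assert got == _bfs_components(mask, connectivity)


def test_two_adjacent_voxels_form_one_cluster():
    shape = (5, 5, 5)
    p = np.ones(125)
    a = np.ravel_multi_index((2, 2, 2), shape)
    b = np.ravel_multi_index((2, 2, 3), shape)
    p[[a, b]] = 1e-5
    sm = _map(p, shape=shape, voxel_size=3.0)
    out = cs.form_clusters(sm, lambda vox: (0.9, 1e-4), min_volume=50.0)
    assert len(out) == 1
    assert set(out[0].voxel_indices.tolist()) == {a, b}
    assert out[0].volume_mm3 == pytest.approx(54.0)


def test_minimum_volume_rule_rejects_49_mm3():
    shape = (5, 5, 5)
    p = np.ones(125)
    p[np.ravel_multi_index((2, 2, 2), shape)] = 1e-5
    small = _map(p, shape=shape, voxel_size=49.0 ** (1 / 3))
    assert cs.form_clusters(small, lambda v: (0.9, 1e-4), min_volume=50.0) == []
    big = _map(p, shape=shape, voxel_size=4.0)   # 64 mm^3 voxel survives
    assert len(cs.form_clusters(big, lambda v: (0.9, 1e-4), min_volume=50.0)) == 1


def test_level_with_lowest_cluster_p_reported():
    """Nested L1/L3 components report the level whose statistic is best."""
    shape = (7, 1, 1)
    p = np.ones(7)
    p[2:5] = 5e-3          # L3 component of 3 voxels
    p[3] = 1e-4            # L1 core of 1 voxel
    sm = _map(p, shape=shape, voxel_size=4.0)

    def stat(vox):
        # the larger (L3) extent has the lower recomputed p
        return (0.5, 1e-6 if len(vox) == 3 else 1e-3)

    out = cs.form_clusters(sm, stat, min_volume=50.0)
    assert len(out) == 1
    assert out[0].level == "L3"
    assert out[0].n_voxels == 3

    def stat_rev(vox):
        return (0.5, 1e-6 if len(vox) == 1 else 1e-3)

    out = cs.form_clusters(sm, stat_rev, min_volume=50.0)
    assert out[0].level == "L1"
    assert out[0].n_voxels == 1


def test_no_surviving_cluster_returns_empty():
    sm = _map(np.ones(27), shape=(3, 3, 3))
    assert cs.form_clusters(sm, lambda v: (0, 1)) == []


# ---------------------------------------------------------------------------
# Correction and permutation
# ---------------------------------------------------------------------------

def _cluster(p):
    return cs.ClusterResult(voxel_indices=np.array([0]), volume_mm3=64.0,
                            level="L3", r=0.5, p=p, method="method1")


def test_bonferroni_correction_values():
    out = cs.correct_clusters([_cluster(1e-4), _cluster(0.01)], n_mc=187)
    assert out[0].p_corrected == pytest.approx(0.0187)
    assert out[1].p_corrected == 1.0
    idc = cs.correct_clusters([_cluster(0.03)], n_mc=1)
    assert idc[0].p_corrected == pytest.approx(0.03)
    for c in out:
        assert c.p_corrected >= c.p


def test_correction_flags():
    out = cs.correct_clusters([_cluster(1e-4), _cluster(5e-4), _cluster(0.01)])
    assert out[0].significant is True            # 0.0187
    assert out[1].significant is False           # 0.0935 < 0.2 reportable
    assert out[1].extra["reportable"] is True
    assert out[2].extra["reportable"] is False   # clipped to 1


def test_permutation_p_bounds_and_errors(rng):
    subjects = np.repeat([f"s{i}" for i in range(8)], 4)
    x = rng.normal(size=32)
    groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
    # strong group difference: B's y anti-correlates
    sign = np.array([1.0 if groups[s] == "A" else -1.0 for s in subjects])
    y = sign * x
    p = cs.subgroup_permutation_test(y, x, subjects, groups, n_perm=200, seed=0)
    assert p <= 0.05
    with pytest.raises(ValueError):
        cs.subgroup_permutation_test(y, x, subjects, groups, n_perm=0)
    bad_groups = {f"s{i}": ("A" if i < 1 else "B") for i in range(8)}
    with pytest.raises(ValueError):
        cs.subgroup_permutation_test(y, x, subjects, bad_groups, n_perm=10)


def test_permutation_null_is_calibrated(rng):
    """Label-symmetric data: permutation p values center near 0.5."""
    subjects = np.repeat([f"s{i}" for i in range(8)], 4)
    groups = {f"s{i}": ("A" if i % 2 else "B") for i in range(8)}
    ps = []
    for k in range(30):
        x = rng.normal(size=32)
        y = x + rng.normal(size=32)
        ps.append(cs.subgroup_permutation_test(y, x, subjects, groups,
                                               n_perm=60, seed=k))
    med = np.median(ps)
    assert 0.2 < med < 0.8


def test_permutation_lower_bound(rng):
    subjects = np.repeat([f"s{i}" for i in range(6)], 4)
    groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    x = rng.normal(size=24)
    sign = np.array([1.0 if groups[s] == "A" else -1.0 for s in subjects])
    p = cs.subgroup_permutation_test(sign * x, x, subjects, groups,
                                     n_perm=50, seed=1)
    assert p >= 1.0 / 51.0


def test_calibrate_min_volume_quantile():
    vols = [np.array([float(k)]) for k in range(1, 101)]  # maxima 1..100
    v = cs.calibrate_min_volume(vols, voxel_volume=1.0, target_fpr=0.05)
    assert v == 96.0
    none = cs.calibrate_min_volume([np.array([]) for _ in range(10)],
                                   voxel_volume=8.0)
    assert none == 8.0
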