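"""Voxelwise MEG-DOT coupling statistics and cluster inference.

Three correlation analyses over the gray-matter field of view:

* Method 1 -- across subjects and stimulation frequencies: Pearson
  correlation between the measured HbT AUC vector y (one row per
  subject x frequency) and the MEG-predicted AUC column of one feature.
* Method 2 -- within subject, across the response time course: per
  subject, Pearson correlation between measured and predicted HbT at
  20 samples (five per frequency at 1..9 s, 0.5 Hz); the coefficients
  are Fisher-z transformed and tested for non-zero group mean with a
  one-sample t test.
* Frequency correlation -- Pearson correlation of the HbT AUC with the
  stimulation frequency values.

Adjacent subthreshold voxels (p < 0.001 / 0.003 / 0.01 for levels
L1/L2/L3) are merged into 6-connected clusters with a minimum volume
(default 50 mm^3); the cluster statistic is recomputed on the
voxel-averaged signal, the level giving the lowest cluster p is
reported per spatial component, and cluster p values are Bonferroni
corrected with the number of independently imageable regions
(N_MC = 187).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "LEVELS",
    "N_MC",
    "MIN_CLUSTER_VOLUME",
    "VoxelStatMap",
    "ClusterResult",
    "pearson_rp",
    "fisher_z",
    "inverse_fisher_z",
    "correlate_method1",
    "correlate_method2",
    "correlate_frequency",
    "form_clusters",
    "correct_clusters",
    "subgroup_permutation_test",
    "calibrate_min_volume",
]

#: Voxel-level p thresholds for the three cluster-extent levels.
LEVELS = {"L1": 0.001, "L2": 0.003, "L3": 0.01}

#: Bonferroni divisor: estimated number of independently imageable regions.
N_MC = 187

#: Default minimum cluster volume (mm^3).
MIN_CLUSTER_VOLUME = 50.0

#: Corrected-p thresholds for reporting and significance flags.
REPORT_P = 0.2
SIGNIF_P = 0.05


@dataclass
class VoxelStatMap:
    """Correlation statistics over the field-of-view voxels.

    ``voxel_indices`` are flat indices into the voxel grid of shape
    ``grid_shape``; ``r`` and ``p`` align with them.  Voxels where the
    statistic is undefined (zero variance) carry NaN.
    """

    r: np.ndarray
    p: np.ndarray
    method: str                    # "method1" | "method2" | "frequency"
    voxel_indices: np.ndarray
    grid_shape: tuple
    voxel_size: float              # mm
    feature_id: str | None = None
    subject_r: np.ndarray | None = None   # method 2: (n_subjects, n_vox)
    subject_z: np.ndarray | None = None

    def p_volume(self) -> np.ndarray:
        """Dense p map over the grid (NaN outside the FOV)."""
        vol = np.full(int(np.prod(self.grid_shape)), np.nan)
        vol[self.voxel_indices] = self.p
        return vol.reshape(self.grid_shape)


@dataclass
class ClusterResult:
    """One cluster of covarying voxels and its recomputed statistic."""

    voxel_indices: np.ndarray      # flat grid indices of member voxels
    volume_mm3: float
    level: str                     # "L1" | "L2" | "L3"
    r: float
    p: float
    method: str
    feature_id: str | None = None
    leading_variable: str = "HbT"
    p_corrected: float | None = None
    significant: bool | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(len(self.voxel_indices))


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def pearson_rp(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided p of ``x`` against columns of Y.

    ``x`` is (n,), ``Y`` is (n,) or (n, m).  p values come from the t
    distribution with n - 2 degrees of freedom.  Columns with zero
    variance (in x or Y) return NaN.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(Yc**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ Yc) / (sx * sy)
    bad = (sx == 0) | (sy == 0)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    if squeeze:
        return float(r[0]), float(p[0])
    return r, p


def fisher_z(r: np.ndarray, r_clip: float = 0.999999) -> np.ndarray:
    """Variance-stabilizing Fisher transform z = atanh(r), |r| clipped."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > r_clip):
        import warnings

        warnings.warn("|r| at or near 1 clipped before the Fisher transform")
    return np.arctanh(np.clip(r, -r_clip, r_clip))


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


# ---------------------------------------------------------------------------
# The three correlation analyses
# ---------------------------------------------------------------------------

def correlate_method1(
    Y: np.ndarray,
    x_feature: np.ndarray,
    voxel_indices: np.ndarray,
    grid_shape: tuple,
    voxel_size: float,
    feature_id: str | None = None,
) -> VoxelStatMap:
    """Across-subject correlation of measured HbT AUC with one predictor.

    ``Y`` is (n_rows, n_vox): the measured HbT AUC per (subject,
    frequency) row and FOV voxel; ``x_feature`` is the corresponding
    column of predicted AUCs.
    """
    r, p = pearson_rp(x_feature, Y)
    return VoxelStatMap(r=r, p=p, method="method1", voxel_indices=np.asarray(voxel_indices),
                        grid_shape=tuple(grid_shape), voxel_size=voxel_size,
                        feature_id=feature_id)


def correlate_method2(
    measured: np.ndarray,
    predicted: np.ndarray,
    voxel_indices: np.ndarray,
    grid_shape: tuple,
    voxel_size: float,
    feature_id: str | None = None,
) -> VoxelStatMap:
    """Within-subject time-course correlation, Fisher z, group t test.

    ``measured`` is (n_subjects, 20, n_vox): the measured HbT at the 20
    Method-2 samples; ``predicted`` is (n_subjects, 20).  Per subject
    and voxel a Pearson r is computed, Fisher-transformed, and the
    transformed values are tested across subjects for non-zero mean
    with a two-sided one-sample t test.  The reported voxel r is the
    inverse Fisher transform of the mean z.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n_subj = measured.shape[0]
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    rs = np.empty((n_subj, measured.shape[2]))
    for s in range(n_subj):
        rs[s], _ = pearson_rp(predicted[s], measured[s])
    zs = fisher_z(rs)
    tt = stats.ttest_1samp(zs, 0.0, axis=0, nan_policy="propagate")
    mean_z = zs.mean(axis=0)
    return VoxelStatMap(
        r=inverse_fisher_z(mean_z), p=np.asarray(tt.pvalue), method="method2",
        voxel_indices=np.asarray(voxel_indices), grid_shape=tuple(grid_shape),
        voxel_size=voxel_size, feature_id=feature_id, subject_r=rs, subject_z=zs,
    )


def correlate_frequency(
    Y: np.ndarray,
    frequencies: np.ndarray,
    voxel_indices: np.ndarray,
    grid_shape: tuple,
    voxel_size: float,
) -> VoxelStatMap:
    """Correlation of HbT AUC with the stimulation frequency in Hz."""
    r, p = pearson_rp(np.asarray(frequencies, dtype=float), Y)
    return VoxelStatMap(r=r, p=p, method="frequency",
                        voxel_indices=np.asarray(voxel_indices),
                        grid_shape=tuple(grid_shape), voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# Cluster formation, correction, calibration
# ---------------------------------------------------------------------------

def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def _components(stat_map: VoxelStatMap, threshold: float,
                connectivity: int) -> list[np.ndarray]:
    """Flat-index voxel sets of connected subthreshold components."""
    mask = np.zeros(int(np.prod(stat_map.grid_shape)), dtype=bool)
    sub = stat_map.p < threshold          # NaN-safe: NaN compares False
    mask[stat_map.voxel_indices[sub]] = True
    lab, n = ndimage.label(mask.reshape(stat_map.grid_shape),
                           structure=_connectivity_structure(connectivity))
    lab = lab.ravel()
    return [np.nonzero(lab == i)[0] for i in range(1, n + 1)]


def component_volumes(stat_map: VoxelStatMap, threshold: float,
                      connectivity: int = 6) -> np.ndarray:
    """Volumes (mm^3) of all suprathreshold components, unfiltered.

    The raw ingredient of the minimum-volume calibration: connected
    components of voxels with p below ``threshold``, before any
    minimum-volume rule is applied.
    """
    vox_vol = stat_map.voxel_size**3
    return np.array([
        v.size * vox_vol for v in _components(stat_map, threshold, connectivity)
    ])


def form_clusters(
    stat_map: VoxelStatMap,
    cluster_stat_fn,
    min_volume: float = MIN_CLUSTER_VOLUME,
    levels: dict[str, float] = None,
    connectivity: int = 6,
) -> list[ClusterResult]:
    """Threshold-level clustering with per-component level selection.

    At each voxel-p threshold level, 6-connected components of
    subthreshold FOV voxels with volume >= ``min_volume`` survive;
    their statistic is recomputed by ``cluster_stat_fn(member_flat_indices)
    -> (r, p)``, which should average the member-voxel signals and
    rerun the map's correlation or t test.  Components from different
    levels that overlap spatially describe the same activation at
    different extents: per such spatial component, the level with the
    lowest recomputed cluster p is reported.
    """
    if levels is None:
        levels = LEVELS
    vox_vol = stat_map.voxel_size**3
    candidates = []
    for name, thr in levels.items():
        for vox in _components(stat_map, thr, connectivity):
            vol = vox.size * vox_vol
            if vol < min_volume:
                continue
            r, p = cluster_stat_fn(vox)
            candidates.append(ClusterResult(
                voxel_indices=vox, volume_mm3=vol, level=name, r=float(r),
                p=float(p), method=stat_map.method, feature_id=stat_map.feature_id,
            ))
    if not candidates:
        return []
    # group candidates that share voxels (levels are nested, so overlap
    # is transitive through the loosest-level component)
    parent = list(range(len(candidates)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sets = [set(c.voxel_indices.tolist()) for c in candidates]
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if sets[i] & sets[j]:
                parent[find(i)] = find(j)
    best: dict[int, ClusterResult] = {}
    order = {"L1": 0, "L2": 1, "L3": 2}
    for i, c in enumerate(candidates):
        g = find(i)
        cur = best.get(g)
        if cur is None or (c.p, order.get(c.level, 9)) < (cur.p, order.get(cur.level, 9)):
            best[g] = c
    return sorted(best.values(), key=lambda c: c.p)


def correct_clusters(clusters: list[ClusterResult], n_mc: int = N_MC,
                     report_p: float = REPORT_P,
                     signif_p: float = SIGNIF_P) -> list[ClusterResult]:
    """Bonferroni-correct cluster p values: p_corr = min(1, n_mc p).

    Sets ``p_corrected`` and the ``significant`` flag (p_corr <
    ``signif_p``); clusters above ``report_p`` are retained but marked
    non-significant so callers can render them as NS.
    """
    for c in clusters:
        c.p_corrected = min(1.0, n_mc * c.p)
        c.significant = c.p_corrected < signif_p
        c.extra["reportable"] = c.p_corrected < report_p
    return clusters


def subgroup_permutation_test(
    y: np.ndarray,
    x: np.ndarray,
    row_subjects: np.ndarray,
    subject_groups: dict,
    n_perm: int = 2000,
    seed=None,
) -> float:
    """Permutation test for a subgroup difference in cluster correlation.

    The observed statistic is |r_A - r_B| where r_g is the Pearson
    correlation of (y, x) restricted to the rows of subjects in group
    g.  Group labels are permuted across subjects (keeping group
    sizes); the p value is (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    row_subjects = np.asarray(row_subjects)
    subjects = np.array(sorted({*row_subjects.tolist()}))
    labels = np.array([subject_groups[s] for s in subjects])
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("need exactly two groups")
    if min((labels == g).sum() for g in uniq) < 2:
        raise ValueError("each group needs at least 2 subjects")

    def stat(lab):
        rs = []
        for g in uniq:
            members = set(subjects[lab == g].tolist())
            m = np.array([s in members for s in row_subjects])
            r, _ = pearson_rp(x[m], y[m])
            rs.append(r)
        return abs(rs[0] - rs[1])

    obs = stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def calibrate_min_volume(
    null_component_volumes: list[np.ndarray],
    voxel_volume: float,
    target_fpr: float = 0.05,
) -> float:
    """Smallest minimum-volume rule achieving the target null FPR.

    ``null_component_volumes`` holds, per null dataset, the volumes
    (mm^3) of all suprathreshold connected components before any
    minimum-volume filtering.  The family-wise false-positive rate of a
    rule v is the fraction of datasets with at least one component of
    volume >= v; the calibrated rule is the smallest multiple of the
    voxel volume whose estimated FPR does not exceed ``target_fpr``.
    """
    if not null_component_volumes:
        raise ValueError("need at least one null dataset")
    maxima = np.array([
        (np.max(v) if len(v) else 0.0) for v in null_component_volumes
    ])
    v = voxel_volume
    while np.mean(maxima >= v) > target_fpr:
        v += voxel_volume
    return float(v)
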