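"""Atlas-to-subject head registration.

A voxelized atlas head model is registered to each subject's digitized
head geometry (landmarks plus photogrammetry/digitizer surface points)
with a 9-parameter similarity transform (per-axis scale, rotation,
translation).  The cost is the mean of the Landmark Registration Error
(LRE; component-wise soft-thresholded landmark distances, tolerating
3-5 mm of landmark-picking uncertainty) and the Surface Registration
Error (SRE; weighted mean distance from head points to the warped
atlas scalp mesh, facial points below the nasion down-weighted to 0.8).
Optimization is an iterative-closest-point style coordinate descent
over a discrete parameter grid: closest surface points are recomputed
at every candidate deformation and only cost-lowering steps are
accepted, so the cost is non-increasing.  Optode positions measured in
the subject frame are carried to the atlas frame with the inverse
transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RegistrationParams",
    "SearchGrid",
    "rigid_register",
    "point_mesh_distance",
    "registration_error",
    "optimize_registration",
    "warp_optodes",
]


@dataclass
class RegistrationParams:
    """Similarity transform: x -> R(angles) @ (scale * x) + translation.

    ``scale`` is per-axis (dimensionless), ``rotation_deg`` holds xyz
    Euler angles in degrees and ``translation`` is in mm.  ``cost`` is
    the mean of SRE and LRE at these parameters, when evaluated.
    """

    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cost: float | None = None

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 transform matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation_matrix() @ np.diag(self.scale)
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (self.rotation_matrix() @ (np.asarray(points) * self.scale).T).T + self.translation

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        if np.any(self.scale == 0):
            raise ValueError("singular scale")
        y = (np.asarray(points) - self.translation) @ self.rotation_matrix()
        return y / self.scale

    def as_dict(self) -> dict:
        return {
            "scale": self.scale.tolist(),
            "rotation_deg": self.rotation_deg.tolist(),
            "translation": self.translation.tolist(),
            "cost": self.cost,
            "matrix": self.matrix().tolist(),
        }


def rigid_register(source: np.ndarray, target: np.ndarray):
    """Least-squares rigid transform mapping corresponding points.

    Closed-form (SVD/Kabsch) solution of min_{R,t} sum ||R s_i + t - t_i||^2
    over proper rotations.  Returns ``(R, t, rms)`` where ``rms`` is the
    post-fit residual RMS.  Requires >= 3 non-collinear correspondences.
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if S.shape != T.shape or S.shape[0] < 3:
        raise ValueError("need >= 3 corresponding points of equal count")
    cs, ct = S.mean(axis=0), T.mean(axis=0)
    H = (S - cs).T @ (T - ct)
    U, sv, Vt = np.linalg.svd(H)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    rms = float(np.sqrt(np.mean(np.sum(((R @ S.T).T + t - T) ** 2, axis=1))))
    return R, t, rms


def point_mesh_distance(points: np.ndarray, vertices: np.ndarray,
                        faces: np.ndarray) -> np.ndarray:
    """Exact minimum distance from each point to a triangle mesh.

    Vectorized point-to-triangle distance over all (point, face)
    combinations; intended for the small meshes used in registration.
    """
    P = np.asarray(points, dtype=float)
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=int)
    A, B, C = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    AB = B - A
    AC = C - A
    d1 = np.einsum("fi,pfi->pf", AB, P[:, None, :] - A[None])
    d2 = np.einsum("fi,pfi->pf", AC, P[:, None, :] - A[None])
    a = np.einsum("fi,fi->f", AB, AB)[None]
    b = np.einsum("fi,fi->f", AB, AC)[None]
    c = np.einsum("fi,fi->f", AC, AC)[None]
    det = a * c - b * b
    det = np.where(det <= 0, 1e-300, det)
    # unconstrained barycentric solution, then clamp to the triangle
    v = (c * d1 - b * d2) / det
    w = (a * d2 - b * d1) / det
    v = np.clip(v, 0.0, 1.0)
    w = np.clip(w, 0.0, 1.0)
    s = v + w
    scale = np.where(s > 1.0, 1.0 / np.where(s > 0, s, 1.0), 1.0)
    v *= scale
    w *= scale
    # clamping in barycentric space is not exact for all regions; refine
    # by also testing the three edges
    def seg_dist2(P, E0, E1):
        d = E1 - E0
        tnum = np.einsum("fi,pfi->pf", d, P[:, None, :] - E0[None])
        tden = np.einsum("fi,fi->f", d, d)[None]
        tt = np.clip(tnum / np.where(tden > 0, tden, 1.0), 0.0, 1.0)
        Q = E0[None] + tt[..., None] * d[None]
        return np.sum((P[:, None, :] - Q) ** 2, axis=-1)

    Q = A[None] + v[..., None] * AB[None] + w[..., None] * AC[None]
    d2_face = np.sum((P[:, None, :] - Q) ** 2, axis=-1)
    d2_all = np.minimum(d2_face, seg_dist2(P, A, B))
    d2_all = np.minimum(d2_all, seg_dist2(P, A, C))
    d2_all = np.minimum(d2_all, seg_dist2(P, B, C))
    return np.sqrt(np.min(d2_all, axis=1))


def registration_error(
    params: RegistrationParams,
    atlas_landmarks: np.ndarray,
    target_landmarks: np.ndarray,
    atlas_vertices: np.ndarray,
    atlas_faces: np.ndarray,
    target_head_points: np.ndarray,
    facial: np.ndarray | None = None,
    lre_threshold=4.0,
    facial_weight: float = 0.8,
) -> float:
    """Registration cost: mean of surface and landmark errors.

    LRE: for each landmark, the component-wise absolute differences
    between the warped atlas landmark and the target landmark are
    soft-thresholded (max(|d_c| - tau_c, 0), tau default 4 mm per
    axis, configurable in 3-5 mm) and the norms averaged -- landmarks
    agreeing within the threshold contribute zero.  SRE: weighted mean
    distance from the target head points to the warped atlas scalp
    mesh, with weight ``facial_weight`` for facial points (below the
    nasion) and 1 otherwise.  Cost = (SRE + LRE) / 2.
    """
    atlas_landmarks = np.asarray(atlas_landmarks, dtype=float)
    target_landmarks = np.asarray(target_landmarks, dtype=float)
    if atlas_landmarks.size == 0 or len(atlas_faces) == 0:
        raise ValueError("empty landmark set or surface mesh")
    tau = np.broadcast_to(np.asarray(lre_threshold, dtype=float), (3,))
    warped_lm = params.apply(atlas_landmarks)
    d = np.abs(warped_lm - target_landmarks)
    soft = np.maximum(d - tau, 0.0)
    lre = float(np.mean(np.linalg.norm(soft, axis=1)))
    warped_v = params.apply(np.asarray(atlas_vertices, dtype=float))
    dist = point_mesh_distance(np.asarray(target_head_points, dtype=float),
                               warped_v, atlas_faces)
    if facial is None:
        w = np.ones(dist.size)
    else:
        w = np.where(np.asarray(facial, dtype=bool), facial_weight, 1.0)
    sre = float(np.sum(w * dist) / np.sum(w))
    cost = 0.5 * (sre + lre)
    if not np.isfinite(cost):
        raise ValueError("non-finite registration cost")
    return cost


@dataclass(frozen=True)
class SearchGrid:
    """Discrete per-parameter search ranges around the initial values."""

    scale_range: float = 0.10      # +/- fraction
    scale_step: float = 0.01
    rot_range: float = 15.0        # +/- degrees
    rot_step: float = 1.0
    trans_range: float = 20.0      # +/- mm
    trans_step: float = 1.0

    def offsets(self, kind: str) -> np.ndarray:
        rng, step = {
            "scale": (self.scale_range, self.scale_step),
            "rot": (self.rot_range, self.rot_step),
            "trans": (self.trans_range, self.trans_step),
        }[kind]
        n = int(round(rng / step))
        return np.arange(-n, n + 1) * step


def optimize_registration(
    atlas_landmarks: np.ndarray,
    target_landmarks: np.ndarray,
    atlas_vertices: np.ndarray,
    atlas_faces: np.ndarray,
    target_head_points: np.ndarray,
    facial: np.ndarray | None = None,
    init: RegistrationParams | None = None,
    grid: SearchGrid | None = None,
    max_iter: int = 20,
    lre_threshold=4.0,
    facial_weight: float = 0.8,
) -> RegistrationParams:
    """Discrete coordinate-descent search over the 9 transform parameters.

    Starting from the rigid landmark registration (or ``init``), each
    sweep scans every parameter over its discrete grid (offsets from
    the initial value), accepting the value with the lowest cost;
    closest-surface distances are recomputed at every candidate, i.e.
    the correspondence set follows the deformation as in iterative
    closest points.  Ties break toward the smaller parameter change.
    Terminates when a full sweep changes nothing or after ``max_iter``
    sweeps; the cost sequence is non-increasing by construction.
    """
    if grid is None:
        grid = SearchGrid()
    if init is None:
        R, t, _ = rigid_register(atlas_landmarks, target_landmarks)
        init = RegistrationParams(
            scale=np.ones(3),
            rotation_deg=Rotation.from_matrix(R).as_euler("xyz", degrees=True),
            translation=np.asarray(t, dtype=float),
        )

    def cost_of(p: RegistrationParams) -> float:
        return registration_error(
            p, atlas_landmarks, target_landmarks, atlas_vertices, atlas_faces,
            target_head_points, facial=facial, lre_threshold=lre_threshold,
            facial_weight=facial_weight,
        )

    current = replace(init, scale=init.scale.copy(),
                      rotation_deg=init.rotation_deg.copy(),
                      translation=init.translation.copy())
    current.cost = cost_of(current)
    specs = [("scale", ax) for ax in range(3)] + \
            [("rot", ax) for ax in range(3)] + \
            [("trans", ax) for ax in range(3)]
    base = {
        "scale": init.scale.copy(),
        "rot": init.rotation_deg.copy(),
        "trans": init.translation.copy(),
    }
    arrays = {"scale": current.scale, "rot": current.rotation_deg,
              "trans": current.translation}
    for _ in range(max_iter):
        changed = False
        for kind, ax in specs:
            arr = arrays[kind]
            old = arr[ax]
            best_val, best_cost = old, current.cost
            for off in grid.offsets(kind):
                val = base[kind][ax] + off
                if kind == "scale" and val <= 0:
                    continue
                if val == old:
                    continue
                arr[ax] = val
                c = cost_of(current)
                better = c < best_cost - 1e-12
                tie = abs(c - best_cost) <= 1e-12 and abs(val - old) < abs(best_val - old)
                if better or tie:
                    best_val, best_cost = val, c
            arr[ax] = best_val
            if best_val != old:
                changed = True
                current.cost = best_cost
        if not changed:
            break
    return current


def warp_optodes(params: RegistrationParams, positions: np.ndarray) -> np.ndarray:
    """Map optode positions from the subject frame to the atlas frame.

    ``params`` is the atlas-to-subject transform found by
    :func:`optimize_registration`; its inverse carries subject-frame
    coordinates back to the atlas.
    """
    return params.apply_inverse(positions)
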