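"""Generalized Procrustes Analysis with sliding semilandmarks.

Configurations are superimposed by removing translation (centering), size
(scaling to unit centroid size) and orientation (proper orthogonal rotation
to the consensus), iterating until the total residual stabilizes.  When a
sliding topology is supplied, curve and surface semilandmarks are allowed to
slide along their local tangents so as to minimize the thin-plate-spline
bending energy between each specimen and the consensus, after which the
superimposition is refreshed.

Reflections are excluded from the rotation step; mirror left-side
configurations to the right-side convention (:func:`mirror_configuration`)
before pooling sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ROLE_ANATOMICAL, ROLE_CURVE, ROLE_SURFACE, LandmarkSet, TriMesh
from .warp import bending_energy_matrix, closest_point_on_mesh


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared distances to the centroid (µm)."""
    config = np.asarray(config, dtype=float).reshape(-1, 3)
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered ** 2)))


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    config = np.asarray(config, dtype=float).reshape(-1, 3)
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered ** 2)))
    if cs == 0:
        raise ValueError("degenerate configuration with zero centroid size")
    return centered / cs, cs


def _optimal_rotation(
    x: np.ndarray, target: np.ndarray, allow_reflection: bool = False
) -> np.ndarray:
    """Rotation R minimizing ||x @ R - target||_F (proper unless allowed)."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def mirror_configuration(config: np.ndarray, plane: str = "yz") -> np.ndarray:
    """Mirror a configuration across a coordinate plane (negates one axis)."""
    axis = {"yz": 0, "xz": 1, "xy": 2}.get(plane)
    if axis is None:
        raise ValueError(f"plane must be one of yz/xz/xy, got {plane!r}")
    out = np.array(config, dtype=float)
    out[:, axis] *= -1
    return out


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance: residual after optimally centering, scaling
    and (properly) rotating ``b`` onto ``a``."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("configurations must share the same number of landmarks")
    a1, _ = _center_scale(a)
    b1, _ = _center_scale(b)
    r = _optimal_rotation(b1, a1)
    br = b1 @ r
    beta = float(np.sum(a1 * br))          # optimal scale of b onto a
    return float(np.linalg.norm(a1 - beta * br))


# ---------------------------------------------------------------------------
# sliding topology
# ---------------------------------------------------------------------------

@dataclass
class SlidingTopology:
    """Which landmarks slide, and along what local geometry.

    ``curve_neighbors[i] = (prev, next)`` (either may be ``None`` at open
    curve ends); ``surface_neighbors[i]`` lists indices used for
    tangent-plane estimation when no specimen mesh is available.  Anatomical
    landmarks are fixed and never move.
    """

    roles: list[str]
    curve_neighbors: dict[int, tuple[int | None, int | None]] = field(
        default_factory=dict
    )
    surface_neighbors: dict[int, list[int]] = field(default_factory=dict)

    @classmethod
    def from_landmarks(
        cls,
        landmarks: LandmarkSet,
        closed_curves: set[str] | None = None,
        n_surface_neighbors: int = 8,
    ) -> "SlidingTopology":
        closed_curves = closed_curves or set()
        roles = list(landmarks.roles)
        curve_neighbors: dict[int, tuple[int | None, int | None]] = {}
        by_curve: dict[str, list[tuple[int, int]]] = {}
        for i, (role, cid, o) in enumerate(
            zip(roles, landmarks.curve_ids, landmarks.ordinals)
        ):
            if role == ROLE_CURVE:
                by_curve.setdefault(str(cid), []).append((int(o), i))
        for cid, members in by_curve.items():
            order = [i for _, i in sorted(members)]
            closed = cid in closed_curves
            for pos, i in enumerate(order):
                prev = order[pos - 1] if (pos > 0 or closed) else None
                nxt = order[(pos + 1) % len(order)] if (
                    pos < len(order) - 1 or closed
                ) else None
                curve_neighbors[i] = (prev, nxt)
        surf = [i for i, r in enumerate(roles) if r == ROLE_SURFACE]
        surface_neighbors: dict[int, list[int]] = {}
        pts = landmarks.points
        for i in surf:
            others = [j for j in surf if j != i]
            if len(others) < 2:
                raise ValueError("surface sliding needs >= 3 surface points")
            d = np.linalg.norm(pts[others] - pts[i], axis=1)
            keep = np.argsort(d)[:n_surface_neighbors]
            surface_neighbors[i] = [others[j] for j in keep]
        return cls(roles=roles, curve_neighbors=curve_neighbors,
                   surface_neighbors=surface_neighbors)

    def validate(self, k: int) -> None:
        if len(self.roles) != k:
            raise ValueError("topology roles length does not match landmarks")
        for i, (p, n) in self.curve_neighbors.items():
            for j in (i, p, n):
                if j is not None and not 0 <= j < k:
                    raise ValueError(f"invalid neighbor index {j}")
        for i, nb in self.surface_neighbors.items():
            if not 0 <= i < k or any(not 0 <= j < k for j in nb):
                raise ValueError("invalid surface neighbor index")


def _tangent_dirs(
    x: np.ndarray, topology: SlidingTopology, mesh: TriMesh | None
) -> list[tuple[int, np.ndarray]]:
    """Unit slide directions per sliding degree of freedom at configuration x."""
    dirs: list[tuple[int, np.ndarray]] = []
    for i, role in enumerate(topology.roles):
        if role == ROLE_CURVE:
            prev, nxt = topology.curve_neighbors.get(i, (None, None))
            a = x[prev] if prev is not None else x[i]
            b = x[nxt] if nxt is not None else x[i]
            t = b - a
            norm = np.linalg.norm(t)
            if norm > 0:
                dirs.append((i, t / norm))
        elif role == ROLE_SURFACE:
            if mesh is not None:
                _, _, fidx = closest_point_on_mesh(mesh, x[i][None])
                tm = mesh.to_trimesh()
                normal = np.asarray(tm.face_normals[fidx[0]], dtype=float)
            else:
                nb = topology.surface_neighbors[i]
                local = x[nb] - x[nb].mean(axis=0)
                _, _, vt = np.linalg.svd(local, full_matrices=False)
                normal = vt[-1]
            # orthonormal tangent-plane basis
            ref = np.array([1.0, 0.0, 0.0])
            if abs(normal @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            t1 = np.cross(normal, ref)
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(normal, t1)
            t2 /= np.linalg.norm(t2)
            dirs.append((i, t1))
            dirs.append((i, t2))
    return dirs


def slide_semilandmarks(
    configs: list[np.ndarray],
    consensus: np.ndarray,
    topology: SlidingTopology,
    meshes: list[TriMesh | None] | None = None,
) -> list[np.ndarray]:
    """Slide semilandmarks along their tangents to minimize bending energy.

    Each specimen's semilandmarks move along the local tangent (curve:
    predecessor->successor direction; surface: tangent plane) by the exact
    minimizer of the TPS bending energy against the consensus.  Anatomical
    landmarks are returned unchanged.  If per-specimen meshes are supplied,
    surface points are back-projected onto them after sliding.
    """
    consensus = np.asarray(consensus, dtype=float)
    topology.validate(len(consensus))
    B = bending_energy_matrix(consensus)
    if meshes is None:
        meshes = [None] * len(configs)
    out = []
    for x, mesh in zip(configs, meshes):
        x = np.array(x, dtype=float)
        dirs = _tangent_dirs(x, topology, mesh)
        if not dirs:
            out.append(x)
            continue
        idx = np.array([i for i, _ in dirs])
        u = np.array([d for _, d in dirs])
        G = B[np.ix_(idx, idx)] * (u @ u.T)
        g = np.einsum("jd,jd->j", (B @ x)[idx], u)
        ridge = 1e-12 * max(np.trace(G), 1.0)
        t = np.linalg.solve(G + ridge * np.eye(len(g)), -g)
        delta = np.zeros_like(x)
        np.add.at(delta, idx, t[:, None] * u)
        moved = x + delta
        if mesh is not None:
            surf = [i for i, r in enumerate(topology.roles) if r == ROLE_SURFACE]
            proj, _, _ = closest_point_on_mesh(mesh, moved[surf])
            moved[surf] = proj
        out.append(moved)
    return out


def total_bending_energy(configs: list[np.ndarray], consensus: np.ndarray) -> float:
    """Sum over specimens of TPS bending energy consensus -> specimen."""
    B = bending_energy_matrix(np.asarray(consensus, dtype=float))
    return float(sum(
        max(0.0, np.einsum("id,ij,jd->", np.asarray(x), B, np.asarray(x)))
        for x in configs
    ))


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class GPAResult:
    aligned: np.ndarray           # (n, k, 3) Procrustes coordinates
    consensus: np.ndarray         # (k, 3), centered, unit centroid size
    centroid_sizes: np.ndarray    # (n,) pre-scaling sizes, µm
    iterations: int
    residual_trace: list[float]   # final superimposition phase, non-increasing
    bending_trace: list[float]    # total BE before/after each sliding pass
    specimen_ids: list[str]


def _superimpose(
    shapes: np.ndarray,
    consensus: np.ndarray,
    allow_reflection: bool,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, int, list[float]]:
    """Alternating rotation/consensus updates on unit-size centered shapes."""
    n = len(shapes)
    trace: list[float] = []
    prev = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(
                shapes[i], consensus, allow_reflection
            )
        mean = shapes.mean(axis=0)
        mean -= mean.mean(axis=0)
        mean /= np.sqrt(np.sum(mean ** 2))
        consensus = mean
        residual = float(np.sum((shapes - consensus) ** 2))
        trace.append(residual)
        if prev - residual <= tol * max(prev, 1e-30) and iterations > 1:
            break
        prev = residual
    return shapes, consensus, iterations, trace


def gpa(
    configs: list[LandmarkSet] | list[np.ndarray],
    sliding: SlidingTopology | None = None,
    allow_reflection: bool = False,
    max_iter: int = 1000,
    tol: float = 1e-14,
    slide_iterations: int = 3,
    meshes: list[TriMesh | None] | None = None,
) -> GPAResult:
    """Generalized Procrustes Analysis, optionally with sliding semilandmarks.

    With sliding, the schedule is ``slide_iterations`` outer passes of
    (superimpose to convergence -> slide against the consensus), followed by
    a final superimposition; ``residual_trace`` records that final phase.
    """
    ids: list[str] = []
    arrays: list[np.ndarray] = []
    for i, c in enumerate(configs):
        if isinstance(c, LandmarkSet):
            ids.append(c.specimen_id)
            arrays.append(np.asarray(c.points, dtype=float))
        else:
            ids.append(f"specimen_{i}")
            arrays.append(np.asarray(c, dtype=float).reshape(-1, 3))
    n = len(arrays)
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = arrays[0].shape[0]
    if any(a.shape != (k, 3) for a in arrays):
        raise ValueError("all configurations must share the same number of landmarks")
    if k < 3:
        raise ValueError("GPA needs k >= 3 landmarks")

    shapes = np.empty((n, k, 3))
    sizes = np.empty(n)
    for i, a in enumerate(arrays):
        shapes[i], sizes[i] = _center_scale(a)
    if np.linalg.matrix_rank(shapes[0]) < 2:
        raise ValueError("collinear configurations cannot be superimposed in 3D")

    consensus = shapes[0].copy()
    total_iters = 0
    bending_trace: list[float] = []

    if sliding is not None:
        for _ in range(slide_iterations):
            shapes, consensus, it, _ = _superimpose(
                shapes, consensus, allow_reflection, max_iter, tol
            )
            total_iters += it
            bending_trace.append(total_bending_energy(list(shapes), consensus))
            slid = slide_semilandmarks(list(shapes), consensus, sliding, meshes)
            bending_trace.append(total_bending_energy(slid, consensus))
            for i, x in enumerate(slid):       # re-center/scale after sliding
                shapes[i], _ = _center_scale(x)

    shapes, consensus, it, trace = _superimpose(
        shapes, consensus, allow_reflection, max_iter, tol
    )
    total_iters += it
    return GPAResult(
        aligned=shapes, consensus=consensus, centroid_sizes=sizes,
        iterations=total_iters, residual_trace=trace,
        bending_trace=bending_trace, specimen_ids=ids,
    )


def flag_outliers(
    result: GPAResult, rule: str = "iqr", param: float = 1.5
) -> list[str]:
    """Screen specimens by squared Procrustes distance to the consensus.

    ``iqr`` flags squared distances above ``Q3 + param * IQR``; ``quantile``
    flags those above the ``param`` quantile.
    """
    n = len(result.aligned)
    if n < 4:
        raise ValueError("outlier screening needs n >= 4 specimens")
    d2 = np.array([
        procrustes_distance(result.consensus, x) ** 2 for x in result.aligned
    ])
    eps = 1e-12 * max(float(d2.max()), 1e-30)   # guard pure-roundoff spread
    if rule == "iqr":
        q1, q3 = np.percentile(d2, [25, 75])
        iqr = q3 - q1
        cut = q3 if not np.isfinite(param * iqr) and iqr == 0 else q3 + param * iqr
        if np.isinf(param):
            cut = np.inf
        flagged = d2 > cut + eps
    elif rule == "quantile":
        flagged = d2 > np.quantile(d2, param) + eps
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    return [sid for sid, f in zip(result.specimen_ids, flagged) if f]


def export_procrustes_csv(result: GPAResult, path: str) -> None:
    """Write Procrustes coordinates, one specimen per row (x1,y1,z1,...)."""
    import pandas as pd

    k = result.consensus.shape[0]
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in "xyz"]
    df = pd.DataFrame(
        result.aligned.reshape(len(result.aligned), -1), columns=cols
    )
    df.insert(0, "specimen_id", result.specimen_ids)
    df["centroid_size"] = result.centroid_sizes
    df.to_csv(path, index=False)
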