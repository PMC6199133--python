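"""Thin-plate-spline warping, curve resampling and semilandmark transfer.

The 3D TPS interpolant with kernel ``U(r) = r`` maps a source landmark
configuration exactly onto a target one; its non-affine part carries the
*bending energy*, the quadratic deformation cost that also drives
semilandmark sliding (see :mod:`optmorph.procrustes`).  Surface
semilandmarks are digitized once on a template and transferred to each
target by warping with the TPS fitted on the fixed (anatomical + curve)
landmarks, then projecting onto the target surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    ROLE_ANATOMICAL,
    ROLE_CURVE,
    ROLE_SURFACE,
    LandmarkSet,
    TriMesh,
)


# ---------------------------------------------------------------------------
# thin-plate splines
# ---------------------------------------------------------------------------

@dataclass
class TPSTransform:
    """Exact 3D thin-plate-spline interpolant ``f(x) = A^T [1, x] + W^T U``.

    ``weights`` (k, 3) multiply the kernel ``U(r) = r`` evaluated at the
    source points; ``affine`` is the (4, 3) affine block.  ``bending_energy``
    is the quadratic form of the non-affine part, zero iff the map is affine.
    """

    source: np.ndarray
    target: np.ndarray
    weights: np.ndarray
    affine: np.ndarray
    bending_energy: float


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise kernel U(r) = r between two point sets."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def tps_fit(source: np.ndarray, target: np.ndarray) -> TPSTransform:
    """Fit the exact TPS interpolant mapping ``source`` onto ``target``.

    Requires k >= 4 non-coplanar, pairwise distinct source points.
    """
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    k = len(source)
    if k != len(target):
        raise ValueError("source and target must have the same number of points")
    if k < 4:
        raise ValueError("TPS needs at least 4 source points")
    K = _kernel_matrix(source, source)
    off = K[~np.eye(k, dtype=bool)]
    if off.size and off.min() == 0.0:
        raise ValueError("duplicate source points make the TPS system singular")
    P = np.hstack([np.ones((k, 1)), source])
    if np.linalg.matrix_rank(P) < 4:
        raise ValueError("coplanar source points make the TPS system singular")
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = target
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular TPS system: {exc}") from exc
    W, A = sol[:k], sol[k:]
    # with U(r)=r, w'Kw is <= 0 on the affine-orthogonal subspace; the
    # bending energy is its negation (clipped against roundoff)
    be = float(max(0.0, -np.einsum("id,ij,jd->", W, K, W)))
    return TPSTransform(source=source, target=target, weights=W, affine=A,
                        bending_energy=be)


def tps_apply(transform: TPSTransform, points: np.ndarray) -> np.ndarray:
    """Apply a fitted TPS transform to arbitrary points (m, 3)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    U = _kernel_matrix(points, transform.source)
    P = np.hstack([np.ones((len(points), 1)), points])
    return P @ transform.affine + U @ transform.weights


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix ``B`` (k, k) of a reference configuration.

    For any target configuration ``X`` (k, 3), the bending energy of the TPS
    warp reference -> X equals ``trace(X^T B X)``.  ``B`` is symmetric
    positive semidefinite with the affine configurations in its null space.
    """
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    k = len(reference)
    K = _kernel_matrix(reference, reference)
    P = np.hstack([np.ones((k, 1)), reference])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    Linv = np.linalg.inv(L)
    B = -Linv[:k, :k]          # sign flip: U(r)=r kernel is conditionally negative
    return (B + B.T) / 2.0


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def resample_curve(polyline: np.ndarray, n: int) -> np.ndarray:
    """Resample an ordered polyline to ``n`` points equally spaced by arc
    length, preserving the first and last points."""
    polyline = np.asarray(polyline, dtype=float).reshape(-1, 3)
    if n < 2:
        raise ValueError("n must be >= 2")
    if len(polyline) < 2:
        raise ValueError("polyline needs at least 2 points")
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("degenerate polyline with zero length")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n)
    out = np.column_stack([
        np.interp(targets, s, polyline[:, d]) for d in range(3)
    ])
    out[0], out[-1] = polyline[0], polyline[-1]
    return out


# ---------------------------------------------------------------------------
# point-to-mesh projection (exact, deterministic)
# ---------------------------------------------------------------------------

def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle of ``tri`` (m, 3, 3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                      # vertex a
    out[m], done[m] = a[m], True
    m = ~done & (d3 >= 0) & (d4 <= d3)             # vertex b
    out[m], done[m] = b[m], True
    m = ~done & (d6 >= 0) & (d5 <= d6)             # vertex c
    out[m], done[m] = c[m], True
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done[m] = True
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done[m] = True
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done[m] = True
    m = ~done                                      # interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def closest_point_on_mesh(
    mesh: TriMesh, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest points on a mesh; ties broken by lowest face index.

    Returns ``(projected (m,3), distance (m,), face_index (m,))``.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(mesh.faces) == 0:
        raise ValueError("empty target mesh")
    tri = mesh.vertices[mesh.faces]
    proj = np.empty_like(points)
    dist = np.empty(len(points))
    fidx = np.empty(len(points), dtype=int)
    for i, p in enumerate(points):
        cand = _closest_on_triangles(p, tri)
        d = np.linalg.norm(cand - p, axis=1)
        j = int(np.argmin(d))       # argmin returns the lowest index on ties
        proj[i], dist[i], fidx[i] = cand[j], d[j], j
    return proj, dist, fidx


def mesh_vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Area-weighted vertex normals (unit length)."""
    tm = mesh.to_trimesh()
    normals = np.asarray(tm.vertex_normals, dtype=float)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return normals / norms


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

@dataclass
class TemplateSpec:
    """Template mesh plus the full landmark scheme digitized on it."""

    mesh: TriMesh
    landmarks: LandmarkSet
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        surf = np.asarray(
            [r == ROLE_SURFACE for r in self.landmarks.roles], dtype=bool
        )
        if surf.any():
            _, dist, _ = closest_point_on_mesh(
                self.mesh, self.landmarks.points[surf]
            )
            if dist.max() > 1e-6:
                raise ValueError(
                    "surface semilandmarks must lie on the template mesh "
                    f"(max deviation {dist.max():.3g} µm)"
                )
        if not self.counts:
            self.counts = {
                "anatomical": sum(
                    r == ROLE_ANATOMICAL for r in self.landmarks.roles
                ),
                "curve": sum(r == ROLE_CURVE for r in self.landmarks.roles),
                "surface": int(surf.sum()),
            }

    @property
    def fixed_index(self) -> np.ndarray:
        return np.asarray([
            r in (ROLE_ANATOMICAL, ROLE_CURVE) for r in self.landmarks.roles
        ], dtype=bool)

    @property
    def surface_index(self) -> np.ndarray:
        return np.asarray(
            [r == ROLE_SURFACE for r in self.landmarks.roles], dtype=bool
        )


def transfer_template(
    template: TemplateSpec,
    target_mesh: TriMesh,
    target_fixed: LandmarkSet,
) -> LandmarkSet:
    """Transfer template surface semilandmarks onto a target specimen.

    The TPS fitted on the fixed (anatomical + curve) landmarks warps the
    template surface semilandmarks towards the target; each warped point is
    then projected onto the closest point of the target mesh.  The output
    combines the target's own fixed landmarks with the projected surface
    points, preserving the template's point order and roles.
    """
    fixed = template.fixed_index
    n_fixed = int(fixed.sum())
    if target_fixed.k != n_fixed:
        raise ValueError(
            f"fixed-landmark scheme mismatch: template has {n_fixed}, "
            f"target has {target_fixed.k}"
        )
    if len(target_mesh.faces) == 0:
        raise ValueError("empty target mesh")
    tf = tps_fit(template.landmarks.points[fixed], target_fixed.points)
    warped = tps_apply(tf, template.landmarks.points[template.surface_index])
    projected, _, _ = closest_point_on_mesh(target_mesh, warped)

    points = np.empty_like(template.landmarks.points)
    points[fixed] = target_fixed.points
    points[template.surface_index] = projected
    return LandmarkSet(
        specimen_id=target_fixed.specimen_id,
        structure=target_fixed.structure,
        side=target_fixed.side,
        group=target_fixed.group,
        points=points,
        roles=list(template.landmarks.roles),
        curve_ids=list(template.landmarks.curve_ids),
        ordinals=list(template.landmarks.ordinals),
        landmark_ids=list(template.landmarks.landmark_ids),
    )


# ---------------------------------------------------------------------------
# digitization quality control
# ---------------------------------------------------------------------------

@dataclass
class DigitizationCheck:
    deviations: np.ndarray      # per-landmark Euclidean distance (µm)
    flags: np.ndarray           # deviation > tol
    averaged: LandmarkSet       # per-landmark midpoint of the two trials
    tol: float


def digitization_error_check(
    trial1: LandmarkSet, trial2: LandmarkSet, tol: float = 50.0
) -> DigitizationCheck:
    """Compare two digitization trials of the same specimen.

    ``tol`` is in µm (50 µm = the conventional 0.05 mm repeatability bound).
    """
    if not trial1.same_scheme(trial2) or trial1.specimen_id != trial2.specimen_id:
        raise ValueError("trials must share specimen and landmark scheme")
    deviations = np.linalg.norm(trial1.points - trial2.points, axis=1)
    flags = deviations > tol
    averaged = trial1.with_points((trial1.points + trial2.points) / 2.0)
    return DigitizationCheck(
        deviations=deviations, flags=flags, averaged=averaged, tol=float(tol)
    )
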