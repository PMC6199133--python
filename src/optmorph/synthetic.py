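"""Synthetic limb buds, landmark schemes and stained transmission volumes.

The generator emulates the study system: a limb-bud-like closed surface
whose proximo-distal (PD) elongation and antero-posterior (AP) asymmetry
increase with a developmental *stage* parameter, carrying a dark-stain
expression domain beneath its distal rim (a graded shell with a strongly
stained core, as produced by transmission imaging of NBT/BCIP staining).
A *mutant* group applies a group effect as PD shortening, dorso-ventral
(DV) thickening and expansion of the expression shell.  Axes: x = PD
(distal at +x), y = AP (anterior at +y), z = DV.

Grey-level anchors are 150 (tissue), 90 (stained shell), 30 (stained core)
and 255 (cleared background), chosen so the 1/3 - 2/3 multi-thresholding
rule lands between strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import (
    ROLE_ANATOMICAL,
    ROLE_CURVE,
    ROLE_SURFACE,
    LandmarkSet,
    TriMesh,
    Volume,
)
from .warp import TemplateSpec, closest_point_on_mesh

GREY_AIR = 255.0
GREY_TISSUE = 150.0
GREY_SHELL = 90.0
GREY_CORE = 30.0

WILDTYPE = "wildtype"
MUTANT = "mutant"


@dataclass
class SyntheticSpec:
    """Conditions of one synthetic specimen.

    stage : developmental stage in arbitrary units (~0 young bud, ~1 older).
    group_effect : magnitude of the mutant shift (0 = groups exchangeable).
    noise_sd : landmark jitter (µm) and additive voxel grey noise (grey units).
    spacing : isotropic voxel spacing (µm).
    seed : reproducibility seed; identical spec + seed => identical outputs.
    """

    stage: float = 1.0
    group_effect: float = 0.0
    noise_sd: float = 2.0
    spacing: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_effect < 0 or self.noise_sd < 0 or self.spacing <= 0:
            raise ValueError("invalid synthetic specification")


def _bud_params(spec: SyntheticSpec, group: str) -> tuple[float, float, float, float]:
    """PD length, AP half-width, DV half-height, AP asymmetry."""
    if group not in (WILDTYPE, MUTANT):
        raise ValueError(f"group must be wildtype|mutant, got {group!r}")
    length = 450.0 + 250.0 * spec.stage
    width = 300.0
    height = 260.0
    asym = 0.15 * spec.stage
    if group == MUTANT:
        length *= 1.0 - 0.18 * spec.group_effect
        height *= 1.0 + 0.20 * spec.group_effect
        asym *= max(0.0, 1.0 - 0.5 * spec.group_effect)
    return length, width, height, asym


def _bud_map(dirs: np.ndarray, length: float, width: float, height: float,
             asym: float) -> np.ndarray:
    """Map unit-sphere directions onto the bud surface (µm)."""
    sx, sy, sz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    x = 0.5 * length * (sx + 1.0)
    y = width * sy * (1.0 + asym * 0.5 * (1.0 + np.tanh(3.0 * sy)))
    z = height * sz
    return np.column_stack([x, y, z])


def _scheme_directions() -> tuple[np.ndarray, list[str], list, list]:
    """Fixed landmark scheme as unit-sphere directions with roles."""
    dirs = [
        (1.0, 0.0, 0.0),    # distal tip
        (-1.0, 0.0, 0.0),   # proximal pole
        (0.0, 1.0, 0.0),    # anterior extreme
        (0.0, -1.0, 0.0),   # posterior extreme
        (0.0, 0.0, 1.0),    # dorsal crest
    ]
    roles = [ROLE_ANATOMICAL] * 5
    curve_ids: list = [None] * 5
    ordinals: list = [None] * 5
    n_curve = 12
    for j in range(n_curve):  # closed mid-plane outline (z = 0)
        t = 2.0 * np.pi * j / n_curve
        dirs.append((np.cos(t), np.sin(t), 0.0))
        roles.append(ROLE_CURVE)
        curve_ids.append("outline")
        ordinals.append(j)
    # deterministic dorsal/ventral surface patch (golden-spiral directions
    # kept away from the equator and the poles)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    count = 0
    i = 0
    while count < 24:
        z = 1.0 - 2.0 * (i + 0.5) / 200.0
        r = np.sqrt(max(0.0, 1.0 - z * z))
        t = golden * i
        d = (r * np.cos(t), r * np.sin(t), z)
        i += 1
        if 0.35 <= abs(d[2]) <= 0.85:
            dirs.append(d)
            roles.append(ROLE_SURFACE)
            curve_ids.append(None)
            ordinals.append(None)
            count += 1
    return np.asarray(dirs, dtype=float), roles, curve_ids, ordinals


def make_limb_bud(
    spec: SyntheticSpec, group: str = WILDTYPE
) -> tuple[TriMesh, LandmarkSet]:
    """Generate one bud: a closed surface mesh plus its landmark scheme."""
    import trimesh as _trimesh

    length, width, height, asym = _bud_params(spec, group)
    sphere = _trimesh.creation.icosphere(subdivisions=3)
    verts = _bud_map(np.asarray(sphere.vertices), length, width, height, asym)
    mesh = TriMesh(vertices=verts, faces=np.asarray(sphere.faces))

    dirs, roles, curve_ids, ordinals = _scheme_directions()
    points = _bud_map(dirs, length, width, height, asym)
    rng = np.random.default_rng([int(spec.seed), 0])
    if spec.noise_sd > 0:
        points = points + rng.normal(0.0, spec.noise_sd, points.shape)
    landmarks = LandmarkSet(
        specimen_id=f"s{spec.seed}", structure="limb", group=group,
        points=points, roles=roles, curve_ids=curve_ids, ordinals=ordinals,
    )
    return mesh, landmarks


def make_template(spec: SyntheticSpec, group: str = WILDTYPE) -> TemplateSpec:
    """Noise-free bud with surface semilandmarks projected onto the mesh."""
    noiseless = SyntheticSpec(
        stage=spec.stage, group_effect=spec.group_effect, noise_sd=0.0,
        spacing=spec.spacing, seed=spec.seed,
    )
    mesh, landmarks = make_limb_bud(noiseless, group)
    surf = np.asarray([r == ROLE_SURFACE for r in landmarks.roles], dtype=bool)
    proj, _, _ = closest_point_on_mesh(mesh, landmarks.points[surf])
    points = landmarks.points.copy()
    points[surf] = proj
    return TemplateSpec(mesh=mesh, landmarks=landmarks.with_points(points))


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize(
    mesh: TriMesh,
    spacing: float | tuple[float, float, float],
    origin: tuple[float, float, float] | None = None,
    shape: tuple[int, int, int] | None = None,
    margin: int = 2,
) -> Volume:
    """Voxel-center inside test of a closed mesh (parity fill along z).

    Returns a boolean :class:`Volume`; a voxel is inside iff its centre is.
    Raises on open meshes and when no voxel centre falls inside the grid.
    """
    s = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (3,)).copy()
    if np.any(s <= 0):
        raise ValueError("spacing must be positive")
    if not mesh.is_watertight:
        raise ValueError("voxelize requires a closed (watertight) mesh")
    v = mesh.vertices
    lo, hi = v.min(axis=0), v.max(axis=0)
    if origin is None:
        origin = lo - margin * s
        shape = tuple(
            int(np.ceil((hi[d] - origin[d]) / s[d])) + margin + 1 for d in range(3)
        )
    elif shape is None:
        raise ValueError("shape is required when origin is given")
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = (int(m) for m in shape)

    tri = v[mesh.faces]
    scale = float(np.linalg.norm(hi - lo)) or 1.0
    ztol = 1e-9 * scale
    crossings: dict[tuple[int, int], list[float]] = {}
    for p0, p1, p2 in tri:
        det = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
        if abs(det) < 1e-14 * scale * scale:
            continue  # triangle vertical in z: contributes no column crossing
        txmin = min(p0[0], p1[0], p2[0])
        txmax = max(p0[0], p1[0], p2[0])
        tymin = min(p0[1], p1[1], p2[1])
        tymax = max(p0[1], p1[1], p2[1])
        i0 = max(0, int(np.ceil((txmin - origin[0]) / s[0])))
        i1 = min(nx - 1, int(np.floor((txmax - origin[0]) / s[0])))
        j0 = max(0, int(np.ceil((tymin - origin[1]) / s[1])))
        j1 = min(ny - 1, int(np.floor((tymax - origin[1]) / s[1])))
        if i0 > i1 or j0 > j1:
            continue
        xi = origin[0] + s[0] * np.arange(i0, i1 + 1)
        yj = origin[1] + s[1] * np.arange(j0, j1 + 1)
        gx, gy = np.meshgrid(xi, yj, indexing="ij")
        l1 = ((gx - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (gy - p0[1])) / det
        l2 = ((p1[0] - p0[0]) * (gy - p0[1]) - (gx - p0[0]) * (p1[1] - p0[1])) / det
        inside = (l1 >= -1e-12) & (l2 >= -1e-12) & (l1 + l2 <= 1.0 + 1e-12)
        if not inside.any():
            continue
        zc = p0[2] + l1 * (p1[2] - p0[2]) + l2 * (p2[2] - p0[2])
        ii, jj = np.nonzero(inside)
        for a, b in zip(ii, jj):
            crossings.setdefault((i0 + a, j0 + b), []).append(float(zc[a, b]))

    mask = np.zeros((nx, ny, nz), dtype=bool)
    for (i, j), zs in crossings.items():
        zs = sorted(zs)
        dedup = [zs[0]]
        for z in zs[1:]:
            if z - dedup[-1] > ztol:
                dedup.append(z)
        pairs = zip(dedup[0::2], dedup[1::2])
        for za, zb in pairs:
            k0 = max(0, int(np.ceil((za - origin[2]) / s[2])))
            k1 = min(nz - 1, int(np.floor((zb - origin[2]) / s[2])))
            if k0 <= k1:
                mask[i, j, k0:k1 + 1] = True
    if not mask.any():
        raise ValueError("empty mask: no voxel centre inside the mesh")
    return Volume(grid=mask, spacing=tuple(s), origin=tuple(origin))


# ---------------------------------------------------------------------------
# stained transmission volume
# ---------------------------------------------------------------------------

def make_expression_volume(
    mesh: TriMesh, spec: SyntheticSpec, group: str = WILDTYPE
) -> tuple[Volume, dict]:
    """Voxelize a bud and paint a graded dark-stain expression domain.

    The distal rim of the bud receives a stained shell (grey 90) with a
    strongly stained core (grey 30) nested inside it; the rest of the
    tissue sits at grey 150 and the cleared background at 255.  The mutant
    group thickens and extends the shell/core with ``spec.group_effect``.
    Returns the volume and a ground-truth dict (planted voxel counts,
    volumes in µm³ and the tissue mask).
    """
    if group not in (WILDTYPE, MUTANT):
        raise ValueError(f"group must be wildtype|mutant, got {group!r}")
    vox = voxelize(mesh, spec.spacing)
    inside = vox.grid.astype(bool)
    s = np.asarray(vox.spacing)

    depth = ndimage.distance_transform_edt(inside, sampling=s)  # µm to surface
    xc = vox.origin[0] + s[0] * np.arange(inside.shape[0])
    x3 = np.broadcast_to(xc[:, None, None], inside.shape)
    xin = x3[inside]
    distality = np.zeros(inside.shape)
    span = float(xin.max() - xin.min()) or 1.0
    distality[inside] = (x3[inside] - xin.min()) / span

    t_shell, t_core = 60.0, 34.0
    cut_shell, cut_core = 0.70, 0.78
    if group == MUTANT:
        ge = spec.group_effect
        t_shell *= 1.0 + 0.6 * ge
        t_core *= 1.0 + 0.6 * ge
        cut_shell = max(0.4, cut_shell - 0.08 * ge)
        cut_core = max(0.5, cut_core - 0.08 * ge)

    shell = inside & (depth <= t_shell) & (distality >= cut_shell)
    core = inside & (depth <= t_core) & (distality >= cut_core)
    shell &= ~core

    grid = np.full(inside.shape, GREY_AIR)
    grid[inside] = GREY_TISSUE
    grid[shell] = GREY_SHELL
    grid[core] = GREY_CORE
    rng = np.random.default_rng([int(spec.seed), 1])
    if spec.noise_sd > 0:
        grid = np.clip(grid + rng.normal(0.0, spec.noise_sd, grid.shape), 0, 255)

    voxel = float(np.prod(s))
    truth = {
        "core_voxels": int(core.sum()),
        "shell_voxels": int(shell.sum()),
        "core_volume_um3": float(core.sum() * voxel),
        "moderate_volume_um3": float((core.sum() + shell.sum()) * voxel),
        "tissue_mask": inside,
    }
    volume = Volume(grid=grid, spacing=vox.spacing, origin=vox.origin,
                    polarity="dark-stain")
    return volume, truth
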