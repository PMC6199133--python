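"""Gene-expression domain extraction from stained transmission volumes.

The staining precipitate absorbs transmitted light, so an expression domain
appears as a *dark* region inside brighter tissue.  Because expression forms
a fuzzy spatial gradient rather than a crisp object, the domain is defined by
a multiple-thresholding rule:

1. scan a range of grey thresholds; at each threshold ``T`` keep the largest
   26-connected component of ``{grey <= T}`` and record whether it is
   *detectable* (neither vanishingly small nor swallowing the whole tissue);
2. ``G_last`` is the highest detectable threshold — the last grey value at
   which the domain is still visible as a distinct object;
3. the *high*-expression domain is segmented at ``T_high = G_last / 3`` and
   the *moderate* domain at ``T_moderate = 2 * G_last / 3``, so the strongly
   stained core is nested inside the moderate domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .io_formats import BRIGHT_STAIN, TriMesh, Volume

#: 26-connectivity structuring element for 3D component labelling
_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: default detectability bounds of the threshold scan
DEFAULT_V_MIN = 50
DEFAULT_F_MAX = 0.5
DEFAULT_N_LEVELS = 256


@dataclass
class ThresholdScan:
    """Result of scanning grey thresholds over a stained volume."""

    levels: np.ndarray                 # strictly increasing grey levels
    largest_component_voxels: np.ndarray
    n_components: np.ndarray
    detectable: np.ndarray             # bool per level
    v_min: int
    f_max: float
    mask_voxels: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("scan levels must be strictly increasing")
        if np.any(np.asarray(self.largest_component_voxels) < 0):
            raise ValueError("component counts must be >= 0")


@dataclass
class ExpressionDomain:
    """A segmented expression domain: mask, mesh and physical volume."""

    mask: np.ndarray              # boolean, aligned to the source grid
    threshold_used: float
    kind: str                     # "high" | "moderate"
    volume_um3: float
    mesh: TriMesh

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("expression domain mask is empty")
        if self.volume_um3 <= 0:
            raise ValueError("domain volume must be positive")
        _, n = ndimage.label(self.mask, structure=_CONN26)
        if n != 1:
            raise ValueError("domain mask must be a single 26-connected component")


def _dark_grid(volume: Volume) -> np.ndarray:
    """Grey grid in the dark-stain convention (signal = low values)."""
    grid = np.asarray(volume.grid, dtype=float)
    if volume.polarity == BRIGHT_STAIN:
        grid = grid.max() - grid
    return grid


def _largest_component(binary: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Largest 26-connected component: (mask, its voxel count, n components)."""
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n == 0:
        return np.zeros_like(binary, dtype=bool), 0, 0
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    return labels == best, int(counts[best - 1]), int(n)


def threshold_scan(
    volume: Volume,
    mask: np.ndarray | None = None,
    n_levels: int = DEFAULT_N_LEVELS,
    v_min: int = DEFAULT_V_MIN,
    f_max: float = DEFAULT_F_MAX,
) -> ThresholdScan:
    """Scan ``n_levels`` evenly spaced grey thresholds over the (masked) range.

    At each level ``T`` the largest 26-connected component of
    ``{grey <= T}`` (dark-stain convention) within the tissue mask is
    measured; it is *detectable* iff ``v_min <= voxels <= f_max * mask voxels``.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not 0 < f_max <= 1:
        raise ValueError("f_max must lie in (0, 1]")
    grid = _dark_grid(volume)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError("tissue mask shape does not match volume")
    mask_voxels = int(mask.sum())
    if mask_voxels == 0:
        raise ValueError("empty tissue mask")
    vals = grid[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise ValueError("constant volume: no grey range to scan")
    levels = np.linspace(lo, hi, n_levels)
    largest = np.zeros(n_levels, dtype=int)
    ncomp = np.zeros(n_levels, dtype=int)
    for i, level in enumerate(levels):
        _, count, n = _largest_component((grid <= level) & mask)
        largest[i], ncomp[i] = count, n
    detectable = (largest >= v_min) & (largest <= f_max * mask_voxels)
    return ThresholdScan(
        levels=levels, largest_component_voxels=largest, n_components=ncomp,
        detectable=detectable, v_min=int(v_min), f_max=float(f_max),
        mask_voxels=mask_voxels,
    )


def last_visible_grey(scan: ThresholdScan) -> float:
    """Highest scanned threshold at which the domain is still detectable."""
    if not scan.detectable.any():
        raise ValueError("no expression domain detected")
    return float(scan.levels[np.flatnonzero(scan.detectable)[-1]])


def expression_thresholds(g_last: float) -> tuple[float, float]:
    """High/moderate segmentation thresholds, 1/3 and 2/3 of ``G_last``."""
    if g_last <= 0:
        raise ValueError("g_last must be positive")
    return g_last / 3.0, 2.0 * g_last / 3.0


def _component_mesh(
    volume: Volume, grid: np.ndarray, comp: np.ndarray, level: float
) -> TriMesh:
    """Marching-cubes surface of one component at a grey level, in µm."""
    # suppress everything outside the component, then pad with background so
    # components touching the grid border still close
    background = level + max(1.0, abs(level))
    work = np.where(comp, grid, background)
    work = np.pad(work, 1, mode="constant", constant_values=background)
    verts, faces, _, _ = measure.marching_cubes(work, level=level)
    verts = (verts - 1.0) * np.asarray(volume.spacing) + np.asarray(volume.origin)
    mesh = TriMesh(vertices=verts, faces=faces)
    with np.errstate(invalid="ignore", divide="ignore"):
        signed = mesh.to_trimesh().volume
    if signed < 0:
        mesh = TriMesh(vertices=mesh.vertices, faces=mesh.faces[:, ::-1])
    return mesh


def extract_domain(
    volume: Volume,
    threshold: float,
    kind: str = "high",
    v_min: int = DEFAULT_V_MIN,
    mask: np.ndarray | None = None,
) -> ExpressionDomain:
    """Segment the expression domain at a grey threshold.

    The mask is the largest 26-connected component of ``{grey <= threshold}``
    (after polarity normalization); its physical volume is the voxel count
    times the voxel volume and its surface is a marching-cubes isosurface at
    the threshold restricted to the component.
    """
    if kind not in ("high", "moderate"):
        raise ValueError(f"kind must be 'high' or 'moderate', got {kind!r}")
    grid = _dark_grid(volume)
    binary = grid <= threshold
    if mask is not None:
        binary &= np.asarray(mask, dtype=bool)
    comp, count, _ = _largest_component(binary)
    if count < v_min:
        raise ValueError(
            f"no component with >= {v_min} voxels at threshold {threshold}"
        )
    mesh = _component_mesh(volume, grid, comp, threshold)
    return ExpressionDomain(
        mask=comp, threshold_used=float(threshold), kind=kind,
        volume_um3=count * volume.voxel_volume, mesh=mesh,
    )


def isosurface(volume: Volume, level: float, smooth_sigma: float = 1.0) -> TriMesh:
    """Closed marching-cubes isosurface at a grey level, in physical µm.

    ``smooth_sigma`` (voxels) applies a Gaussian pre-smoothing that removes
    the staircase bias of near-binary grids, which would otherwise inflate
    surface area by ~8%; set it to 0 for an unsmoothed surface.  Faces are
    oriented so the enclosed (divergence-theorem) volume is positive.
    """
    grid = np.asarray(volume.grid, dtype=float)
    lo, hi = float(grid.min()), float(grid.max())
    if not lo < level < hi:
        raise ValueError(f"level {level} outside open grey range ({lo}, {hi})")
    if smooth_sigma > 0:
        grid = ndimage.gaussian_filter(grid, smooth_sigma)
    background = hi + 1.0
    work = np.pad(grid, 1, mode="constant", constant_values=background)
    verts, faces, _, _ = measure.marching_cubes(work, level=level)
    verts = (verts - 1.0) * np.asarray(volume.spacing) + np.asarray(volume.origin)
    mesh = TriMesh(vertices=verts, faces=faces)
    with np.errstate(invalid="ignore", divide="ignore"):
        signed = mesh.to_trimesh().volume
    if signed < 0:
        mesh = TriMesh(vertices=mesh.vertices, faces=mesh.faces[:, ::-1])
    return mesh
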