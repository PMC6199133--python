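"""Superimposition, sliding, Procrustes distances and outlier screening."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from optmorph.io_formats import LandmarkSet
from optmorph.procrustes import (
    SlidingTopology,
    centroid_size,
    flag_outliers,
    gpa,
    mirror_configuration,
    procrustes_distance,
    slide_semilandmarks,
    total_bending_energy,
)
from optmorph.warp import bending_energy_matrix


def similarity_copy(rng, config, scale=2.0):
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1e6)))).as_matrix()
    return scale * (config @ R.T) + rng.normal(size=3) * 10


# ---------------------------------------------------------------------------
# centroid size
# ---------------------------------------------------------------------------

def test_centroid_size_unit_square():
    square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
    assert centroid_size(square) == pytest.approx(np.sqrt(2))


def test_centroid_size_homogeneity(rng):
    config = rng.normal(size=(9, 3))
    assert centroid_size(3.0 * config) == pytest.approx(3 * centroid_size(config))
    assert centroid_size(config + 100.0) == pytest.approx(centroid_size(config))


def test_centroid_size_matches_direct_formula(rng):
    config = rng.normal(size=(20, 3)) * 50
    centroid = config.mean(axis=0)
    oracle = np.sqrt(sum(np.sum((p - centroid) ** 2) for p in config))
    assert centroid_size(config) == pytest.approx(oracle, rel=1e-12)
    assert centroid_size(np.array([[1.0, 2.0, 3.0]])) == 0.0


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------

def test_gpa_identical_configurations(rng):
    config = rng.normal(size=(12, 3))
    res = gpa([config, config.copy()])
    assert np.abs(res.aligned[0] - res.aligned[1]).max() < 1e-12
    assert procrustes_distance(res.aligned[0], res.aligned[1]) < 1e-12


def test_gpa_similarity_invariance(rng):
    config = rng.normal(size=(10, 3))
    res = gpa([config, similarity_copy(rng, config)])
    assert np.abs(res.aligned[0] - res.aligned[1]).max() < 1e-9
    # pre-scaling centroid sizes are preserved in µm
    assert res.centroid_sizes[0] == pytest.approx(centroid_size(config))


def test_gpa_invariants(rng):
    configs = [rng.normal(size=(8, 3)) * 30 for _ in range(5)]
    res = gpa(configs)
    assert np.abs(res.consensus.mean(axis=0)).max() < 1e-12
    assert np.sqrt((res.consensus ** 2).sum()) == pytest.approx(1.0)
    for x in res.aligned:
        assert np.sqrt((x ** 2).sum()) == pytest.approx(1.0)
    assert all(np.diff(res.residual_trace) <= 1e-12)


def gpa_oracle(configs, n_iter=500):
    """Independent alternating minimization using scipy's solver."""
    shapes = []
    for c in configs:
        c = c - c.mean(axis=0)
        shapes.append(c / np.sqrt((c ** 2).sum()))
    consensus = shapes[0]
    for _ in range(n_iter):
        rotated = []
        for s in shapes:
            R, _ = orthogonal_procrustes(s, consensus)
            if np.linalg.det(R) < 0:  # enforce proper rotation
                u, sv, vt = np.linalg.svd(s.T @ consensus)
                u[:, -1] *= -1
                R = u @ vt
            rotated.append(s @ R)
        shapes = rotated
        consensus = np.mean(shapes, axis=0)
        consensus -= consensus.mean(axis=0)
        consensus /= np.sqrt((consensus ** 2).sum())
    return consensus


def test_gpa_consensus_matches_oracle(rng):
    configs = [rng.normal(size=(7, 3)) for _ in range(5)]
    res = gpa(configs)
    oracle = gpa_oracle(configs)
    assert procrustes_distance(res.consensus, oracle) < 1e-6


def test_gpa_order_independence(rng):
    configs = [rng.normal(size=(7, 3)) for _ in range(6)]
    a = gpa(configs)
    b = gpa(configs[::-1])
    assert procrustes_distance(a.consensus, b.consensus) < 1e-6


def test_gpa_consensus_is_optimal_reference(rng):
    configs = [rng.normal(size=(8, 3)) for _ in range(6)]
    res = gpa(configs)
    at_consensus = sum(
        procrustes_distance(res.consensus, x) ** 2 for x in res.aligned
    )
    for _ in range(5):
        ref = rng.normal(size=(8, 3))
        other = sum(procrustes_distance(ref, x) ** 2 for x in res.aligned)
        assert at_consensus <= other + 1e-10


def test_gpa_validation(rng):
    with pytest.raises(ValueError):
        gpa([rng.normal(size=(5, 3))])
    with pytest.raises(ValueError):
        gpa([rng.normal(size=(5, 3)), rng.normal(size=(6, 3))])
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear"):
        gpa([line, line + rng.normal(size=(5, 3)) * 0])


# ---------------------------------------------------------------------------
# sliding
# ---------------------------------------------------------------------------

def bent_curve_instance():
    """Anchored 3D configuration with a 5-point curve whose middle point is
    displaced along the curve, plus an equally spaced consensus."""
    anchors = np.array([
        [0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0],
    ])
    t_even = np.linspace(0, 1, 5)
    curve_even = np.column_stack([
        10 * t_even, 3 * np.sin(np.pi * t_even), np.full(5, 2.0),
    ])
    t_off = t_even.copy()
    t_off[2] = 0.62     # middle point pushed along the arc
    curve_off = np.column_stack([
        10 * t_off, 3 * np.sin(np.pi * t_off), np.full(5, 2.0),
    ])
    consensus = np.vstack([anchors, curve_even])
    specimen = np.vstack([anchors, curve_off])
    roles = ["anatomical"] * 4 + ["curve"] * 5
    topo = SlidingTopology(
        roles=roles,
        curve_neighbors={4: (None, 5), 5: (4, 6), 6: (5, 7), 7: (6, 8),
                         8: (7, None)},
    )
    return specimen, consensus, topo


def test_slide_at_consensus_is_identity():
    _, consensus, topo = bent_curve_instance()
    out = slide_semilandmarks([consensus.copy()], consensus, topo)[0]
    assert np.abs(out - consensus).max() < 1e-8


def test_slide_reduces_bending_energy():
    specimen, consensus, topo = bent_curve_instance()
    B = bending_energy_matrix(consensus)
    before = np.einsum("id,ij,jd->", specimen, B, specimen)
    out = slide_semilandmarks([specimen], consensus, topo)[0]
    after = np.einsum("id,ij,jd->", out, B, out)
    assert after < before


def test_slide_never_moves_anatomical_landmarks():
    specimen, consensus, topo = bent_curve_instance()
    out = slide_semilandmarks([specimen], consensus, topo)[0]
    assert np.array_equal(out[:4], specimen[:4])  # bit-identical


def test_gpa_sliding_bending_trace_decreases(rng):
    specimen, consensus, topo = bent_curve_instance()
    configs = [consensus + rng.normal(size=consensus.shape) * 0.3
               for _ in range(6)]
    res = gpa(configs, sliding=topo, slide_iterations=2)
    # within each slide pass the total bending energy does not increase
    pairs = list(zip(res.bending_trace[0::2], res.bending_trace[1::2]))
    assert pairs and all(after <= before + 1e-12 for before, after in pairs)


def test_total_bending_energy_zero_at_consensus():
    _, consensus, topo = bent_curve_instance()
    assert total_bending_energy([consensus], consensus) == pytest.approx(
        0.0, abs=1e-10
    )


# ---------------------------------------------------------------------------
# Procrustes distance
# ---------------------------------------------------------------------------

def test_procrustes_distance_zero_cases(rng):
    a = rng.normal(size=(8, 3))
    assert procrustes_distance(a, a) < 1e-12
    assert procrustes_distance(a, similarity_copy(rng, a)) < 1e-9
    with pytest.raises(ValueError):
        procrustes_distance(a, rng.normal(size=(9, 3)))


def distance_oracle(a, b):
    """Minimize over rotations parameterized by Euler angles."""
    a = a - a.mean(axis=0)
    a /= np.sqrt((a ** 2).sum())
    b = b - b.mean(axis=0)
    b /= np.sqrt((b ** 2).sum())

    def cost(angles):
        R = Rotation.from_euler("xyz", angles).as_matrix()
        br = b @ R.T
        beta = max(np.sum(a * br), 0.0)   # scale is positive in shape space
        return np.sum((a - beta * br) ** 2)

    best = np.inf
    for seed in range(12):
        x0 = np.random.default_rng(seed).uniform(-np.pi, np.pi, 3)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        best = min(best, res.fun)
    return np.sqrt(best)


def test_procrustes_distance_matches_rotation_search(rng):
    a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
    assert procrustes_distance(a, b) == pytest.approx(
        distance_oracle(a, b), abs=1e-3
    )


# ---------------------------------------------------------------------------
# outliers and mirroring
# ---------------------------------------------------------------------------

def test_flag_outliers(rng):
    base = rng.normal(size=(10, 3))
    configs = [base + rng.normal(size=base.shape) * 0.01 for _ in range(9)]
    bad = base + rng.normal(size=base.shape) * 2.0
    sets = [LandmarkSet(specimen_id=f"s{i}", structure="limb", points=c)
            for i, c in enumerate(configs)]
    sets.append(LandmarkSet(specimen_id="outlier", structure="limb", points=bad))
    res = gpa(sets)
    assert flag_outliers(res, "iqr", 1.5) == ["outlier"]
    assert flag_outliers(res, "iqr", np.inf) == []


def test_flag_outliers_identical_specimens(rng):
    base = rng.normal(size=(6, 3))
    res = gpa([base.copy() for _ in range(5)])
    assert flag_outliers(res) == []
    with pytest.raises(ValueError):
        flag_outliers(gpa([base, base.copy()]))


def test_mirror_properties(rng):
    config = rng.normal(size=(9, 3))
    assert np.array_equal(
        mirror_configuration(mirror_configuration(config, "yz"), "yz"), config
    )
    assert centroid_size(mirror_configuration(config, "xy")) == pytest.approx(
        centroid_size(config)
    )
    # a mirrored left configuration superimposes exactly on its right twin
    left = mirror_configuration(config, "xz")
    assert procrustes_distance(config, mirror_configuration(left, "xz")) < 1e-12
    with pytest.raises(ValueError):
        mirror_configuration(config, "ab")
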