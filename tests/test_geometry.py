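"""Point-cloud generation: volumes, containment, uniformity, precedence, PDB."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sasbead import (
    ModelSpec,
    PointModel,
    Subunit,
    build_point_model,
    contains,
    sample_subunit,
    subunit_volume,
    write_pdb,
)
from sasbead.geometry import EmptyModelError, UnsupportedShapeError

ALL_KINDS = [
    ("sphere", (50.0,)),
    ("triaxial_ellipsoid", (30.0, 40.0, 60.0)),
    ("cylinder", (20.0, 360.0)),
    ("disc", (50.0, 10.0)),
    ("cube", (40.0,)),
    ("cuboid", (10.0, 20.0, 30.0)),
    ("hollow_sphere", (50.0, 30.0)),
    ("hollow_cube", (40.0, 20.0)),
    ("cylindrical_ring", (40.0, 20.0, 360.0)),
    ("discoidal_ring", (50.0, 30.0, 10.0)),
]


@pytest.mark.parametrize(
    "kind, dims, expected",
    [
        ("sphere", (50.0,), 4 / 3 * math.pi * 50**3),
        ("hollow_sphere", (50.0, 30.0), 4 / 3 * math.pi * (50**3 - 30**3)),
        ("cylinder", (20.0, 360.0), math.pi * 400 * 360),
        ("disc", (50.0, 10.0), math.pi * 2500 * 10),
        ("cube", (40.0,), 64000.0),
        ("cuboid", (10.0, 20.0, 30.0), 6000.0),
        ("triaxial_ellipsoid", (30.0, 40.0, 60.0), 4 / 3 * math.pi * 30 * 40 * 60),
        ("hollow_cube", (40.0, 20.0), 64000.0 - 8000.0),
        ("cylindrical_ring", (40.0, 20.0, 360.0), math.pi * (1600 - 400) * 360),
    ],
)
def test_subunit_volume_closed_forms(kind, dims, expected):
    assert subunit_volume(Subunit(kind, dims)) == pytest.approx(expected, rel=1e-12)


def test_subunit_validation_errors():
    with pytest.raises(UnsupportedShapeError):
        Subunit("torus", (10.0,))
    with pytest.raises(ValueError, match="dimension"):
        Subunit("sphere", (10.0, 20.0))
    with pytest.raises(ValueError, match="> 0"):
        Subunit("cylinder", (-5.0, 10.0))
    with pytest.raises(ValueError, match="inner"):
        Subunit("hollow_sphere", (30.0, 50.0))
    with pytest.raises(ValueError):
        ModelSpec(subunits=(), n_points_total=3000)
    with pytest.raises(ValueError):
        ModelSpec(subunits=(Subunit("sphere", (10.0,)),), n_points_total=50)


@pytest.mark.parametrize(
    "su, point, expected",
    [
        (Subunit("sphere", (50.0,)), (0.0, 0.0, 50.0), True),  # boundary inclusive
        (Subunit("sphere", (50.0,)), (0.0, 0.0, 50.001), False),
        (Subunit("hollow_sphere", (50.0, 30.0)), (0.0, 0.0, 10.0), False),  # cavity
        (Subunit("hollow_sphere", (50.0, 30.0)), (0.0, 0.0, 40.0), True),
        (Subunit("cuboid", (10.0, 20.0, 30.0), com=(100.0, 0.0, 0.0)), (104.0, 9.0, -14.0), True),
        (Subunit("cuboid", (10.0, 20.0, 30.0), com=(100.0, 0.0, 0.0)), (106.0, 0.0, 0.0), False),
        (Subunit("cylinder", (20.0, 400.0)), (0.0, 19.0, 199.0), True),
        (Subunit("cylinder", (20.0, 400.0)), (0.0, 19.0, 201.0), False),
    ],
)
def test_contains(su, point, expected):
    assert contains(su, np.array(point)) is expected


@pytest.mark.parametrize("kind, dims", ALL_KINDS)
def test_sampled_points_are_contained(kind, dims):
    su = Subunit(kind, dims, com=(10.0, -5.0, 3.0))
    pts = sample_subunit(su, 500, np.random.default_rng(3))
    assert pts.shape == (500, 3)
    assert contains(su, pts).all()


_BASE_DIMS = dict(ALL_KINDS)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    kind=st.sampled_from(sorted(_BASE_DIMS)),
    scale=st.floats(0.2, 5.0),
    com=st.tuples(*[st.floats(-100.0, 100.0)] * 3),
    seed=st.integers(0, 2**31 - 1),
)
def test_sampling_containment_property(kind, scale, com, seed):
    """For any subunit geometry, size and placement, every sampled point lies
    inside the subunit and the analytic volume is positive."""
    su = Subunit(kind, tuple(d * scale for d in _BASE_DIMS[kind]), com=com)
    assert subunit_volume(su) > 0
    pts = sample_subunit(su, 64, np.random.default_rng(seed))
    assert contains(su, pts).all()


def test_sphere_mean_radial_coordinate():
    """Uniform ball: E[r] = 3R/4 exactly; check against the sample mean."""
    n, radius = 100_000, 50.0
    pts = sample_subunit(Subunit("sphere", (radius,)), n, np.random.default_rng(5))
    r = np.linalg.norm(pts, axis=1)
    se = np.sqrt(3.0 / 80.0) * radius / np.sqrt(n)  # sd of r is sqrt(3/80)·R
    assert abs(r.mean() - 0.75 * radius) < 4 * se


def test_octant_uniformity():
    """Counts per octant of a sampled sphere pass a chi-square test at α=0.01."""
    pts = sample_subunit(Subunit("sphere", (50.0,)), 10_000, np.random.default_rng(11))
    octant = (pts[:, 0] > 0) * 4 + (pts[:, 1] > 0) * 2 + (pts[:, 2] > 0)
    counts = np.bincount(octant, minlength=8)
    assert stats.chisquare(counts).pvalue > 0.01


def test_monte_carlo_volume_check():
    """Acceptance fraction in the bounding box recovers the analytic volume."""
    su = Subunit("triaxial_ellipsoid", (30.0, 40.0, 60.0))
    half = np.array([30.0, 40.0, 60.0])
    n = 50_000
    rng = np.random.default_rng(7)
    box = rng.uniform(-half, half, size=(n, 3))
    inside = contains(su, box)
    p_hat = inside.mean()
    box_volume = np.prod(2 * half)
    sigma = np.sqrt(p_hat * (1 - p_hat) / n) * box_volume
    assert abs(p_hat * box_volume - subunit_volume(su)) < 3 * sigma


def test_single_sphere_allocation_and_weights():
    spec = ModelSpec(subunits=(Subunit("sphere", (50.0,), 2.0),), n_points_total=3000)
    model = build_point_model(spec, np.random.default_rng(0))
    assert model.n_points == 3000
    v_eff = subunit_volume(spec.subunits[0]) / 3000
    assert model.effective_volume == pytest.approx(v_eff)
    assert np.allclose(model.weights, 2.0 * v_eff)
    assert model.total_volume == pytest.approx(subunit_volume(spec.subunits[0]))


def test_proportional_allocation_disjoint_spheres():
    """Two disjoint spheres with volume ratio 8:1 get points in that ratio."""
    spec = ModelSpec(
        subunits=(
            Subunit("sphere", (50.0,), com=(-100.0, 0.0, 0.0)),
            Subunit("sphere", (25.0,), com=(100.0, 0.0, 0.0)),
        ),
        n_points_total=3000,
    )
    model = build_point_model(spec, np.random.default_rng(0))
    counts = np.bincount(model.subunit_index)
    assert model.n_points == 3000  # largest-remainder totals are exact
    assert counts[0] / counts[1] == pytest.approx(8.0, rel=0.01)


def test_core_shell_precedence():
    """A 30 Å sphere (ΔSLD −1) before a 50 Å sphere (+1) gives a core–shell
    particle: all points inside 30 Å carry the core contrast."""
    spec = ModelSpec(
        subunits=(
            Subunit("sphere", (30.0,), -1.0),
            Subunit("sphere", (50.0,), +1.0),
        ),
        n_points_total=3000,
        exclude_overlap=True,
    )
    model = build_point_model(spec, np.random.default_rng(1))
    r = np.linalg.norm(model.coords, axis=1)
    v = model.effective_volume
    assert np.allclose(model.weights[r <= 30.0], -v)
    assert np.allclose(model.weights[r > 30.0], +v)
    # deleted shell points shrink the covered volume to that of the 50 Å ball
    assert model.total_volume == pytest.approx(4 / 3 * math.pi * 50**3, rel=0.05)


def test_point_density_constant_across_subunits():
    spec = ModelSpec(
        subunits=(
            Subunit("cylinder", (20.0, 100.0), com=(-100.0, 0.0, 0.0)),
            Subunit("cube", (40.0,), com=(100.0, 0.0, 0.0)),
        ),
        n_points_total=4000,
    )
    model = build_point_model(spec, np.random.default_rng(2))
    counts = np.bincount(model.subunit_index)
    for i, su in enumerate(spec.subunits):
        density = counts[i] / subunit_volume(su)
        assert density == pytest.approx(4000 / model.total_volume, rel=0.01)


def test_build_is_reproducible():
    spec = ModelSpec(subunits=(Subunit("sphere", (50.0,)),), n_points_total=500)
    a = build_point_model(spec, np.random.default_rng(42))
    b = build_point_model(spec, np.random.default_rng(42))
    assert np.array_equal(a.coords, b.coords)
    assert np.array_equal(a.weights, b.weights)


def _manual_model(coords: np.ndarray) -> PointModel:
    return PointModel(
        coords=coords,
        weights=np.ones(len(coords)),
        effective_volume=1.0,
        total_volume=float(len(coords)),
    )


def test_write_pdb_roundtrip(tmp_path):
    coords = np.array([[1.234, -5.678, 9.012], [0.0, 0.0, 0.0], [-3.1, 2.2, 100.456]])
    path = tmp_path / "model.pdb"
    write_pdb(_manual_model(coords), path)
    lines = [l for l in path.read_text().splitlines() if l.startswith("ATOM")]
    assert len(lines) == 3
    parsed = np.array(
        [[float(l[30:38]), float(l[38:46]), float(l[46:54])] for l in lines]
    )
    assert np.allclose(parsed, coords, atol=5e-4)  # PDB stores 3 decimals

    import gemmi  # independent reader

    st = gemmi.read_structure(str(path))
    atoms = [a.pos for model in st for chain in model for res in chain for a in res]
    assert len(atoms) == 3
    assert np.allclose([[p.x, p.y, p.z] for p in atoms], coords, atol=5e-4)


def test_write_pdb_errors(tmp_path):
    with pytest.raises(EmptyModelError):
        write_pdb(_manual_model(np.empty((0, 3))), tmp_path / "empty.pdb")
    with pytest.raises(ValueError, match="99999"):
        write_pdb(_manual_model(np.zeros((100_000, 3))), tmp_path / "big.pdb")
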