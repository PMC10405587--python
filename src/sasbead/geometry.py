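"""Point-cloud construction for particles built from geometric subunits.

A particle is described as an ordered list of geometric subunits (spheres,
cylinders, rings, ...), each with dimensions in Å, an excess scattering-length
density (contrast relative to the solvent, unitless) and a center-of-mass
displacement.  The particle is represented as a "bead model": a cloud of point
scatterers filled uniformly into the subunit volumes at a constant point
density, so that every point carries the same effective volume
``V = V_p / N`` and the excess scattering length of point *j* is
``Δb_j = ΔSLD_i · V`` for its owning subunit *i*.

Overlaps between subunits are resolved by list precedence: points of a later
subunit that fall inside an earlier one are deleted (not resampled), which
lets multi-contrast particles such as core–shell bodies be assembled from
overlapping primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SUBUNIT_KINDS",
    "DIM_NAMES",
    "Subunit",
    "ModelSpec",
    "PointModel",
    "subunit_volume",
    "contains",
    "sample_subunit",
    "build_point_model",
    "write_pdb",
]

# dims arity and meaning per kind; order is the order expected in `dims`
DIM_NAMES: dict[str, tuple[str, ...]] = {
    "sphere": ("R",),
    "triaxial_ellipsoid": ("a", "b", "c"),
    "cylinder": ("R", "L"),
    "disc": ("R", "L"),
    "cube": ("a",),
    "cuboid": ("a", "b", "c"),
    "hollow_sphere": ("R_out", "R_in"),
    "hollow_cube": ("a_out", "a_in"),
    "cylindrical_ring": ("R_out", "R_in", "L"),
    "discoidal_ring": ("R_out", "R_in", "L"),
}

SUBUNIT_KINDS = tuple(DIM_NAMES)

# kinds whose first two dims are (outer, inner) and must satisfy inner < outer
_HOLLOW_KINDS = frozenset(
    {"hollow_sphere", "hollow_cube", "cylindrical_ring", "discoidal_ring"}
)


class UnsupportedShapeError(ValueError):
    """Raised for an unknown subunit kind."""


class EmptyModelError(ValueError):
    """Raised when overlap exclusion deletes every point of a model."""


@dataclass(frozen=True)
class Subunit:
    """One geometric primitive of a particle.

    Parameters
    ----------
    kind:
        One of `SUBUNIT_KINDS`.
    dims:
        Positive lengths in Å; arity and order per kind as in `DIM_NAMES`
        (e.g. sphere: ``(R,)``; cylindrical ring: ``(R_out, R_in, L)``).
    delta_sld:
        Excess scattering-length density ΔSLD (unitless contrast relative to
        the solvent).  May be negative.
    com:
        Center-of-mass displacement in Å.
    """

    kind: str
    dims: tuple[float, ...]
    delta_sld: float = 1.0
    com: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in DIM_NAMES:
            raise UnsupportedShapeError(f"unknown subunit kind: {self.kind!r}")
        object.__setattr__(self, "dims", tuple(float(d) for d in self.dims))
        object.__setattr__(self, "com", tuple(float(c) for c in self.com))
        names = DIM_NAMES[self.kind]
        if len(self.dims) != len(names):
            raise ValueError(
                f"{self.kind} takes {len(names)} dimension(s) "
                f"{names}, got {len(self.dims)}"
            )
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"{self.kind}: all dimensions must be > 0, got {self.dims}")
        if len(self.com) != 3:
            raise ValueError("com must be a 3-vector")
        if self.kind in _HOLLOW_KINDS and self.dims[1] >= self.dims[0]:
            raise ValueError(
                f"{self.kind}: inner dimension must be smaller than outer, got {self.dims}"
            )


@dataclass(frozen=True)
class ModelSpec:
    """A full particle: ordered subunits (order = overlap precedence)."""

    subunits: tuple[Subunit, ...]
    exclude_overlap: bool = True
    n_points_total: int = 3000

    def __post_init__(self) -> None:
        object.__setattr__(self, "subunits", tuple(self.subunits))
        if len(self.subunits) < 1:
            raise ValueError("a model needs at least one subunit")
        if self.n_points_total < 100:
            raise ValueError("n_points_total must be >= 100")


@dataclass
class PointModel:
    """Weighted point cloud of a whole particle.

    ``weights[j]`` is the excess scattering length Δb_j = ΔSLD · V of point j,
    with V = total_volume / N the effective volume of one scatterer (constant
    across subunits because the point density is constant).
    """

    coords: np.ndarray  # (N_kept, 3), Å
    weights: np.ndarray  # (N_kept,), excess scattering lengths
    effective_volume: float  # V = ΣV_i / N_allocated, Å³
    total_volume: float  # V_p = V · N_kept, the volume the particle occupies, Å³
    subunit_index: np.ndarray = field(default=None)  # owning subunit per point

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


def subunit_volume(su: Subunit) -> float:
    """Exact analytic volume of a subunit in Å³ (hollow kinds: outer − inner)."""
    d = su.dims
    if su.kind == "sphere":
        return 4.0 / 3.0 * math.pi * d[0] ** 3
    if su.kind == "triaxial_ellipsoid":
        return 4.0 / 3.0 * math.pi * d[0] * d[1] * d[2]
    if su.kind in ("cylinder", "disc"):
        return math.pi * d[0] ** 2 * d[1]
    if su.kind == "cube":
        return d[0] ** 3
    if su.kind == "cuboid":
        return d[0] * d[1] * d[2]
    if su.kind == "hollow_sphere":
        return 4.0 / 3.0 * math.pi * (d[0] ** 3 - d[1] ** 3)
    if su.kind == "hollow_cube":
        return d[0] ** 3 - d[1] ** 3
    if su.kind in ("cylindrical_ring", "discoidal_ring"):
        return math.pi * (d[0] ** 2 - d[1] ** 2) * d[2]
    raise UnsupportedShapeError(f"unknown subunit kind: {su.kind!r}")


def _contains_local(su: Subunit, pts: np.ndarray) -> np.ndarray:
    """Vectorized containment test in the subunit's own (un-shifted) frame."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    d = su.dims
    if su.kind == "sphere":
        return x * x + y * y + z * z <= d[0] ** 2
    if su.kind == "triaxial_ellipsoid":
        a, b, c = d
        return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    if su.kind in ("cylinder", "disc"):
        r, length = d
        return (x * x + y * y <= r * r) & (np.abs(z) <= length / 2.0)
    if su.kind == "cube":
        h = d[0] / 2.0
        return (np.abs(x) <= h) & (np.abs(y) <= h) & (np.abs(z) <= h)
    if su.kind == "cuboid":
        return (
            (np.abs(x) <= d[0] / 2.0)
            & (np.abs(y) <= d[1] / 2.0)
            & (np.abs(z) <= d[2] / 2.0)
        )
    if su.kind == "hollow_sphere":
        r2 = x * x + y * y + z * z
        return (r2 <= d[0] ** 2) & (r2 >= d[1] ** 2)
    if su.kind == "hollow_cube":
        h_out, h_in = d[0] / 2.0, d[1] / 2.0
        m = np.maximum(np.maximum(np.abs(x), np.abs(y)), np.abs(z))
        return (m <= h_out) & (m >= h_in)
    if su.kind in ("cylindrical_ring", "discoidal_ring"):
        r_out, r_in, length = d
        r2 = x * x + y * y
        return (r2 <= r_out**2) & (r2 >= r_in**2) & (np.abs(z) <= length / 2.0)
    raise UnsupportedShapeError(f"unknown subunit kind: {su.kind!r}")


def contains(su: Subunit, points: np.ndarray) -> np.ndarray | bool:
    """True where a point (global frame, Å) lies inside the subunit.

    Boundary points count as inside.  Accepts a single 3-vector or an
    (n, 3) array; returns a bool or a boolean array accordingly.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inside = _contains_local(su, pts - np.asarray(su.com, dtype=float))
    if np.ndim(points) == 1:
        return bool(inside[0])
    return inside


def _bounding_half_extents(su: Subunit) -> np.ndarray:
    """Half-extents of the axis-aligned bounding box in the local frame."""
    d = su.dims
    if su.kind == "sphere":
        return np.array([d[0]] * 3)
    if su.kind == "triaxial_ellipsoid":
        return np.array(d)
    if su.kind in ("cylinder", "disc"):
        return np.array([d[0], d[0], d[1] / 2.0])
    if su.kind == "cube":
        return np.array([d[0] / 2.0] * 3)
    if su.kind == "cuboid":
        return np.array(d) / 2.0
    if su.kind == "hollow_sphere":
        return np.array([d[0]] * 3)
    if su.kind == "hollow_cube":
        return np.array([d[0] / 2.0] * 3)
    if su.kind in ("cylindrical_ring", "discoidal_ring"):
        return np.array([d[0], d[0], d[2] / 2.0])
    raise UnsupportedShapeError(f"unknown subunit kind: {su.kind!r}")


def sample_subunit(su: Subunit, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` uniform points from the subunit volume (global frame, Å).

    Rejection sampling from the axis-aligned bounding box: exactly uniform
    for every supported shape.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    half = _bounding_half_extents(su)
    box_volume = float(np.prod(2.0 * half))
    accept_rate = subunit_volume(su) / box_volume
    out = np.empty((n, 3), dtype=float)
    filled = 0
    while filled < n:
        # oversample by the expected rejection rate plus margin
        n_draw = max(int((n - filled) / max(accept_rate, 1e-3) * 1.2), 64)
        cand = rng.uniform(-half, half, size=(n_draw, 3))
        keep = cand[_contains_local(su, cand)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out + np.asarray(su.com, dtype=float)


def _allocate_counts(n_total: int, volumes: np.ndarray) -> np.ndarray:
    """Split ``n_total`` points over subunits ∝ volume (largest remainder)."""
    quota = n_total * volumes / volumes.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n_total - counts.sum()
    for i in np.argsort(remainder)[::-1][:short]:
        counts[i] += 1
    return counts


def build_point_model(spec: ModelSpec, rng: np.random.Generator) -> PointModel:
    """Assemble the weighted point cloud of a particle.

    Points are allocated to subunits proportionally to their analytic volumes
    so the point density is constant; the effective volume per point is
    ``V = ΣV_i / N`` (computed before any overlap deletion, so surviving
    points keep their correct per-point volume).  With ``exclude_overlap``,
    points of subunit *j* falling inside any earlier subunit *i < j* are
    deleted, so earlier subunits take precedence in overlap regions.
    """
    volumes = np.array([subunit_volume(su) for su in spec.subunits])
    total_volume = float(volumes.sum())
    counts = _allocate_counts(spec.n_points_total, volumes)
    effective_volume = total_volume / spec.n_points_total

    coords_parts: list[np.ndarray] = []
    weights_parts: list[np.ndarray] = []
    owner_parts: list[np.ndarray] = []
    for i, (su, n_i) in enumerate(zip(spec.subunits, counts)):
        if n_i == 0:
            continue
        pts = sample_subunit(su, int(n_i), rng)
        if spec.exclude_overlap:
            keep = np.ones(len(pts), dtype=bool)
            for earlier in spec.subunits[:i]:
                keep &= ~contains(earlier, pts)
            pts = pts[keep]
        coords_parts.append(pts)
        weights_parts.append(np.full(len(pts), su.delta_sld * effective_volume))
        owner_parts.append(np.full(len(pts), i, dtype=int))

    if not coords_parts or sum(len(p) for p in coords_parts) == 0:
        raise EmptyModelError("overlap exclusion removed all points of the model")

    coords = np.concatenate(coords_parts)
    # particle volume V_p: each retained point stands for one effective
    # volume, so deletion of overlap points shrinks V_p from ΣV_i to the
    # volume of the union actually covered
    return PointModel(
        coords=coords,
        weights=np.concatenate(weights_parts),
        effective_volume=effective_volume,
        total_volume=effective_volume * len(coords),
        subunit_index=np.concatenate(owner_parts),
    )


def write_pdb(model: PointModel, path, comment: str | None = None) -> None:
    """Write the point model as pseudo-atoms in PDB format.

    One carbon ``ATOM`` record per point, coordinates in Å in the standard
    fixed columns (x/y/z in columns 31–54, %8.3f each), occupancy 1.00 and
    B-factor 0.00.  The fixed-width serial field limits models to 99 999
    points.
    """
    if model.n_points == 0:
        raise EmptyModelError("cannot write an empty model")
    if model.n_points > 99999:
        raise ValueError(
            f"PDB serial numbers overflow at 99999 atoms (model has {model.n_points})"
        )
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"REMARK   1 {line}\n")
        for serial, (x, y, z) in enumerate(model.coords, start=1):
            fh.write(
                f"ATOM  {serial:5d}  C   DUM A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
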