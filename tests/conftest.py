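"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's binned/histogram code
paths: direct O(N²) Debye sums over explicit pair lists, closed-form p(r)
and R_g for spheres, and analytic subunit volumes, so that tests compare two
independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from sasbead import ModelSpec, PointModel, Subunit, build_point_model


def pair_weight_products(weights: np.ndarray) -> np.ndarray:
    """Condensed (pdist-ordered) products w_j·w_k over unordered pairs j<k."""
    return np.concatenate(
        [weights[i] * weights[i + 1 :] for i in range(len(weights) - 1)]
    )


def debye_direct(coords: np.ndarray, weights: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Direct, unbinned Debye sum over all unordered pairs (self terms excluded),
    normalized to 1 at q→0.  The O(N²) oracle for the histogram path."""
    d = pdist(coords)
    w = pair_weight_products(weights)
    return np.sinc(np.outer(q, d) / np.pi) @ w / w.sum()


def sphere_pr_analytic(r: np.ndarray, radius: float) -> np.ndarray:
    """Pair distance distribution of a uniform solid sphere, normalized to max 1."""
    x = np.clip(r / (2.0 * radius), 0.0, 1.0)
    p = r**2 * (1.0 - 1.5 * x + 0.5 * x**3)
    return p / p.max()


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Exact normalized sphere intensity [3(sin x − x cos x)/x³]², x = qR."""
    x = q * radius
    return (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2


def single_subunit_model(
    kind: str, dims, n_points: int, seed: int, delta_sld: float = 1.0
) -> PointModel:
    spec = ModelSpec(
        subunits=(Subunit(kind, tuple(dims), delta_sld),), n_points_total=n_points
    )
    return build_point_model(spec, np.random.default_rng(seed))


def two_point_model(distance: float, w1: float = 1.0, w2: float = 1.0) -> PointModel:
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, distance]])
    return PointModel(
        coords=coords,
        weights=np.array([w1, w2]),
        effective_volume=1.0,
        total_volume=2.0,
    )


@pytest.fixture(scope="session")
def sphere_5000() -> PointModel:
    """A 50 Å sphere sampled with 5000 points (shared; read-only)."""
    return single_subunit_model("sphere", (50.0,), 5000, seed=2024)
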