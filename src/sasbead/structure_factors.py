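"""Interparticle structure factors and the decoupling approximation.

At finite concentration the measured intensity of interacting particles is
modulated by a structure factor S(q).  For non-spherical (or multi-contrast)
particles the spherical S(q) is applied through the decoupling approximation,

    I(q) = P(q) · [1 + β(q) (S(q) − 1)],   β(q) = ⟨F(q)⟩² / ⟨|F(q)|²⟩,

where ⟨F⟩ is the orientation-averaged scattering amplitude of the particle.
Two structure factors are provided: the Percus–Yevick hard-sphere solution
(interparticle repulsion) and a fractal aggregate model with fractal
dimension 2 (particle aggregation).  Structure factors modify I(q) only;
the pair distance distribution always describes non-interacting particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .debye import PairDistanceHistogram, ScatteringCurve, _sinc
from .geometry import PointModel

__all__ = [
    "HardSphereParams",
    "FractalParams",
    "hard_sphere_sq",
    "fractal_sq",
    "decoupling_beta",
    "apply_structure_factor",
]

# close packing bound for the PY volume fraction
_ETA_MAX = 0.74

# numerical floor on the effective structure factor, guards against negative
# intensities from noise in beta near form-factor zeros
_S_EFF_FLOOR = 1e-6


@dataclass(frozen=True)
class HardSphereParams:
    """Percus–Yevick hard spheres: interaction radius (Å) and volume fraction."""

    r_hs: float
    eta: float

    def __post_init__(self) -> None:
        if self.r_hs <= 0:
            raise ValueError("r_hs must be > 0")
        if not 0.0 < self.eta < _ETA_MAX:
            raise ValueError(f"eta must be in (0, {_ETA_MAX})")


@dataclass(frozen=True)
class FractalParams:
    """Aggregation model: fraction aggregated, mean aggregation number, per-particle radius (Å)."""

    frac_aggregated: float
    n_agg: float
    r_eff: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_aggregated <= 1.0:
            raise ValueError("frac_aggregated must be in [0, 1]")
        if self.n_agg < 1:
            raise ValueError("n_agg must be >= 1")
        if self.r_eff <= 0:
            raise ValueError("r_eff must be > 0")


def hard_sphere_sq(q: np.ndarray, p: HardSphereParams) -> np.ndarray:
    """Percus–Yevick hard-sphere structure factor.

    S(q) = 1 / (1 + 24η G(A)/A) with A = 2 q R_hs and G the standard PY
    polynomial in sin A, cos A with coefficients
    α = (1+2η)²/(1−η)⁴, β = −6η(1+η/2)²/(1−η)⁴, γ = ηα/2.
    The q→0 limit is the PY compressibility, (1−η)⁴/(1+2η)².
    """
    q = np.asarray(q, dtype=float)
    eta = p.eta
    alpha = (1.0 + 2.0 * eta) ** 2 / (1.0 - eta) ** 4
    beta = -6.0 * eta * (1.0 + eta / 2.0) ** 2 / (1.0 - eta) ** 4
    gamma = eta * alpha / 2.0

    a = 2.0 * q * p.r_hs
    small = a < 1e-3
    a_safe = np.where(small, 1.0, a)
    sin_a, cos_a = np.sin(a_safe), np.cos(a_safe)
    g = (
        alpha * (sin_a - a_safe * cos_a) / a_safe**2
        + beta * (2.0 * a_safe * sin_a + (2.0 - a_safe**2) * cos_a - 2.0) / a_safe**3
        + gamma
        * (
            -(a_safe**4) * cos_a
            + 4.0 * ((3.0 * a_safe**2 - 6.0) * cos_a + (a_safe**3 - 6.0 * a_safe) * sin_a + 6.0)
        )
        / a_safe**5
    )
    # series limit A→0: G/A → α/3 + β/4 + γ/6, giving the compressibility limit
    g_over_a = np.where(small, alpha / 3.0 + beta / 4.0 + gamma / 6.0, g / a_safe)
    return 1.0 / (1.0 + 24.0 * eta * g_over_a)


def fractal_sq(q: np.ndarray, p: FractalParams) -> np.ndarray:
    """Structure factor of fractal aggregates with fractal dimension 2.

    A flat (two-dimensional) aggregate of n_agg particles of effective radius
    r_eff has

        S_agg(q) = 1 + (n_agg − 1) / (1 + (q r_eff)² n_agg / 3),

    which goes to n_agg at q → 0 and to 1 at large q.  A fraction
    ``frac_aggregated`` of the particles sits in aggregates, the rest are
    free (S = 1); the two populations mix linearly.
    """
    q = np.asarray(q, dtype=float)
    qr = q * p.r_eff
    s_agg = 1.0 + (p.n_agg - 1.0) / (1.0 + qr**2 * p.n_agg / 3.0)
    return 1.0 + p.frac_aggregated * (s_agg - 1.0)


def decoupling_beta(
    model: PointModel,
    q: np.ndarray,
    hist: PairDistanceHistogram | None = None,
) -> np.ndarray:
    """β(q) = ⟨F(q)⟩² / ⟨|F(q)|²⟩ for the decoupling approximation.

    The orientation-averaged amplitude is ⟨F(q)⟩ = Σ_j Δb_j sinc(q r_j) with
    r_j the distance of point j from the particle's scattering-weighted
    center (|Δb| weights).  ⟨|F|²⟩ is the unnormalized Debye intensity of the
    same point model, self terms included; passing a precomputed pair
    histogram avoids recomputing it.  β is clipped to [0, 1]; β(q→0) = 1,
    and β ≡ 1 for centrosymmetric (e.g. spherical) particles.
    """
    from .debye import pair_histogram  # deferred: debye imports nothing from here

    q = np.asarray(q, dtype=float)
    w = np.asarray(model.weights, dtype=float)
    net = w.sum()
    if net == 0:
        raise ValueError("zero net contrast; decoupling amplitude is undefined")
    center = (np.abs(w)[:, None] * model.coords).sum(axis=0) / np.abs(w).sum()
    r_j = np.linalg.norm(model.coords - center, axis=1)
    f_mean = _sinc(np.outer(q, r_j)) @ w

    if hist is None:
        hist = pair_histogram(model)
    # ⟨F²⟩ = 2 Σ_pairs Δb_jΔb_k sinc(q r_jk) + Σ_j Δb_j²  (self terms restored)
    f_sq = 2.0 * (_sinc(np.outer(q, hist.r_centers)) @ hist.p_values) + hist.sum_weight_sq
    beta = f_mean**2 / np.where(f_sq <= 0, np.inf, f_sq)
    return np.clip(beta, 0.0, 1.0)


def apply_structure_factor(
    curve: ScatteringCurve, sq: np.ndarray, beta: np.ndarray | None = None
) -> tuple[ScatteringCurve, np.ndarray]:
    """Multiply a normalized intensity by a (decoupled) structure factor.

    Returns the modulated curve and the effective structure factor
    S_eff(q) = 1 + β(q)(S(q) − 1) actually applied (β ≡ 1 if not given).
    p(r) is never touched by structure factors.
    """
    sq = np.asarray(sq, dtype=float)
    if sq.shape != curve.q.shape:
        raise ValueError("structure factor grid does not match the curve's q grid")
    if beta is None:
        beta = np.ones_like(sq)
    else:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != curve.q.shape:
            raise ValueError("beta grid does not match the curve's q grid")
    s_eff = np.maximum(1.0 + beta * (sq - 1.0), _S_EFF_FLOOR)
    return ScatteringCurve(q=curve.q, intensity=curve.intensity * s_eff), s_eff
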