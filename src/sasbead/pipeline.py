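"""End-to-end simulation of one particle model.

Chains the full computation: point cloud → pair-distance histogram → p(r),
R_g, D_max → normalized intensity (with optional size polydispersity) →
structure factor via the decoupling approximation → interface roughness →
experimental scale and noise → stochastic virtual data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .debye import (
    PairDistanceHistogram,
    PolydispersitySpec,
    ScatteringCurve,
    intensity_from_histogram,
    p_of_r,
    pair_histogram,
    polydisperse_intensity,
    radius_of_gyration,
)
from .experiment import (
    ExperimentParams,
    SimulatedDataset,
    apply_roughness,
    forward_scattering,
    sample_dataset,
    simulate_errors,
)
from .geometry import ModelSpec, PointModel, build_point_model
from .structure_factors import (
    FractalParams,
    HardSphereParams,
    apply_structure_factor,
    decoupling_beta,
    fractal_sq,
    hard_sphere_sq,
)

__all__ = ["ModelResult", "simulate_model"]


@dataclass
class ModelResult:
    """Everything computed for one model in a run."""

    model: PointModel
    hist: PairDistanceHistogram
    pr: np.ndarray  # (M+1, 2) table (r, p), max 1, leading (0, 0)
    curve: ScatteringCurve  # normalized I(q) incl. polydispersity, SF, roughness
    s_eff: np.ndarray | None  # effective structure factor, None if no SF
    i0: float  # forward scattering, a.u.
    i_scaled: np.ndarray  # I(0) · I_norm(q)
    sigma: np.ndarray  # σ_sim(q)
    dataset: SimulatedDataset
    rg: float  # Å
    d_max: float  # Å


def simulate_model(
    spec: ModelSpec,
    q: np.ndarray,
    rng: np.random.Generator,
    pd: PolydispersitySpec | None = None,
    structure_factor: HardSphereParams | FractalParams | None = None,
    experiment: ExperimentParams | None = None,
    n_bins: int = 200,
) -> ModelResult:
    """Run the full virtual experiment for one particle model.

    The returned p(r) is always that of free, non-interacting particles;
    structure factor and roughness modify only I(q).
    """
    if pd is None:
        pd = PolydispersitySpec()
    if experiment is None:
        experiment = ExperimentParams()
    q = np.asarray(q, dtype=float)

    model = build_point_model(spec, rng)
    hist = pair_histogram(model, n_bins=n_bins)

    if pd.sigma_s > 0:
        curve, pr = polydisperse_intensity(hist, q, pd)
    else:
        curve = intensity_from_histogram(hist, q)
        pr = p_of_r(hist)

    s_eff = None
    if structure_factor is not None:
        if isinstance(structure_factor, HardSphereParams):
            sq = hard_sphere_sq(q, structure_factor)
        elif isinstance(structure_factor, FractalParams):
            sq = fractal_sq(q, structure_factor)
        else:
            raise TypeError(f"unknown structure factor type: {type(structure_factor)!r}")
        beta = decoupling_beta(model, q, hist=hist)
        curve, s_eff = apply_structure_factor(curve, sq, beta)

    curve = apply_roughness(curve, experiment.sigma_rough)

    i0 = forward_scattering(model, experiment)
    i_scaled = i0 * curve.intensity
    sigma = simulate_errors(q, i_scaled, experiment)
    dataset = sample_dataset(q, i_scaled, sigma, rng)

    return ModelResult(
        model=model,
        hist=hist,
        pr=pr,
        curve=curve,
        s_eff=s_eff,
        i0=i0,
        i_scaled=i_scaled,
        sigma=sigma,
        dataset=dataset,
        rg=radius_of_gyration(hist),
        d_max=hist.d_max,
    )
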