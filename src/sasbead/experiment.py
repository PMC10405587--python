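"""Virtual SAXS experiment: roughness, forward scattering, noise, sampling.

The normalized intensity is turned into realistic synthetic data in four
steps.  (1) Interface roughness: sharp subunit boundaries are smeared by a
multiplicative factor exp(−(q σ_rough)²) on the intensity.  (2) Forward
scattering: the curve is put on an arbitrary-unit experimental scale
I(0) = η (Σ_j Δb_j)² / V_p, linear in the volume fraction η and quadratic in
contrast — for a uniform particle this reduces to η Δρ² V_p.  (3) An
empirical SAXS error model assigns a standard deviation to every point,

    σ²(q) = (I(q) + c) / (k · q · t),

with t the relative exposure time (t = 1 resembles a typical synchrotron
exposure; divide by ~10 for a laboratory source) and calibration constants
c, k in the same arbitrary intensity units.  (4) The data are drawn from
independent normal distributions, I_sim(q) ~ N(I(q), σ(q)²); negative draws
are kept, as in real background-subtracted data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .debye import ScatteringCurve
from .geometry import PointModel

__all__ = [
    "ExperimentParams",
    "SimulatedDataset",
    "apply_roughness",
    "forward_scattering",
    "simulate_errors",
    "sample_dataset",
    "write_dat",
    "read_dat",
]


@dataclass(frozen=True)
class ExperimentParams:
    """Conditions of the virtual experiment.

    eta:
        Volume fraction of particles (sample concentration proxy); default
        0.01, a typical dilute biological SAXS sample.
    exposure:
        Relative exposure time; 1 resembles a synchrotron experiment, ~0.1 a
        laboratory source.
    sigma_rough:
        Interface roughness in Å (0 = sharp interfaces).
    noise_scale:
        Overall multiplier on σ(q) (default 1).
    noise_c, noise_k:
        Calibration constants of the empirical error model, in the model's
        arbitrary intensity units.
    """

    eta: float = 0.01
    exposure: float = 1.0
    sigma_rough: float = 0.0
    noise_scale: float = 1.0
    noise_c: float = 0.85
    noise_k: float = 4500.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")
        if self.sigma_rough < 0:
            raise ValueError("sigma_rough must be >= 0")
        if self.noise_scale <= 0 or self.noise_c < 0 or self.noise_k <= 0:
            raise ValueError("invalid noise-model constants")


@dataclass
class SimulatedDataset:
    """(q, I_sim, σ_sim) triples — the output of the virtual experiment."""

    q: np.ndarray  # Å⁻¹
    i_sim: np.ndarray  # arbitrary units
    sigma_sim: np.ndarray  # 1σ errors, same units

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.i_sim = np.asarray(self.i_sim, dtype=float)
        self.sigma_sim = np.asarray(self.sigma_sim, dtype=float)
        if not (self.q.shape == self.i_sim.shape == self.sigma_sim.shape):
            raise ValueError("q, i_sim and sigma_sim must have equal length")
        if np.any(self.sigma_sim <= 0):
            raise ValueError("sigma_sim must be > 0 everywhere")


def apply_roughness(curve: ScatteringCurve, sigma_rough: float) -> ScatteringCurve:
    """Damp the intensity by the interface-roughness factor exp(−(q σ_rough)²).

    The convention here puts the full factor on the intensity (i.e.
    exp(−(qσ)²/2) on the amplitude).  p(r) is never modified by roughness.
    """
    if sigma_rough < 0:
        raise ValueError("sigma_rough must be >= 0")
    if sigma_rough == 0:
        return ScatteringCurve(q=curve.q, intensity=curve.intensity.copy())
    factor = np.exp(-((curve.q * sigma_rough) ** 2))
    return ScatteringCurve(q=curve.q, intensity=curve.intensity * factor)


def forward_scattering(model: PointModel, params: ExperimentParams) -> float:
    """I(0) = η (Σ_j Δb_j)² / V_p in arbitrary units.

    Linear in volume fraction, quadratic in contrast; for a uniform particle
    of contrast Δρ this is η Δρ² V_p.
    """
    if model.total_volume <= 0:
        raise ValueError("particle volume must be > 0")
    net_b = float(np.sum(model.weights))
    return params.eta * net_b**2 / model.total_volume


def simulate_errors(
    q: np.ndarray, i_scaled: np.ndarray, params: ExperimentParams
) -> np.ndarray:
    """Per-point 1σ errors from the empirical SAXS variance model.

    σ²(q) = (I(q) + c) / (k q t): counting-statistics-like growth with
    intensity, a background-dominated floor c at vanishing intensity, the
    Poisson σ ∝ 1/√t exposure scaling, and the ~1/q growth of the solid
    angle per q bin of an isotropic detector.
    """
    q = np.asarray(q, dtype=float)
    i_scaled = np.asarray(i_scaled, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be > 0")
    variance = (np.maximum(i_scaled, 0.0) + params.noise_c) / (
        params.noise_k * q * params.exposure
    )
    return params.noise_scale * np.sqrt(variance)


def sample_dataset(
    q: np.ndarray,
    i_scaled: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Draw I_sim(q) ~ N(I(q), σ(q)²), independently per point."""
    q = np.asarray(q, dtype=float)
    i_scaled = np.asarray(i_scaled, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (q.shape == i_scaled.shape == sigma.shape):
        raise ValueError("q, intensity and sigma grids must match")
    i_sim = i_scaled + sigma * rng.standard_normal(q.shape)
    return SimulatedDataset(q=q, i_sim=i_sim, sigma_sim=sigma)


def write_dat(dataset: SimulatedDataset, path, header: str | None = None) -> None:
    """Write 3-column text (q [Å⁻¹], I, σ) — the de facto SAS .dat format."""
    lines = []
    if header:
        lines += [f"# {line}" for line in header.splitlines()]
    lines.append("# q[1/AA]  I(q)[a.u.]  sigma[a.u.]")
    for qk, ik, sk in zip(dataset.q, dataset.i_sim, dataset.sigma_sim):
        lines.append(f"{qk:.8e}  {ik:.8e}  {sk:.8e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dat(path) -> SimulatedDataset:
    """Read a 3-column (q, I, σ) text file, skipping # comment lines."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (q, I, sigma)")
    return SimulatedDataset(q=data[:, 0], i_sim=data[:, 1], sigma_sim=data[:, 2])
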