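"""Closed-form form factors and a weighted least-squares fitter.

These orientation-averaged analytic models are the validation surface of the
bead-model simulator: Monte Carlo curves are checked against them, and the
fitter recovers model parameters from simulated noisy data the way a user
would fit real data.

All models are normalized so P(0) = 1 and evaluated as
I(q) = scale · P(q) + background.  Anisotropic shapes are orientation
averaged by Gauss–Legendre quadrature over u = cos α ∈ [0, 1], where α is the
angle between the symmetry axis and the momentum transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.special import j1

__all__ = ["AnalyticModel", "FitResult", "analytic_intensity", "fit_weighted"]

# 64 Gauss-Legendre nodes resolve the orientation average to ~1e-4 relative
# for aspect ratios up to ~20 over the default q range
_N_QUAD = 64

_MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "sphere": ("radius",),
    "cylinder": ("radius", "length"),
    "ellipsoid_of_revolution": ("r_equatorial", "r_polar"),
    "core_shell_cylinder": ("radius", "length", "thickness", "sld_core", "sld_shell"),
}


@dataclass
class AnalyticModel:
    """A named closed-form model with its parameter values.

    ``params`` holds the geometric/contrast parameters per kind (see
    `_MODEL_PARAMS`) plus the universal ``scale`` (default 1) and
    ``background`` (default 0).
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _MODEL_PARAMS:
            raise ValueError(f"unsupported analytic model kind: {self.kind!r}")
        missing = [n for n in _MODEL_PARAMS[self.kind] if n not in self.params]
        if missing:
            raise ValueError(f"{self.kind}: missing parameter(s) {missing}")
        self.params.setdefault("scale", 1.0)
        self.params.setdefault("background", 0.0)


@dataclass
class FitResult:
    """Outcome of a weighted least-squares fit."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    chi2_reduced: float
    success: bool
    message: str = ""

    def report(self) -> str:
        lines = [f"{'parameter':<16}{'value':>14}{'std error':>14}"]
        for name, val in self.estimates.items():
            err = self.std_errors.get(name, float("nan"))
            lines.append(f"{name:<16}{val:>14.5g}{err:>14.3g}")
        lines.append(f"reduced chi-square: {self.chi2_reduced:.4f}")
        return "\n".join(lines)


def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """Normalized sphere amplitude 3(sin x − x cos x)/x³, A(0) = 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    amp = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    return np.where(small, 1.0 - x**2 / 10.0, amp)


def _j1x(x: np.ndarray) -> np.ndarray:
    """2 J₁(x)/x with the x→0 limit 1 (cylinder cross-section amplitude)."""
    small = np.abs(x) < 1e-6
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0, 2.0 * j1(xs) / xs)


def _sinc(x: np.ndarray) -> np.ndarray:
    return np.sinc(np.asarray(x) / np.pi)


def _orientation_nodes(n: int = _N_QUAD) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes/weights for ∫₀¹ du (u = cos α)."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def _cylinder_amplitude(q: np.ndarray, u: np.ndarray, radius: float, length: float) -> np.ndarray:
    """Normalized amplitude of a cylinder at orientations u; shape (len(q), len(u))."""
    sin_a = np.sqrt(1.0 - u**2)
    qr = np.outer(q, sin_a) * radius
    ql = np.outer(q, u) * length / 2.0
    return _j1x(qr) * _sinc(ql)


def analytic_intensity(m: AnalyticModel, q: np.ndarray, n_quad: int = _N_QUAD) -> np.ndarray:
    """Evaluate I(q) = scale · P(q) + background for a closed-form model.

    ``n_quad`` sets the Gauss–Legendre order of the orientation average for
    the anisotropic kinds (the sphere needs none).
    """
    q = np.asarray(q, dtype=float)
    p = m.params
    scale, background = p["scale"], p["background"]

    if m.kind == "sphere":
        pq = _sphere_amplitude(q * p["radius"]) ** 2
        return scale * pq + background

    u, w = _orientation_nodes(n_quad)

    if m.kind == "cylinder":
        amp = _cylinder_amplitude(q, u, p["radius"], p["length"])
        return scale * (amp**2 @ w) + background

    if m.kind == "ellipsoid_of_revolution":
        a, c = p["r_equatorial"], p["r_polar"]
        r_eff = np.sqrt(a**2 * (1.0 - u**2) + c**2 * u**2)
        amp = _sphere_amplitude(np.outer(q, r_eff))
        return scale * (amp**2 @ w) + background

    if m.kind == "core_shell_cylinder":
        r_c, l_c, t = p["radius"], p["length"], p["thickness"]
        v_core = np.pi * r_c**2 * l_c
        v_total = np.pi * (r_c + t) ** 2 * (l_c + 2.0 * t)
        # core against shell, plus whole outer body against solvent (SLD 0)
        b_core = (p["sld_core"] - p["sld_shell"]) * v_core
        b_outer = p["sld_shell"] * v_total
        f0 = b_core + b_outer
        if f0 == 0:
            raise ValueError("core_shell_cylinder: zero net contrast, P(q) undefined")
        amp = (
            b_core * _cylinder_amplitude(q, u, r_c, l_c)
            + b_outer * _cylinder_amplitude(q, u, r_c + t, l_c + 2.0 * t)
        ) / f0
        return scale * (amp**2 @ w) + background

    raise ValueError(f"unsupported analytic model kind: {m.kind!r}")


# relative jitter applied to free parameters for the extra fit starts;
# guards against shallow local minima from parameter correlations
_JITTER = (0.0, 0.1, -0.08)


def fit_weighted(
    dataset,
    m0: AnalyticModel,
    free: set[str] | None = None,
    fixed: dict[str, float] | None = None,
) -> FitResult:
    """Weighted least-squares fit of an analytic model to (q, I, σ) data.

    Minimizes Σ[(I_sim − I_model)/σ]² with a bounded Levenberg–Marquardt-type
    local minimizer, multi-started from ``m0`` and two jittered copies.
    ``free`` names the parameters to vary (default: all, including scale and
    background); ``fixed`` pins parameters at given values.  Standard errors
    come from the covariance of the weighted least squares at the optimum.
    """
    params0 = dict(m0.params)
    if fixed:
        params0.update(fixed)
    all_names = list(params0)
    if free is None:
        free_names = [n for n in all_names if not (fixed and n in fixed)]
    else:
        unknown = set(free) - set(all_names)
        if unknown:
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
        free_names = [n for n in all_names if n in free]
    n_free = len(free_names)
    if len(dataset.q) < n_free + 1:
        raise ValueError("not enough data points for the number of free parameters")

    geometric = set(_MODEL_PARAMS[m0.kind])

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        model = AnalyticModel(m0.kind, {n: pars[n].value for n in all_names})
        return (dataset.i_sim - analytic_intensity(model, dataset.q)) / dataset.sigma_sim

    best = None
    for jit in _JITTER:
        pars = lmfit.Parameters()
        for name in all_names:
            val = params0[name]
            vary = name in free_names
            if vary and name in geometric and "sld" not in name:
                val = val * (1.0 + jit)
                pars.add(name, value=val, vary=True, min=1e-3)
            elif name == "scale":
                pars.add(name, value=val * (1.0 + jit) if vary else val, vary=vary)
            else:
                pars.add(name, value=val, vary=vary)
        try:
            # scale_covar=False: σ are absolute experimental errors, so the
            # covariance (hence std errors) honors them directly
            res = lmfit.minimize(residual, pars, method="leastsq", scale_covar=False)
        except Exception:  # singular step from a bad start: try the next one
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None:
        return FitResult({}, {}, float("nan"), False, "all fit starts failed")

    estimates = {n: float(best.params[n].value) for n in all_names}
    std_errors = {
        n: float(best.params[n].stderr) if best.params[n].stderr is not None else float("nan")
        for n in free_names
    }
    return FitResult(
        estimates=estimates,
        std_errors=std_errors,
        chi2_reduced=float(best.redchi),
        success=bool(best.success),
        message=str(best.message),
    )
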