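"""Parameter-recovery experiment on a multi-contrast reference particle.

A core–shell cylinder (core radius 20 Å, core length 360 Å, shell thickness
20 Å, core contrast −1, shell contrast +1) is simulated as a bead model with
realistic noise, then fitted with the closed-form core–shell-cylinder model
(core contrast fixed at −1, scale and background free).  Recovering the
construction parameters from the virtual data is an end-to-end check of the
whole chain: geometry, binned Debye sum, experimental scaling, noise model
and fitter.
"""

from __future__ import annotations

import numpy as np

from .analytic import AnalyticModel, FitResult, fit_weighted
from .debye import default_q_grid
from .geometry import ModelSpec, Subunit
from .pipeline import simulate_model

__all__ = ["core_shell_cylinder_spec", "recover_core_shell_cylinder"]

# construction parameters of the reference particle (Å / unitless contrast)
CORE_RADIUS = 20.0
CORE_LENGTH = 360.0
SHELL_THICKNESS = 20.0
CORE_SLD = -1.0
SHELL_SLD = +1.0


def core_shell_cylinder_spec(n_points: int = 3000, via_exclusion: bool = True) -> ModelSpec:
    """The reference core–shell cylinder, built one of two equivalent ways.

    ``via_exclusion``: a small core cylinder (contrast −1) listed before a
    full-size cylinder (+1); overlap points of the outer cylinder are deleted,
    leaving the shell.  Otherwise: four non-overlapping subunits — core,
    radial ring and two end caps.
    """
    r_out = CORE_RADIUS + SHELL_THICKNESS
    l_out = CORE_LENGTH + 2.0 * SHELL_THICKNESS
    if via_exclusion:
        subunits = (
            Subunit("cylinder", (CORE_RADIUS, CORE_LENGTH), CORE_SLD),
            Subunit("cylinder", (r_out, l_out), SHELL_SLD),
        )
    else:
        z_cap = (CORE_LENGTH + SHELL_THICKNESS) / 2.0
        subunits = (
            Subunit("cylinder", (CORE_RADIUS, CORE_LENGTH), CORE_SLD),
            Subunit("cylindrical_ring", (r_out, CORE_RADIUS, CORE_LENGTH), SHELL_SLD),
            Subunit("cylinder", (r_out, SHELL_THICKNESS), SHELL_SLD, (0.0, 0.0, z_cap)),
            Subunit("cylinder", (r_out, SHELL_THICKNESS), SHELL_SLD, (0.0, 0.0, -z_cap)),
        )
    return ModelSpec(subunits=subunits, n_points_total=n_points, exclude_overlap=True)


def recover_core_shell_cylinder(
    seed: int, n_points: int = 3000, q: np.ndarray | None = None
) -> FitResult:
    """Simulate the reference particle with default noise and fit it.

    Free parameters: core radius, core length, shell thickness, shell
    contrast, scale and background; the core contrast is fixed at −1 (fitting
    both contrasts plus scale is degenerate).  The fit starts from the
    construction values.
    """
    if q is None:
        q = default_q_grid()
    rng = np.random.default_rng([seed, 0])
    result = simulate_model(core_shell_cylinder_spec(n_points), q, rng)
    start = AnalyticModel(
        "core_shell_cylinder",
        {
            "radius": CORE_RADIUS,
            "length": CORE_LENGTH,
            "thickness": SHELL_THICKNESS,
            "sld_core": CORE_SLD,
            "sld_shell": SHELL_SLD,
            "scale": result.i0,
            "background": 0.0,
        },
    )
    return fit_weighted(result.dataset, start, fixed={"sld_core": CORE_SLD})
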