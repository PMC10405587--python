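"""Optional matplotlib plots: p(r), I(q), simulated data, 2D projections.

Kept separate so the numeric core carries no plotting dependency; imported
only when plots are requested.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_run(results: dict, outdir) -> None:
    """Write comparison plots for a run and per-model point projections."""
    outdir = Path(outdir)

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for name, res in results.items():
        axes[0].plot(res.pr[:, 0], res.pr[:, 1], label=name)
        axes[1].loglog(res.curve.q, res.curve.intensity, label=name)
        axes[2].errorbar(
            res.dataset.q,
            res.dataset.i_sim,
            yerr=res.dataset.sigma_sim,
            fmt=".",
            ms=2,
            lw=0.5,
            label=name,
        )
    axes[0].set(xlabel="r [Å]", ylabel="p(r)", title="pair distance distribution")
    axes[1].set(xlabel="q [Å$^{-1}$]", ylabel="I$_{norm}$(q)", title="normalized intensity")
    axes[2].set(xlabel="q [Å$^{-1}$]", ylabel="I$_{sim}$(q) [a.u.]", title="simulated data")
    axes[2].set_xscale("log")
    axes[2].set_yscale("log")
    for ax in axes:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "comparison.png", dpi=150)
    plt.close(fig)

    for name, res in results.items():
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        xyz = res.model.coords
        pairs = [(0, 1, "x", "y"), (0, 2, "x", "z"), (1, 2, "y", "z")]
        for ax, (i, j, li, lj) in zip(axes, pairs):
            ax.scatter(xyz[:, i], xyz[:, j], s=1, c=res.model.weights, cmap="coolwarm")
            ax.set(xlabel=f"{li} [Å]", ylabel=f"{lj} [Å]", aspect="equal")
        fig.suptitle(f"{name}: 2D projections of the point model")
        fig.tight_layout()
        fig.savefig(outdir / f"projections_{name}.png", dpi=150)
        plt.close(fig)
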