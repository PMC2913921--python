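"""Optional diagnostic figures; the numeric pipeline never requires them."""

from __future__ import annotations

import numpy as np


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_estimate(masses, unwrapped, reference, estimate, path) -> None:
    """User points, both reference lines, the fitted line and the estimate."""
    plt = _pyplot()
    masses = np.asarray(masses, dtype=float)
    grid = np.linspace(0, masses.max() * 1.05, 50)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(grid, reference.b_12C * grid, color="0.4", lw=1, label="0 atom % reference")
    ax.plot(grid, reference.b_13C * grid, color="0.7", lw=1, label="100 atom % reference")
    ax.plot(
        grid,
        estimate.slope_fit.b * grid,
        color="black",
        lw=2,
        label=f"fit: {estimate.atom_percent:.1f} ± {estimate.se:.1f} atom %",
    )
    ax.scatter(masses, np.asarray(unwrapped, dtype=float), s=12, color="0.2", zorder=3)
    ax.set_xlabel("peptide mass (Da)")
    ax.set_ylabel("unwrapped decimal residual (Da)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_accuracy(cells, path) -> None:
    """Box plot of replicate estimates per subsample size, one panel per truth."""
    plt = _pyplot()
    truths = sorted({c.truth for c in cells})
    fig, axes = plt.subplots(
        1, len(truths), figsize=(4 * len(truths), 4), squeeze=False, sharey=True
    )
    for ax, truth in zip(axes[0], truths):
        sub = sorted((c for c in cells if c.truth == truth), key=lambda c: c.n_peptides)
        ax.boxplot(
            [c.estimates for c in sub],
            tick_labels=[str(c.n_peptides) for c in sub],
            whis=(2.5, 97.5),
            flierprops={"markersize": 2},
        )
        ax.axhline(truth, color="0.5", lw=1, ls="--")
        ax.axhline(truth + 5, color="0.8", lw=0.8)
        ax.axhline(truth - 5, color="0.8", lw=0.8)
        ax.set_title(f"truth {truth:.0f} atom %")
        ax.set_xlabel("peptide masses per draw")
        ax.tick_params(axis="x", rotation=60)
    axes[0][0].set_ylabel("estimated atom % 13C")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
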