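"""Figure-style reports: sensitivity profiles with null bands and
scoring-matrix logo data.

Plotting needs matplotlib and is optional; every report also has a plain
TSV form so results remain inspectable without a display stack.
"""

from __future__ import annotations

import numpy as np

from .models import MechanismAgnosticModel


def logo_matrix(model: MechanismAgnosticModel) -> np.ndarray:
    """Per-position logo heights of a scoring matrix.

    The display gauge centers each position to zero mean (the indicator
    design is redundant, so only within-position contrasts are defined);
    rows are positions, columns A, C, G, T in -ddG/RT.
    """
    b1 = model.beta1
    return b1 - b1.mean(axis=1, keepdims=True)


def write_logo_tsv(model: MechanismAgnosticModel, path) -> None:
    heights = logo_matrix(model)
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\n")
        for i, row in enumerate(heights):
            fh.write(f"{i + 1}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def plot_profile_with_bands(
    profile: np.ndarray,
    bands: np.ndarray | None,
    feature_name: str,
    out_path,
    units: str = "per unit shape",
):
    """Plot a shape-sensitivity profile with null percentile bands.

    ``bands`` is the (4, n) array of 2.5/25/75/97.5 percentiles from a
    null ensemble, or None for a bare profile.
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "plotting requires matplotlib; install it or use the TSV outputs"
        ) from exc
    x = np.arange(1, profile.size + 1)
    fig, ax = plt.subplots(figsize=(5, 3))
    if bands is not None:
        ax.fill_between(x, bands[0], bands[3], alpha=0.2, color="gray", label="2.5-97.5%")
        ax.fill_between(x, bands[1], bands[2], alpha=0.35, color="gray", label="25-75%")
    ax.axhline(0.0, lw=0.5, color="k")
    ax.plot(x, profile, "o-", color="C3", label="observed")
    ax.set_xlabel("binding-site position")
    ax.set_ylabel(f"{feature_name} sensitivity (-ddG/RT {units})")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
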