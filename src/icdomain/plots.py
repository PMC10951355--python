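"""Basic plots for the main analysis outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .perturb import PermutationResult


def plot_permutation_null(result: PermutationResult, path: str) -> None:
    """Null distribution of average degree with the observed value marked."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.null_values, bins=30, color="0.7", edgecolor="0.4")
    ax.axvline(result.observed, color="crimson", lw=2, label="CRE-removed")
    ax.set_xlabel("average degree after removal")
    ax.set_ylabel("permutations")
    ax.legend(frameon=False)
    ax.set_title(f"p = {result.p_value:.3g} (n = {result.n_perm})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_erosion_curves(curve: pd.DataFrame, path: str) -> None:
    """Promoter-survival fraction vs erosion percentile per gene group."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, sub in curve.groupby("group"):
        ax.plot(
            sub["percentile"], sub["promoter_fraction"], marker="o", label=group
        )
    ax.set_xlabel("connectivity percentile threshold")
    ax.set_ylabel("fraction of promoters retained")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decile_probabilities(bins: pd.DataFrame, path: str) -> None:
    """P(count > mean) per connectivity decile."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(bins["bin"], bins["p_direct"], color="steelblue")
    ax.set_xlabel("connectivity decile")
    ax.set_ylabel("P(count > mean | decile)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
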