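"""Static overview plots of a biclustering run."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .datatypes import BiclusterSet, DataMatrix
from .factorize import FactorizationResult

logger = logging.getLogger("mfbiclust")

__all__ = ["plot_overview"]


def plot_overview(
    matrix: DataMatrix,
    result: FactorizationResult,
    biclusters: BiclusterSet,
    out: str | Path,
) -> list[Path]:
    """Write the run overview figures and return their paths.

    Produces a heatmap with per-bicluster row/column membership bars, the
    median spectrum with member variables highlighted, and per-factor
    score/loading profiles.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    m, n = matrix.shape
    k = max(biclusters.k, 1)

    try:
        fig, axes = plt.subplots(
            2,
            2,
            figsize=(11, 8),
            gridspec_kw={"width_ratios": [4, 1], "height_ratios": [4, 1]},
        )
        ax = axes[0, 0]
        im = ax.imshow(matrix.values, aspect="auto", cmap="viridis", interpolation="nearest")
        ax.set_xlabel("variables")
        ax.set_ylabel("samples")
        ax.set_title("data matrix")
        fig.colorbar(im, ax=ax, fraction=0.04)

        # membership bars: one stripe per bicluster along each axis
        row_bar = np.zeros((m, k))
        col_bar = np.zeros((k, n))
        for a, b in enumerate(biclusters):
            row_bar[sorted(b.rows), a] = a + 1
            col_bar[a, sorted(b.cols)] = a + 1
        axes[0, 1].imshow(row_bar, aspect="auto", cmap="tab10", interpolation="nearest")
        axes[0, 1].set_title("row membership")
        axes[0, 1].set_xticks(range(k))
        axes[1, 0].imshow(col_bar, aspect="auto", cmap="tab10", interpolation="nearest")
        axes[1, 0].set_title("column membership")
        axes[1, 1].axis("off")
        fig.tight_layout()
        p = out / "overview_heatmap.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    except Exception as exc:  # pragma: no cover - plotting must not kill a run
        logger.warning("heatmap plot failed: %s", exc)

    try:
        median_spectrum = np.median(matrix.values, axis=0)
        member_cols = sorted(set().union(*(b.cols for b in biclusters)) if biclusters.k else set())
        fig, ax = plt.subplots(figsize=(10, 3))
        ax.plot(median_spectrum, color="0.4", lw=0.8, label="median spectrum")
        if member_cols:
            ax.plot(
                member_cols,
                median_spectrum[member_cols],
                "r.",
                ms=4,
                label="bicluster variables",
            )
        ax.set_xlabel("variable index")
        ax.set_ylabel("median intensity")
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        p = out / "median_spectrum.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    except Exception as exc:  # pragma: no cover
        logger.warning("median spectrum plot failed: %s", exc)

    try:
        fig, axes = plt.subplots(result.k, 2, figsize=(10, 1.8 * result.k), squeeze=False)
        for a in range(result.k):
            axes[a, 0].plot(result.W[:, a], lw=0.9)
            axes[a, 0].set_ylabel(f"factor {a + 1}\nscores", fontsize=8)
            axes[a, 1].plot(result.H[a, :], lw=0.9)
            axes[a, 1].set_ylabel("loadings", fontsize=8)
        axes[-1, 0].set_xlabel("sample index")
        axes[-1, 1].set_xlabel("variable index")
        fig.tight_layout()
        p = out / "factor_profiles.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    except Exception as exc:  # pragma: no cover
        logger.warning("factor profile plot failed: %s", exc)

    return paths
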