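"""Multivariate exploration of the per-cell feature table: pairwise
correlation/histogram summaries and a 2D t-SNE embedding for visual QC."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

__all__ = ["EmbeddingResult", "pairwise_summary", "tsne_embed", "plot_embedding"]


@dataclass(frozen=True)
class EmbeddingResult:
    coords: pd.DataFrame = field(repr=False)  # cell_id, x, y (input order)
    features: tuple[str, ...] = ()
    perplexity: float = 30.0
    n_iter: int = 1000
    seed: int = 0
    scaling: str = "z-score (pooled)"

    def params(self) -> dict:
        return {
            "features": list(self.features),
            "perplexity": self.perplexity,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "scaling": self.scaling,
        }


def pairwise_summary(
    cells: pd.DataFrame,
    features: list[str],
    n_bins: int = 40,
) -> tuple[pd.DataFrame, dict]:
    """Pairwise Pearson correlation matrix plus per-feature histograms
    (per condition when a condition column exists). Zero-variance features
    get missing correlations off the diagonal."""
    if len(features) < 2:
        raise ValueError("need at least two features")
    if len(cells) < 3:
        raise ValueError("need at least three cells")
    data = cells[features].astype(float)
    corr = data.corr(method="pearson")  # pandas leaves NaN for zero variance
    np.fill_diagonal(corr.values, 1.0)

    hists: dict = {}
    groups = (
        cells.groupby("condition", sort=True)
        if "condition" in cells.columns
        else [("all", cells)]
    )
    for feat in features:
        lo = float(data[feat].min())
        hi = float(data[feat].max())
        if lo == hi:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
        hists[feat] = {
            str(cond): np.histogram(grp[feat].dropna().to_numpy(float), bins=edges)[0]
            for cond, grp in groups
        }
        hists[feat]["edges"] = edges
    return corr, hists


def tsne_embed(
    cells: pd.DataFrame,
    features: list[str],
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
) -> EmbeddingResult:
    """Embed z-scored features in 2D with t-SNE (deterministic per seed).

    Coordinates are for visualization/QC of population structure only; no
    quantitative claim attaches to specific t-SNE geometry.
    """
    n = len(cells)
    min_n = int(3 * perplexity) + 1
    if n <= 3 * perplexity:
        raise ValueError(
            f"t-SNE with perplexity {perplexity} needs more than {int(3 * perplexity)} "
            f"cells (minimum {min_n}), got {n}"
        )
    X = cells[features].to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=n_iter,
    )
    Y = tsne.fit_transform(Z)
    coords = pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy()
            if "cell_id" in cells.columns
            else np.arange(1, n + 1),
            "x": Y[:, 0],
            "y": Y[:, 1],
        },
        index=cells.index,
    )
    return EmbeddingResult(
        coords=coords,
        features=tuple(features),
        perplexity=perplexity,
        n_iter=n_iter,
        seed=seed,
    )


def plot_embedding(
    result: EmbeddingResult,
    cells: pd.DataFrame,
    path,
    color_by: list[str] | None = None,
) -> None:
    """Scatter panels of the embedding colored by condition and by each
    feature's intensity (visual QC of population structure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    color_by = list(color_by or result.features)
    panels = (["condition"] if "condition" in cells.columns else []) + color_by
    ncol = min(3, len(panels))
    nrow = -(-len(panels) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.5 * nrow), squeeze=False)
    x, y = result.coords["x"], result.coords["y"]
    for ax, panel in zip(axes.ravel(), panels):
        if panel == "condition":
            for cond, grp in cells.groupby("condition", sort=True):
                idx = grp.index
                ax.scatter(x.loc[idx], y.loc[idx], s=4, alpha=0.6, label=str(cond))
            ax.legend(fontsize=7)
        else:
            sc = ax.scatter(x, y, c=cells[panel], s=4, cmap="viridis")
            fig.colorbar(sc, ax=ax, shrink=0.8)
        ax.set_title(panel, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    for ax in axes.ravel()[len(panels):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
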