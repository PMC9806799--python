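"""Per-cell intensity quantification.

Reduces an aligned ImageSet plus label images to one feature row per cell:
areas, centroid, and mean/sum intensity of the cell region in every
round/channel (column scheme ``r{round}_{channel}_{mean|sum}``), with
optional per-cell Pearson colocalization over the cytosol. Intensities are
raw by default; an optional per-field background subtraction (median of
non-cell pixels, per round/channel) is available for noisy acquisitions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imageset import ImageSet
from .segment import LabelImage

__all__ = ["max_project", "measure_cells", "colocalize", "column_name"]


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum intensity projection over z (axis 0). Idempotent on 2D input."""
    arr = np.asarray(stack)
    if arr.size == 0:
        raise ValueError("cannot max-project an empty stack")
    if arr.ndim == 2:
        return arr
    return arr.max(axis=0)


def column_name(round_idx: int, channel: str, stat: str) -> str:
    """Stable column naming: r{round}_{channel}_{mean|sum}, rounds 1-based."""
    return f"r{round_idx + 1}_{channel}_{stat}"


def measure_cells(
    cells: LabelImage,
    aligned: ImageSet,
    nuclei: LabelImage | None = None,
    cytosol: LabelImage | None = None,
    subtract_background: bool = False,
    condition: str | None = None,
) -> pd.DataFrame:
    """One row per cell with centroid, areas, per-round/channel mean and sum
    intensity over the cell region, and border/invalid-mask flags.

    ``subtract_background`` removes the per-round/channel median of non-cell
    pixels from means (and proportionally from sums, preserving
    sum = mean × area).
    """
    labels = cells.data
    if labels.shape != aligned.shape[-2:]:
        raise ValueError(
            f"label grid {labels.shape} does not match image shape {aligned.shape}"
        )
    ids = cells.labels
    if len(ids) == 0:
        return pd.DataFrame(columns=["cell_id"])
    index = np.arange(1, int(ids.max()) + 1)
    counts = np.bincount(labels.ravel(), minlength=len(index) + 1)[1:]
    if (counts[ids - 1] == 0).any():
        bad = [int(k) for k in ids if counts[k - 1] == 0]
        raise ValueError(f"labels with zero pixels: {bad}")

    cent = ndi.center_of_mass(np.ones_like(labels), labels, ids)
    cent = np.asarray(cent, dtype=float)
    out = pd.DataFrame(
        {
            "cell_id": ids.astype(int),
            "centroid_row": cent[:, 0],
            "centroid_col": cent[:, 1],
            "cell_area": counts[ids - 1].astype(int),
        }
    )
    if nuclei is not None:
        ncounts = np.bincount(nuclei.data.ravel(), minlength=len(index) + 1)[1:]
        out["nucleus_area"] = ncounts[ids - 1].astype(int)
    if cytosol is not None:
        ccounts = np.bincount(cytosol.data.ravel(), minlength=len(index) + 1)[1:]
        out["cytosol_area"] = ccounts[ids - 1].astype(int)

    bg_mask = labels == 0
    for r in range(aligned.n_rounds):
        for ch, grid in aligned.rounds[r].items():
            project = max_project(grid).astype(np.float64)
            mean = ndi.mean(project, labels, ids)
            bg = float(np.median(project[bg_mask])) if subtract_background else 0.0
            mean = np.asarray(mean) - bg
            out[column_name(r, ch, "mean")] = mean
            out[column_name(r, ch, "sum")] = mean * out["cell_area"].to_numpy()

    out["flag_border"] = out["cell_id"].isin(cells.border_labels)
    if aligned.valid_mask is not None:
        invalid = ~aligned.valid_mask
        overlap = ndi.sum_labels(invalid.astype(np.float64), labels, ids)
        out["flag_invalid"] = np.asarray(overlap) > 0
    else:
        out["flag_invalid"] = False
    if condition is not None:
        out["condition"] = condition
    out["field_id"] = aligned.field_id
    return out


def colocalize(
    cytosol: LabelImage,
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    min_pixels: int = 3,
) -> pd.DataFrame:
    """Per-cell Pearson correlation between two channels over the cytosol.

    Cells with fewer than ``min_pixels`` cytosol pixels or zero variance in
    either channel get a missing coefficient and are flagged undefined.
    """
    if channel_a.shape != cytosol.data.shape or channel_b.shape != cytosol.data.shape:
        raise ValueError("channel images must match the cytosol label grid shape")
    labels = cytosol.data
    ids = np.arange(1, int(max(labels.max(), max(cytosol.empty_labels, default=0))) + 1)
    a = channel_a.astype(np.float64)
    b = channel_b.astype(np.float64)
    n = np.bincount(labels.ravel(), minlength=len(ids) + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        sa = np.bincount(labels.ravel(), weights=a.ravel(), minlength=len(ids) + 1)[1:]
        sb = np.bincount(labels.ravel(), weights=b.ravel(), minlength=len(ids) + 1)[1:]
        saa = np.bincount(labels.ravel(), weights=(a * a).ravel(), minlength=len(ids) + 1)[1:]
        sbb = np.bincount(labels.ravel(), weights=(b * b).ravel(), minlength=len(ids) + 1)[1:]
        sab = np.bincount(labels.ravel(), weights=(a * b).ravel(), minlength=len(ids) + 1)[1:]
        cov = sab - sa * sb / n
        va = saa - sa**2 / n
        vb = sbb - sb**2 / n
        r = cov / np.sqrt(va * vb)
    valid = (n >= min_pixels) & (va > 1e-12) & (vb > 1e-12)
    r = np.where(valid, r, np.nan)
    return pd.DataFrame(
        {"cell_id": ids.astype(int), "pearson": r, "n_pixels": n.astype(int),
         "undefined": ~valid}
    )
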