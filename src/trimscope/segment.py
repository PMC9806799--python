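"""Nuclear segmentation and cell/cytosol region derivation.

Nuclei are detected on the (max-projected, aligned) nuclear channel by
thresholding and connected components, optionally splitting touching nuclei
by watershed on the smoothed distance transform. Cell regions are derived by
thickening each nucleus up to a fixed radius with nearest-nucleus collision
handling; the cytosol is the cell region minus its nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, watershed

__all__ = ["LabelImage", "segment_nuclei", "expand_cells", "derive_cytosol"]

DEFAULT_MIN_AREA_PX = 25
DEFAULT_EXPAND_RADIUS_PX = 12.0
# minimum separation between watershed seeds; larger than the distance-ridge
# length of a single elliptical nucleus at the default geometry
_SEED_MIN_DISTANCE = 15


@dataclass
class LabelImage:
    """Integer label grid: 0 = background, k > 0 = object k (consecutive)."""

    data: np.ndarray
    kind: Literal["nucleus", "cell", "cytosol"]
    border_labels: frozenset[int] = field(default_factory=frozenset)
    empty_labels: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_objects(self) -> int:
        return int(self.data.max())

    @property
    def labels(self) -> np.ndarray:
        vals = np.unique(self.data)
        return vals[vals > 0]


def _border_labels(labels: np.ndarray) -> frozenset[int]:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return frozenset(int(v) for v in np.unique(edge) if v > 0)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[vals] = np.arange(1, len(vals) + 1, dtype=np.int32)
    return lut[labels]


def segment_nuclei(
    nuclear_image: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    fill_holes: bool = True,
    split_touching: bool = True,
) -> LabelImage:
    """Detect nuclei on a 2D nuclear-channel image.

    Binarizes by Otsu's rule (or a fixed ``threshold`` when given), fills
    holes, drops objects under ``min_area_px``, optionally splits touching
    nuclei by watershed on the distance transform seeded at local maxima, and
    labels connected components. Objects touching the image border are
    recorded in ``border_labels``. An all-background result yields an empty
    LabelImage rather than an error.
    """
    if nuclear_image.ndim != 2:
        raise ValueError("segment_nuclei expects a 2D image (max-project z first)")
    img = nuclear_image.astype(np.float64)
    if threshold is None:
        if np.ptp(img) == 0:
            return LabelImage(np.zeros(img.shape, np.int32), "nucleus")
        threshold = float(threshold_otsu(img))
    mask = img > threshold
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=max(min_area_px - 1, 0))
    if not mask.any():
        return LabelImage(np.zeros(img.shape, np.int32), "nucleus")

    if split_touching:
        dist = ndi.distance_transform_edt(mask)
        smooth = gaussian(dist, sigma=1.5)
        peaks = peak_local_max(
            smooth, min_distance=_SEED_MIN_DISTANCE, labels=mask, exclude_border=False
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        if markers.max() == 0:
            labels = cc_label(mask, connectivity=2).astype(np.int32)
        else:
            labels = watershed(-smooth, markers, mask=mask).astype(np.int32)
    else:
        labels = cc_label(mask, connectivity=2).astype(np.int32)

    # watershed can orphan components that received no seed; label them too
    orphan = mask & (labels == 0)
    if orphan.any():
        extra = cc_label(orphan, connectivity=2)
        extra_mask = extra > 0
        labels[extra_mask] = extra[extra_mask] + labels.max()

    labels = _relabel_consecutive(labels)
    # drop fragments under the minimum area that splitting may have produced
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area_px)
    if len(small):
        labels[np.isin(labels, small)] = 0
        labels = _relabel_consecutive(labels)
    return LabelImage(labels, "nucleus", border_labels=_border_labels(labels))


def expand_cells(nuclei: LabelImage, radius_px: float = DEFAULT_EXPAND_RADIUS_PX) -> LabelImage:
    """Thicken nuclei into cell regions: every pixel within ``radius_px``
    (Euclidean) of a nucleus joins the nearest nucleus's label. Nucleus pixels
    keep their labels; radius 0 returns the nuclei unchanged."""
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    cells = expand_labels(nuclei.data, distance=radius_px).astype(np.int32)
    return LabelImage(
        cells, "cell",
        border_labels=_border_labels(cells) | nuclei.border_labels,
    )


def derive_cytosol(cells: LabelImage, nuclei: LabelImage) -> LabelImage:
    """Cytosol k = cell k minus nucleus k. Cells with an empty cytosol are
    retained (their label simply has no pixels) and listed in
    ``empty_labels``."""
    cell_set = set(cells.labels.tolist())
    nuc_set = set(nuclei.labels.tolist())
    if cell_set != nuc_set:
        raise ValueError(
            f"label mismatch between cells and nuclei: "
            f"only-cells={sorted(cell_set - nuc_set)}, only-nuclei={sorted(nuc_set - cell_set)}"
        )
    cyto = np.where(nuclei.data > 0, 0, cells.data).astype(np.int32)
    present = set(np.unique(cyto).tolist()) - {0}
    empty = frozenset(int(k) for k in cell_set - present)
    return LabelImage(cyto, "cytosol", border_labels=cells.border_labels, empty_labels=empty)
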