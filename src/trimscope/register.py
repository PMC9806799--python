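"""Round-to-round alignment of cyclic immunofluorescence images.

All rounds are aligned to round 1 using the nuclear (Hoechst) channel as the
reference, with a translation-only model: the plate is fixed between rounds
and only the stage is repositioned, so residual motion is rigid drift.
Estimation uses normalized cross-correlation in the frequency domain with
sub-pixel upsampling; a validity mask tracks pixels covered by every round
so downstream quantification can exclude cells touching exposed borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .imageset import ImageSet

__all__ = ["ShiftEstimate", "ShiftReport", "estimate_shift", "apply_shift", "register_rounds"]

DEFAULT_UPSAMPLE = 10
DEFAULT_MAX_SHIFT_FRAC = 0.10  # of image width


@dataclass(frozen=True)
class ShiftEstimate:
    shift: tuple[float, float]  # (dy, dx) of the moving image's content vs reference
    score: float  # Pearson correlation at the aligned overlap, in [-1, 1]
    low_confidence: bool = False


@dataclass(frozen=True)
class ShiftReport:
    """Per-round alignment summary for one ImageSet."""

    shifts: list[tuple[float, float]]
    scores: list[float]
    residuals: list[float]  # |shift| re-estimated after alignment
    low_confidence: list[bool]

    def to_dict(self) -> dict:
        return {
            "rounds": [
                {
                    "round": i + 1,
                    "shift_dy_dx": list(self.shifts[i]),
                    "score": self.scores[i],
                    "residual_px": self.residuals[i],
                    "low_confidence": self.low_confidence[i],
                }
                for i in range(len(self.shifts))
            ]
        }


def _overlap_correlation(ref: np.ndarray, moved: np.ndarray, shift) -> float:
    """Pearson correlation between reference and aligned image, excluding the
    border strip exposed by the translation."""
    dy = int(np.ceil(abs(shift[0]))) + 1
    dx = int(np.ceil(abs(shift[1]))) + 1
    a = ref[dy:-dy or None, dx:-dx or None].astype(np.float64).ravel()
    b = moved[dy:-dy or None, dx:-dx or None].astype(np.float64).ravel()
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def estimate_shift(
    reference: np.ndarray,
    moving: np.ndarray,
    upsample: int = DEFAULT_UPSAMPLE,
    max_shift_frac: float = DEFAULT_MAX_SHIFT_FRAC,
) -> ShiftEstimate:
    """Estimate the translation of ``moving``'s content relative to ``reference``.

    Returns the shift (dy, dx) such that the moving image's scene sits at
    +shift relative to the reference; sub-pixel resolution 1/upsample.
    Shifts larger than ``max_shift_frac`` of the width are flagged
    low-confidence rather than silently accepted.
    """
    if reference.shape != moving.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {moving.shape}")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise ValueError("no registration signal: constant image")
    # phase_cross_correlation returns the shift that moves `moving` onto the
    # reference, i.e. minus the drift of its content.
    reg, _, _ = phase_cross_correlation(
        reference.astype(np.float64),
        moving.astype(np.float64),
        upsample_factor=upsample,
        normalization="phase",
    )
    shift = (-float(reg[0]), -float(reg[1]))
    moved = apply_shift(moving.astype(np.float64), shift)
    score = _overlap_correlation(reference.astype(np.float64), moved, shift)
    max_px = max_shift_frac * reference.shape[1]
    low = bool(np.hypot(*shift) > max_px)
    return ShiftEstimate(shift=shift, score=score, low_confidence=low)


def _int_roll_fill(img: np.ndarray, dy: int, dx: int, fill) -> np.ndarray:
    out = np.full_like(img, fill)
    h, w = img.shape[-2], img.shape[-1]
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[..., ys, xs] = img[..., ys_src, xs_src]
    return out


def apply_shift(image: np.ndarray, shift, fill: float = 0.0) -> np.ndarray:
    """Translate an image by −shift so content drifted by +shift lands back on
    the reference frame. Integer shifts are exact pixel moves; fractional
    shifts use first-order (bilinear) interpolation. Shape is unchanged;
    exposed borders are filled with ``fill``."""
    dy, dx = float(shift[0]), float(shift[1])
    if not (np.isfinite(dy) and np.isfinite(dx)):
        raise ValueError(f"shift must be finite, got {shift}")
    if dy == int(dy) and dx == int(dx):
        return _int_roll_fill(image, -int(dy), -int(dx), fill)
    return ndi.shift(
        image.astype(np.float64), (-dy, -dx), order=1, mode="constant", cval=fill
    )


def register_rounds(
    image_set: ImageSet,
    nuclear_channel: str = "Hoechst",
    upsample: int = DEFAULT_UPSAMPLE,
    max_shift_frac: float = DEFAULT_MAX_SHIFT_FRAC,
) -> tuple[ImageSet, ShiftReport]:
    """Align every round of an ImageSet to round 1 via its nuclear channel.

    Each round's shift is estimated on the nuclear channel and then applied to
    all channels of that round. Round 1 is never modified. The returned set
    carries a ``valid_mask`` of pixels covered by every round; the input set
    is untouched.
    """
    for i, rnd in enumerate(image_set.rounds):
        if nuclear_channel not in rnd:
            raise ValueError(f"round {i + 1} is missing nuclear channel {nuclear_channel!r}")

    ref = image_set.rounds[0][nuclear_channel]
    shifts: list[tuple[float, float]] = [(0.0, 0.0)]
    scores: list[float] = [1.0]
    residuals: list[float] = [0.0]
    low_conf: list[bool] = [False]
    aligned_rounds: list[dict[str, np.ndarray]] = [
        {c: g.copy() for c, g in image_set.rounds[0].items()}
    ]
    mask = np.ones(ref.shape, dtype=bool)

    for r in range(1, image_set.n_rounds):
        est = estimate_shift(
            ref, image_set.rounds[r][nuclear_channel], upsample=upsample,
            max_shift_frac=max_shift_frac,
        )
        shifts.append(est.shift)
        scores.append(est.score)
        low_conf.append(est.low_confidence)
        aligned = {
            c: apply_shift(g.astype(np.float64), est.shift)
            for c, g in image_set.rounds[r].items()
        }
        mask &= apply_shift(np.ones(ref.shape), est.shift) > 0.999
        aligned_rounds.append(aligned)
        res = estimate_shift(ref, aligned[nuclear_channel], upsample=upsample)
        residuals.append(float(np.hypot(*res.shift)))

    out = ImageSet(
        rounds=aligned_rounds,
        pixel_um=image_set.pixel_um,
        field_id=image_set.field_id,
        true_shifts=None,
        valid_mask=mask,
    )
    report = ShiftReport(
        shifts=shifts, scores=scores, residuals=residuals, low_confidence=low_conf
    )
    return out, report
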