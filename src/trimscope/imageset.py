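"""In-memory container for a multi-round, multi-channel fluorescence image set."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageSet"]


@dataclass
class ImageSet:
    """One imaged field across staining rounds.

    ``rounds[r]`` maps channel name → 2D (or 3D, z-first) intensity grid.
    ``true_shifts`` holds the generator's ground-truth stage drift per round,
    as (dy, dx) in pixels relative to round 1 — ``None`` for real data.
    ``valid_mask`` (set by registration) marks pixels covered by every round
    after alignment.
    """

    rounds: list[dict[str, np.ndarray]]
    pixel_um: float = 0.33
    field_id: str = "field_000"
    true_shifts: list[tuple[float, float]] | None = None
    valid_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shapes = {g.shape for rnd in self.rounds for g in rnd.values()}
        if len(shapes) > 1:
            raise ValueError(f"all grids in an ImageSet must share a shape, got {shapes}")
        if self.true_shifts is not None:
            if len(self.true_shifts) != len(self.rounds):
                raise ValueError("true_shifts must have one entry per round")
            if tuple(self.true_shifts[0]) != (0.0, 0.0) and tuple(self.true_shifts[0]) != (0, 0):
                raise ValueError("round 1 true_shift must be (0, 0)")

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.rounds[0].values())).shape

    def channel_names(self, round_idx: int) -> tuple[str, ...]:
        return tuple(self.rounds[round_idx])

    def get(self, round_idx: int, channel: str) -> np.ndarray:
        try:
            return self.rounds[round_idx][channel]
        except KeyError:
            raise KeyError(
                f"round {round_idx + 1} has no channel {channel!r}; "
                f"available: {list(self.rounds[round_idx])}"
            ) from None

    def copy(self) -> "ImageSet":
        return ImageSet(
            rounds=[{c: g.copy() for c, g in rnd.items()} for rnd in self.rounds],
            pixel_um=self.pixel_um,
            field_id=self.field_id,
            true_shifts=None if self.true_shifts is None else list(self.true_shifts),
            valid_mask=None if self.valid_mask is None else self.valid_mask.copy(),
        )
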