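"""File formats: multi-page TIFF image sets with JSON sidecars, CSV tables,
JSON reports. All round-trips are lossless."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imageset import ImageSet

__all__ = [
    "write_imageset",
    "read_imageset",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
]

SIDECAR_NAME = "imageset.json"


def write_imageset(image_set: ImageSet, directory: str | Path, suffix: str = "") -> Path:
    """Write one multi-page TIFF per round (page order = channel order) plus a
    JSON sidecar with rounds, channels, true shifts, pixel size and field id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rounds_meta = []
    for r, rnd in enumerate(image_set.rounds):
        fname = f"{image_set.field_id}_round{r + 1}{suffix}.tif"
        pages = np.stack([np.asarray(rnd[c]) for c in rnd])
        tifffile.imwrite(directory / fname, pages, photometric="minisblack")
        meta = {"file": fname, "channels": list(rnd)}
        if image_set.true_shifts is not None:
            meta["true_shift"] = list(image_set.true_shifts[r])
        rounds_meta.append(meta)
    sidecar = {
        "rounds": rounds_meta,
        "pixel_um": image_set.pixel_um,
        "field_id": image_set.field_id,
    }
    path = directory / f"{image_set.field_id}{suffix}.json"
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_imageset(sidecar_path: str | Path) -> ImageSet:
    """Read an ImageSet from its JSON sidecar; validates page/channel counts."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    for key in ("rounds", "pixel_um", "field_id"):
        if key not in meta:
            raise ValueError(f"malformed sidecar {sidecar_path.name}: missing field {key!r}")
    rounds: list[dict[str, np.ndarray]] = []
    shifts: list[tuple[float, float]] | None = []
    for r, rmeta in enumerate(meta["rounds"]):
        for key in ("file", "channels"):
            if key not in rmeta:
                raise ValueError(
                    f"malformed sidecar {sidecar_path.name}: round {r + 1} missing {key!r}"
                )
        pages = tifffile.imread(sidecar_path.parent / rmeta["file"])
        if pages.ndim == 2:
            pages = pages[None]
        channels = rmeta["channels"]
        if len(pages) != len(channels):
            raise ValueError(
                f"round {r + 1}: TIFF has {len(pages)} pages but sidecar lists "
                f"{len(channels)} channels"
            )
        rounds.append({c: pages[i] for i, c in enumerate(channels)})
        if "true_shift" in rmeta and shifts is not None:
            shifts.append(tuple(rmeta["true_shift"]))
        else:
            shifts = None
    return ImageSet(
        rounds=rounds,
        pixel_um=meta["pixel_um"],
        field_id=meta["field_id"],
        true_shifts=shifts,
    )


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """CSV with stable formatting: full float precision so round-trips are
    value-identical and reruns byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
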