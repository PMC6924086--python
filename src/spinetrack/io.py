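"""Image and table I/O used across the CLI: PNG/TIFF/BMP grayscale frames,
CSV tables, diffable JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .datatypes import DiscTrack, GrayImage
from .errors import DataError


def read_image(path, mm_per_px: Optional[float] = None) -> GrayImage:
    """Read a PNG/TIFF/BMP frame; color inputs are converted by channel average."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise DataError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return GrayImage(arr.astype(float), mm_per_px=mm_per_px)


def write_image(path, img: GrayImage, bits: int = 8) -> None:
    """Write a grayscale image as 8- or 16-bit PNG/TIFF."""
    path = Path(path)
    if bits == 8:
        data = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
    elif bits == 16:
        data = np.clip(np.rint(img.pixels * 257.0), 0, 65535).astype(np.uint16)
    else:
        raise DataError("bits must be 8 or 16")
    iio.imwrite(path, data)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(Path(path), index=False)


def dump_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def tracks_to_frame(tracks: Sequence[DiscTrack]) -> pd.DataFrame:
    """Flatten tracks into a CSV-ready table (frame, disc_id, x_px, y_px, pixel_count)."""
    rows = []
    for tr in tracks:
        for det in tr.detections:
            rows.append(
                {
                    "frame": det.frame_id,
                    "disc_id": tr.disc_id,
                    "x_px": det.center[0],
                    "y_px": det.center[1],
                    "pixel_count": det.pixel_count,
                }
            )
    df = pd.DataFrame(rows, columns=["frame", "disc_id", "x_px", "y_px", "pixel_count"])
    return df.sort_values(["frame", "disc_id"], kind="stable").reset_index(drop=True)
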