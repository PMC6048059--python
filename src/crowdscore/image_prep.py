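"""Prepare core images for crowd presentation: 6x6 tiling, central-16
selection and colour inversion."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

GRID = 6
N_SEGMENTS = GRID * GRID
_PAD_VALUE = 255  # white, stain-background-like


@dataclass
class CoreImage:
    core_id: str
    pixels: np.ndarray  # (H, W, 3) uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise ValueError("pixels must be a non-empty (H, W, 3) raster")
        self.pixels = px


def pad_to_grid(pixels: np.ndarray) -> np.ndarray:
    """Pad the right/bottom edges with white so both dimensions divide by 6."""
    h, w = pixels.shape[:2]
    pad_h = (-h) % GRID
    pad_w = (-w) % GRID
    if pad_h == 0 and pad_w == 0:
        return pixels
    return np.pad(
        pixels,
        ((0, pad_h), (0, pad_w), (0, 0)),
        mode="constant",
        constant_values=_PAD_VALUE,
    )


def tile_core(image: CoreImage | np.ndarray) -> list[np.ndarray]:
    """Split a core raster into 36 tiles, row-major: tile k covers grid row
    k // 6, column k % 6 of the (padded) image."""
    pixels = image.pixels if isinstance(image, CoreImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.size == 0:
        raise ValueError("expected a non-empty (H, W, 3) raster")
    padded = pad_to_grid(pixels)
    th = padded.shape[0] // GRID
    tw = padded.shape[1] // GRID
    return [
        padded[r * th : (r + 1) * th, c * tw : (c + 1) * tw]
        for r in range(GRID)
        for c in range(GRID)
    ]


def central_segment_indices() -> list[int]:
    """Row-major indices of the central 4x4 block (rows 1-4, cols 1-4)."""
    return [r * GRID + c for r in range(1, 5) for c in range(1, 5)]


def invert_colors(tile: np.ndarray) -> np.ndarray:
    """Per-channel complement v -> 255 - v (a display transform only)."""
    t = np.asarray(tile)
    if t.dtype != np.uint8:
        t = t.astype(np.uint8)
    return (255 - t).astype(np.uint8)


def write_tiles(image: CoreImage, out_dir, invert: bool = True) -> list[str]:
    """Tile a core and write PNGs named <core_id>_s<index>.png."""
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for idx, tile in enumerate(tile_core(image)):
        if invert:
            tile = invert_colors(tile)
        path = os.path.join(out_dir, f"{image.core_id}_s{idx}.png")
        Image.fromarray(tile).save(path)
        paths.append(path)
    return paths


def read_core_image(core_id: str, path) -> CoreImage:
    from PIL import Image

    with Image.open(path) as im:
        return CoreImage(core_id, np.asarray(im.convert("RGB")))
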