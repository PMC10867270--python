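"""Raster I/O and visualisation.

Masks follow the labelling convention of the source imagery: a paletted PNG
whose index 0 (crop/background) renders black and index 1 (ridge) renders
yellow. ``read_mask`` inverts the palette back to {0, 1} labels. Images are
8-bit RGB PNG/JPEG (via Pillow) or TIFF (via tifffile, so very large aerial
rasters round-trip without PIL's decompression limits).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "render_overlay", "MASK_PALETTE"]

# palette index -> display colour: 0 background (black), 1 ridge (yellow)
MASK_PALETTE = {0: (0, 0, 0), 1: (255, 255, 0)}

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_image(path) -> np.ndarray:
    """Read an RGB image (PNG/JPEG/TIFF) as an H x W x 3 uint8 array."""
    path = Path(path)
    try:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im.convert("RGB"))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise OSError(f"cannot read image {path}: unsupported shape {arr.shape}")
    return np.ascontiguousarray(arr[:, :, :3]).astype(np.uint8)


def write_image(img: np.ndarray, path) -> None:
    """Write an H x W x 3 uint8 image as PNG/JPEG/TIFF by extension."""
    path = Path(path)
    img = np.asarray(img, dtype=np.uint8)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, img)
    else:
        Image.fromarray(img).save(path)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1} label mask as a paletted PNG (0 black, 1 yellow)."""
    mask = np.asarray(mask)
    bad = set(np.unique(mask)) - {0, 1}
    if bad:
        raise ValueError(f"mask contains labels outside {{0, 1}}: {sorted(bad)}")
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = [0] * 768
    for idx, rgb in MASK_PALETTE.items():
        palette[3 * idx:3 * idx + 3] = rgb
    im.putpalette(palette)
    im.save(Path(path))


def read_mask(path) -> np.ndarray:
    """Read a segmentation mask back to an H x W uint8 array over {0, 1}.

    Accepts the paletted PNGs this package writes (indices are the labels)
    and plain single-channel masks using either {0, 1} or {0, 255}.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode == "P":
                arr = np.asarray(im)
            else:
                arr = np.asarray(im.convert("L"))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    vals = set(np.unique(arr))
    if vals <= {0, 1}:
        return arr.astype(np.uint8)
    if vals <= {0, 255}:
        return (arr > 0).astype(np.uint8)
    raise OSError(f"cannot read mask {path}: values {sorted(vals)[:6]} are not binary labels")


def render_overlay(img: np.ndarray | None, mask: np.ndarray,
                   mode: str = "label", alpha: float = 0.5) -> np.ndarray:
    """Visualise a segmentation result.

    ``label`` mode paints ridge pixels yellow on black, the style used for
    ground-truth panels; ``overlay`` mode alpha-blends yellow over the
    source photo (``alpha=0`` returns the photo unchanged).
    """
    mask = np.asarray(mask)
    yellow = np.array(MASK_PALETTE[1], dtype=np.float32)
    if mode == "label":
        out = np.zeros(mask.shape + (3,), dtype=np.uint8)
        out[mask == 1] = MASK_PALETTE[1]
        return out
    if mode == "overlay":
        if img is None:
            raise ValueError("overlay mode requires the source image")
        img = np.asarray(img)
        if img.shape[:2] != mask.shape:
            raise ValueError(f"image {img.shape[:2]} and mask {mask.shape} shapes differ")
        out = img.astype(np.float32).copy()
        sel = mask == 1
        out[sel] = (1.0 - alpha) * out[sel] + alpha * yellow
        return np.clip(out, 0, 255).astype(np.uint8)
    raise ValueError(f"unknown overlay mode {mode!r}")
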