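"""Microscope label-mask I/O, tiling, filtering and a fallback segmenter.

Label masks assign 0 to background and a unique positive integer to each
cell. Masks are normally produced externally (Cellpose or manual
annotation) and consumed here; :func:`fallback_segment` provides a simple
classical segmenter so the pipeline runs end-to-end without external
tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage


@dataclass
class LabelMask:
    """Integer-labelled 2D segmentation image.

    Parameters
    ----------
    labels : ndarray of int, shape (H, W)
        0 = background, k >= 1 = cell k.
    pixel_size_um : float, optional
        Physical pixel pitch in micrometres.
    """

    labels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"label image must be 2D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise TypeError(f"label image must be integer-typed, got {labels.dtype}")
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    def pixel_set(self, cell_id: int) -> np.ndarray:
        """(n, 2) array of (row, col) pixels belonging to ``cell_id``."""
        rows, cols = np.nonzero(self.labels == cell_id)
        return np.column_stack([rows, cols])


def read_mask(path: str | Path, pixel_size_um: float | None = None) -> LabelMask:
    """Read a TIFF/PNG integer label image. Float images are rejected."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(
            f"{path} has pixel type {arr.dtype}; label masks must be integer images"
        )
    return LabelMask(arr, pixel_size_um=pixel_size_um)


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask; round-trips bit-exactly through :func:`read_mask`."""
    path = Path(path)
    arr = mask.labels
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)
    return path


@dataclass
class TiledImage:
    """2D image cut into a regular grid of tiles, with padding bookkeeping."""

    tiles: list[np.ndarray]
    grid: tuple[int, int]
    original_shape: tuple[int, int]
    pad: tuple[int, int] = (0, 0)


def tile_image(image: np.ndarray, grid: tuple[int, int] = (2, 2)) -> TiledImage:
    """Cut ``image`` into ``grid`` tiles (row-major order).

    If the dimensions are not divisible by the grid, the image is
    zero-padded at the bottom/right and the padding recorded so
    :func:`untile_image` reassembles the original exactly.
    """
    image = np.asarray(image)
    gr, gc = grid
    h, w = image.shape[:2]
    pad_r = (-h) % gr
    pad_c = (-w) % gc
    if pad_r or pad_c:
        pad_width = [(0, pad_r), (0, pad_c)] + [(0, 0)] * (image.ndim - 2)
        padded = np.pad(image, pad_width)
    else:
        padded = image
    th, tw = padded.shape[0] // gr, padded.shape[1] // gc
    tiles = [
        padded[i * th : (i + 1) * th, j * tw : (j + 1) * tw].copy()
        for i in range(gr)
        for j in range(gc)
    ]
    return TiledImage(tiles=tiles, grid=grid, original_shape=(h, w), pad=(pad_r, pad_c))


def untile_image(tiled: TiledImage) -> np.ndarray:
    """Inverse of :func:`tile_image`; bit-exact."""
    gr, gc = tiled.grid
    rows = [np.concatenate(tiled.tiles[i * gc : (i + 1) * gc], axis=1) for i in range(gr)]
    full = np.concatenate(rows, axis=0)
    h, w = tiled.original_shape
    return full[:h, :w]


def fallback_segment(
    image: np.ndarray,
    smooth_sigma: float = 2.0,
    threshold: float | None = None,
    min_area: int = 9,
) -> LabelMask:
    """Classical segmenter: Gaussian smooth, threshold, connected components.

    ``threshold=None`` uses Otsu on the smoothed image. Components smaller
    than ``min_area`` pixels are dropped; surviving components get
    sequential labels 1..n.
    """
    from skimage.filters import threshold_otsu

    image = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(image, smooth_sigma) if smooth_sigma > 0 else image
    if threshold is None:
        if smoothed.max() == smoothed.min():
            return LabelMask(np.zeros(image.shape, dtype=np.int32))
        threshold = threshold_otsu(smoothed)
    fg = smoothed > threshold
    labelled, n = ndimage.label(fg)
    if n == 0:
        return LabelMask(labelled.astype(np.int32))
    areas = ndimage.sum_labels(np.ones_like(labelled), labelled, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    out = np.zeros_like(labelled, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        out[labelled == old_id] = new_id
    return LabelMask(out)


def filter_mask(mask: LabelMask, min_area: int = 0, max_area: float = np.inf) -> LabelMask:
    """Remove cells whose pixel area falls outside [min_area, max_area].

    Surviving cell IDs are unchanged.
    """
    if min_area > max_area:
        raise ValueError(f"min_area ({min_area}) > max_area ({max_area})")
    out = mask.labels.copy()
    for cid in mask.cell_ids:
        area = int(np.count_nonzero(mask.labels == cid))
        if area < min_area or area > max_area:
            out[out == cid] = 0
    return LabelMask(out, pixel_size_um=mask.pixel_size_um)
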