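"""Single-cell selection on the biosensor plane and (t, 8, 8) sample export.

Three strategies pick single cells:

* **M** — cover pixels of manually annotated microscope masks projected
  onto the biosensor grid;
* **P** — the same cover-pixel rule applied to predicted masks;
* **W** — watershed on the kinetic image, seeded by local maxima.

Candidates are filtered on per-cell properties (area, maximum adhesion,
distance from the well edge) and exported as (t, 8, 8) wavelength-shift
videos centered on each cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.segmentation import watershed

from .masks import LabelMask
from .preprocess import WELL_SIZE, WellVideo

CROP = 8
CROP_BEFORE = 3  # rows r-3 .. r+4 put the centroid at index (3, 3)
CROP_AFTER = 4


@dataclass
class CellCandidate:
    well_id: tuple[int, int]
    cell_id: int
    centroid: tuple[int, int]  # biosensor grid pixel
    pixel_set: np.ndarray  # (n, 2) int
    area: int
    max_adhesion: float  # pm, max over time and pixel_set
    edge_distance: float  # px from centroid to nearest well border
    strategy: str  # 'M' | 'P' | 'W'


@dataclass
class SingleCellSample:
    video: np.ndarray  # (t, 8, 8) pm
    label: str | None
    well_id: tuple[int, int]
    cell_id: int
    strategy: str
    centroid: tuple[int, int]
    timespan_min: float


def find_local_maxima(
    kinetic_image: np.ndarray,
    lower_threshold: float = 75.0,
    upper_threshold: float = np.inf,
    min_distance: float = 2.0,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Local maxima of the kinetic image within [lower, upper] thresholds.

    A pixel is a maximum if no pixel within Euclidean ``min_distance``
    exceeds it. Plateau ties are broken lexicographically by (row, col),
    keeping the first. ``exclude`` removes (outlier) pixels from
    consideration. Returns an (n, 2) int array in lexicographic order.
    """
    img = np.asarray(kinetic_image, dtype=float)
    valid = np.isfinite(img)
    if exclude is not None:
        valid &= ~exclude
    H, W = img.shape
    r = int(np.floor(min_distance))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (dy**2 + dx**2) <= min_distance**2
    footprint = disk
    neg_inf = np.full_like(img, -np.inf)
    masked = np.where(valid, img, neg_inf)
    local_max = ndimage.maximum_filter(
        masked, footprint=footprint, mode="constant", cval=-np.inf
    )
    is_peak = valid & (masked == local_max)
    is_peak &= (img >= lower_threshold) & (img <= upper_threshold)
    peaks = np.column_stack(np.nonzero(is_peak))
    # suppress plateau duplicates: keep the lexicographically first of any
    # equal-valued peaks within min_distance of each other
    kept: list[tuple[int, int]] = []
    for p in peaks:  # already lexicographic from nonzero
        pr, pc = int(p[0]), int(p[1])
        if all(
            (pr - q[0]) ** 2 + (pc - q[1]) ** 2 > min_distance**2
            or img[pr, pc] != img[q[0], q[1]]
            for q in kept
        ):
            kept.append((pr, pc))
    return np.array(kept, dtype=int).reshape(-1, 2)


def watershed_segment(
    kinetic_image: np.ndarray,
    seeds: np.ndarray,
    lower_threshold: float = 75.0,
) -> LabelMask:
    """Watershed of the foreground from the given seeds.

    Foreground is the lower-threshold superlevel set of the kinetic image.
    The Euclidean distance transform of the foreground is negated and
    flooded from the seeds; regions partition the foreground with exactly
    one seed each. No seeds yields an empty mask.
    """
    img = np.asarray(kinetic_image, dtype=float)
    foreground = img >= lower_threshold
    labels = np.zeros(img.shape, dtype=np.int32)
    seeds = np.asarray(seeds, dtype=int).reshape(-1, 2)
    if len(seeds) == 0:
        return LabelMask(labels)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds, start=1):
        markers[r, c] = i
    distance = ndimage.distance_transform_edt(foreground)
    labels = watershed(-distance, markers=markers, mask=foreground)
    return LabelMask(labels.astype(np.int32))


def _edge_distance(centroid: tuple[int, int]) -> float:
    r, c = centroid
    return float(min(r, c, WELL_SIZE - 1 - r, WELL_SIZE - 1 - c))


def build_candidates(
    well: WellVideo,
    source: dict[int, np.ndarray] | LabelMask,
    strategy: str,
) -> list[CellCandidate]:
    """One candidate per labelled cell of ``source``.

    ``source`` is either a cover-pixel dict (cell_id -> (n, 2) biosensor
    pixels, strategies M/P) or a biosensor-plane LabelMask (strategy W).
    The centroid is the pixel-set centroid rounded to the nearest grid
    pixel; area, max adhesion and edge distance come from the pixel set
    and the corrected video.
    """
    if isinstance(source, LabelMask):
        sets = {int(cid): source.pixel_set(int(cid)) for cid in source.cell_ids}
    else:
        sets = {int(cid): np.asarray(p, dtype=int) for cid, p in source.items()}
    candidates = []
    for cid in sorted(sets):
        pix = sets[cid]
        if pix.size == 0:
            continue
        cent = np.round(pix.mean(axis=0)).astype(int)
        cent = (int(np.clip(cent[0], 0, WELL_SIZE - 1)), int(np.clip(cent[1], 0, WELL_SIZE - 1)))
        max_adh = float(well.video[:, pix[:, 0], pix[:, 1]].max())
        candidates.append(
            CellCandidate(
                well_id=well.well_id,
                cell_id=cid,
                centroid=cent,
                pixel_set=pix,
                area=int(len(pix)),
                max_adhesion=max_adh,
                edge_distance=_edge_distance(cent),
                strategy=strategy,
            )
        )
    return candidates


def filter_candidates(
    candidates: list[CellCandidate],
    min_area: int = 1,
    max_area: float = np.inf,
    min_max_adhesion: float = 0.0,
    min_edge_distance: float = 4.0,
) -> list[CellCandidate]:
    """Keep candidates satisfying all property bounds; order preserved."""
    if min_area > max_area:
        raise ValueError("min_area exceeds max_area")
    if min(min_area, min_max_adhesion, min_edge_distance) < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        c
        for c in candidates
        if min_area <= c.area <= max_area
        and c.max_adhesion >= min_max_adhesion
        and c.edge_distance >= min_edge_distance
    ]


def extract_sample(
    well: WellVideo,
    candidate: CellCandidate,
    timespan_min: float | None = None,
    label: str | None = None,
) -> SingleCellSample:
    """Crop the (t, 8, 8) neighborhood of a candidate.

    Rows r-3..r+4 and cols c-3..c+4 put the centroid at index (3, 3).
    Frames are truncated to the first ``timespan_min`` minutes of the
    re-zeroed timeline (None keeps all frames). Pixels outside the
    candidate's pixel set are kept, not zeroed.
    """
    r, c = candidate.centroid
    if not (CROP_BEFORE <= r <= WELL_SIZE - 1 - CROP_AFTER) or not (
        CROP_BEFORE <= c <= WELL_SIZE - 1 - CROP_AFTER
    ):
        raise ValueError(f"centroid {candidate.centroid} too close to the well border")
    if timespan_min is None:
        t_end = len(well.timeline)
    else:
        t_end = int(np.searchsorted(well.timeline, timespan_min * 60.0, side="right"))
        if t_end == 0:
            raise ValueError("timespan shorter than one frame")
    crop = well.video[:t_end, r - CROP_BEFORE : r + CROP_AFTER + 1,
                      c - CROP_BEFORE : c + CROP_AFTER + 1]
    span = well.timeline[t_end - 1] / 60.0
    return SingleCellSample(
        video=crop.copy(),
        label=label,
        well_id=candidate.well_id,
        cell_id=candidate.cell_id,
        strategy=candidate.strategy,
        centroid=candidate.centroid,
        timespan_min=float(span),
    )


def export_samples(samples: list[SingleCellSample], directory: str | Path) -> pd.DataFrame:
    """Write one multi-frame TIFF per sample plus a manifest CSV.

    Returns the manifest with columns (path, label, well_row, well_col,
    cell_id, strategy). Videos round-trip bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        name = f"well_r{s.well_id[0]}c{s.well_id[1]}_cell{s.cell_id}_{s.strategy}.tiff"
        tifffile.imwrite(directory / name, s.video.astype(np.float32))
        rows.append(
            {
                "path": name,
                "label": s.label,
                "well_row": s.well_id[0],
                "well_col": s.well_id[1],
                "cell_id": s.cell_id,
                "strategy": s.strategy,
            }
        )
    manifest = pd.DataFrame(rows, columns=["path", "label", "well_row", "well_col", "cell_id", "strategy"])
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def load_samples(directory: str | Path) -> tuple[np.ndarray, list]:
    """Read exported samples back as (X, labels) using the manifest."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    videos = [tifffile.imread(directory / p) for p in manifest["path"]]
    return np.asarray(videos), manifest["label"].tolist()
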