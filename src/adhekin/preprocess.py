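"""Raw biosensor mosaic -> per-well, corrected wavelength-shift videos.

The instrument exports one (T', 240, 320) wavelength-shift video covering
12 wells in a 3 x 4 arrangement (80 x 80 px each) together with a frame
timeline. Preprocessing proceeds well by well:

1. split the mosaic into wells;
2. trim to the adhesion phase, found from the pipetting gap in the
   timeline;
3. offset-correct by subtracting the first trimmed frame;
4. mask outlier pixels (well-boundary artifacts) outside a 3-sigma band
   of the reference image;
5. pick background pixels below the 75 pm foreground threshold and
   subtract their per-frame mean (removes common-mode drift).

The "reference image" used for thresholding and outlier statistics is the
per-pixel maximum over time of the offset-corrected video, which is robust
to cells that adhere late in the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

WELL_SIZE = 80
MOSAIC_SHAPE = (240, 320)
GRID = (3, 4)
FOREGROUND_THRESHOLD_PM = 75.0


@dataclass
class RawRecording:
    """The instrument's raw export: mosaic video + timeline."""

    video: np.ndarray  # (T', 240, 320) pm
    timeline: np.ndarray  # (T',) seconds, strictly increasing

    def __post_init__(self) -> None:
        self.video = np.asarray(self.video, dtype=float)
        self.timeline = np.asarray(self.timeline, dtype=float)
        if self.video.ndim != 3 or self.video.shape[1:] != MOSAIC_SHAPE:
            raise ValueError(
                f"mosaic video must be (T, 240, 320), got {self.video.shape}"
            )
        if len(self.timeline) != len(self.video):
            raise ValueError("timeline length must match frame count")
        if np.any(np.diff(self.timeline) <= 0):
            raise ValueError("timeline must be strictly increasing")

    @classmethod
    def from_files(cls, video_path: str | Path, timeline_path: str | Path) -> "RawRecording":
        video = tifffile.imread(video_path)
        timeline = pd.read_csv(timeline_path)["t_seconds"].to_numpy(float)
        return cls(video=video, timeline=timeline)


@dataclass
class WellVideo:
    """One well's video with its correction state."""

    well_id: tuple[int, int]
    video: np.ndarray  # (T, 80, 80) pm
    timeline: np.ndarray  # (T,) seconds, re-zeroed at adhesion start once trimmed
    outlier_mask: np.ndarray = field(default=None)  # True = excluded pixel
    background_pixels: np.ndarray | None = None  # (n, 2) int

    def __post_init__(self) -> None:
        self.video = np.asarray(self.video, dtype=float)
        if self.video.shape[1:] != (WELL_SIZE, WELL_SIZE):
            raise ValueError(f"well video must be (T, 80, 80), got {self.video.shape}")
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros((WELL_SIZE, WELL_SIZE), dtype=bool)

    def reference_image(self) -> np.ndarray:
        """Per-pixel max over time (the cell adhesion image)."""
        return self.video.max(axis=0)


def split_wells(raw: RawRecording) -> list[WellVideo]:
    """Partition the (T, 240, 320) mosaic into 12 (T, 80, 80) wells.

    Well (i, j) is ``video[:, 80i:80(i+1), 80j:80(j+1)]``; concatenating
    the wells back reproduces the mosaic exactly.
    """
    wells = []
    for i in range(GRID[0]):
        for j in range(GRID[1]):
            sub = raw.video[:, i * WELL_SIZE : (i + 1) * WELL_SIZE,
                            j * WELL_SIZE : (j + 1) * WELL_SIZE]
            wells.append(WellVideo(well_id=(i, j), video=sub.copy(),
                                   timeline=raw.timeline.copy()))
    return wells


def detect_adhesion_start(timeline: np.ndarray, gap_factor: float = 10.0) -> int:
    """Index of the first frame after the pipetting gap.

    Looks for the largest inter-frame interval exceeding
    ``gap_factor`` x the median interval. The pipetting pause is minutes
    long against scans of a few seconds, so the gap dominates.
    """
    timeline = np.asarray(timeline, dtype=float)
    if len(timeline) < 3:
        raise ValueError("need at least 3 timestamps to detect the adhesion start")
    intervals = np.diff(timeline)
    median = np.median(intervals)
    qualifying = np.flatnonzero(intervals > gap_factor * median)
    if qualifying.size == 0:
        raise ValueError(
            "no pipetting gap found in the timeline; pass the start index manually"
        )
    largest = qualifying[np.argmax(intervals[qualifying])]
    return int(largest) + 1


def trim_well(well: WellVideo, start: int, end: int | None = None) -> WellVideo:
    """Cut the well to [start, end) and re-zero the timeline at the start."""
    end = len(well.timeline) if end is None else end
    return replace(
        well,
        video=well.video[start:end],
        timeline=well.timeline[start:end] - well.timeline[start],
    )


def offset_correct(well: WellVideo) -> WellVideo:
    """Subtract the first frame pixel-wise; frame 0 becomes all zeros."""
    return replace(well, video=well.video - well.video[0])


def mask_outliers(well: WellVideo, k: float = 3.0) -> WellVideo:
    """Mask pixels outside mean +/- k*std of the reference image.

    Statistics are computed over currently-unmasked pixels of the
    per-pixel-max reference image; a masked pixel is excluded for all
    frames thereafter. A degenerate zero std masks nothing.
    """
    ref = well.reference_image()
    valid = ~well.outlier_mask
    mu = ref[valid].mean()
    sd = ref[valid].std()
    new_mask = well.outlier_mask.copy()
    if sd > 0:
        new_mask |= np.abs(ref - mu) > k * sd
    return replace(well, outlier_mask=new_mask)


def select_background_pixels(
    well: WellVideo,
    threshold: float = FOREGROUND_THRESHOLD_PM,
    n: int = 100,
    min_dist_fg: float = 2.0,
    min_dist_bg: float = 2.0,
    center_sigma: float = 20.0,
    min_candidates: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Pseudorandomly pick up to ``n`` background pixels.

    Candidates are unmasked pixels of the reference image below the
    foreground ``threshold`` and at least ``min_dist_fg`` px (Euclidean)
    from every foreground pixel. Pixels are drawn without replacement with
    probability decaying with distance from the well center (Gaussian,
    ``center_sigma``), rejecting picks within ``min_dist_bg`` of an
    already-selected pixel. Deterministic for a fixed seed.
    """
    from scipy.ndimage import distance_transform_edt

    ref = well.reference_image()
    foreground = (ref >= threshold) & ~well.outlier_mask
    # distance from each pixel to the nearest foreground pixel
    dist_fg = distance_transform_edt(~foreground)
    candidates = (~well.outlier_mask) & (ref < threshold) & (dist_fg >= min_dist_fg)
    rows, cols = np.nonzero(candidates)
    if rows.size < min_candidates:
        raise ValueError(
            f"only {rows.size} background candidates; well too confluent"
        )
    center = (WELL_SIZE - 1) / 2.0
    d2 = (rows - center) ** 2 + (cols - center) ** 2
    weights = np.exp(-d2 / (2 * center_sigma**2))
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    order = rng.choice(rows.size, size=rows.size, replace=False, p=weights)
    chosen: list[tuple[int, int]] = []
    for idx in order:
        p = (int(rows[idx]), int(cols[idx]))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_dist_bg**2 for q in chosen):
            chosen.append(p)
            if len(chosen) == n:
                break
    return np.array(chosen, dtype=int).reshape(-1, 2)


def correct_background(well: WellVideo, pixels: np.ndarray) -> WellVideo:
    """Subtract the per-frame mean over background pixels from every pixel.

    Removes temporal drift common to the whole well; afterwards the mean
    of every frame over the background pixels is zero to float precision.
    """
    pixels = np.asarray(pixels, dtype=int)
    if pixels.size == 0:
        raise ValueError("background pixel list is empty")
    bg = well.video[:, pixels[:, 0], pixels[:, 1]].mean(axis=1)
    return replace(well, video=well.video - bg[:, None, None],
                   background_pixels=pixels)


def preprocess_well(
    well: WellVideo,
    start: int,
    end: int | None = None,
    k_sigma: float = 3.0,
    threshold: float = FOREGROUND_THRESHOLD_PM,
    n_background: int = 100,
    min_dist_fg: float = 2.0,
    min_dist_bg: float = 2.0,
    seed: int = 0,
) -> WellVideo:
    """Trim -> offset -> outlier-mask -> background-correct one well."""
    well = trim_well(well, start, end)
    well = offset_correct(well)
    well = mask_outliers(well, k=k_sigma)
    pixels = select_background_pixels(
        well, threshold=threshold, n=n_background,
        min_dist_fg=min_dist_fg, min_dist_bg=min_dist_bg, seed=seed,
    )
    return correct_background(well, pixels)


def preprocess_recording(
    raw: RawRecording,
    start: int | None = None,
    gap_factor: float = 10.0,
    seed: int = 0,
    **well_kwargs,
) -> list[WellVideo]:
    """Full preprocessing of a raw mosaic recording into 12 corrected wells."""
    if start is None:
        start = detect_adhesion_start(raw.timeline, gap_factor=gap_factor)
    wells = split_wells(raw)
    out = []
    for w_index, well in enumerate(wells):
        out.append(preprocess_well(well, start=start, seed=seed + w_index, **well_kwargs))
    return out
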