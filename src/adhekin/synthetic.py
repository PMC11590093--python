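"""Synthetic adhesion experiments with known ground truth.

Emulates a 12-well resonant waveguide grating (RWG) recording paired with
per-well phase-contrast microscope images:

* a wavelength-shift mosaic of shape (T', 240, 320) covering the wells in
  a 3 x 4 arrangement at 25 um pitch (80 x 80 px per well), in picometres;
* a timeline with a pipetting gap separating baseline frames from the
  adhesion phase;
* per-well microscope images at ``true_scale`` times the biosensor
  resolution, with integer ground-truth label masks (ellipses), related to
  the biosensor plane by a known scale+translation transform.

Each cell contributes a saturating-exponential adhesion signal

    A * (1 - exp(-k * t)) * G(p; centroid, sigma)

with ``A`` the plateau amplitude in pm, ``k`` the adhesion rate in 1/min,
and ``G`` an isotropic spatial Gaussian whose width is chosen so that a
~150 pm cell exceeds the 75 pm foreground threshold over roughly a
3 x 3 pixel block, matching what the instrument resolves. Additive
Gaussian sensor noise and an optional linear per-frame drift complete the
signal model. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as draw_ellipse

from .masks import LabelMask, write_mask
from .projection import ProjectionTransform

WELL_SHAPE = (80, 80)
FOREGROUND_THRESHOLD_PM = 75.0

WellId = tuple[int, int]


@dataclass
class KineticParams:
    """Per-cell-type adhesion kinetics: plateau amplitude and rate."""

    amplitude_pm: float
    rate_per_min: float
    onset_jitter_min: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_pm <= 0 or self.rate_per_min <= 0:
            raise ValueError("amplitude and rate must be strictly positive")
        if self.onset_jitter_min < 0:
            raise ValueError("onset jitter must be non-negative")


def default_cell_types() -> dict[str, KineticParams]:
    """Three well-separated synthetic cell types.

    Plateau amplitudes are spaced by 50 pm, five times the default 10 pm
    sensor noise, so the types are separable from their kinetics. All
    amplitudes sit high enough above the 75 pm foreground threshold that
    each cell's superlevel footprint covers ~3 x 3 pixels, the occupancy
    the instrument resolves for adhered cells.
    """
    return {
        "typeA": KineticParams(amplitude_pm=140.0, rate_per_min=0.08, onset_jitter_min=2.0),
        "typeB": KineticParams(amplitude_pm=190.0, rate_per_min=0.06, onset_jitter_min=2.0),
        "typeC": KineticParams(amplitude_pm=240.0, rate_per_min=0.05, onset_jitter_min=2.0),
    }


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic experiment.

    The defaults describe a desk-scale recording: 40 adhesion frames at
    135 s sampling (a temporally downsampled 90 min measurement), 5
    baseline frames, a 30 min pipetting gap, and a microscope plane at
    10x the biosensor resolution.
    """

    n_wells: int = 4
    grid: tuple[int, int] = (3, 4)
    n_frames: int = 40  # adhesion-phase frames
    n_baseline_frames: int = 5
    frame_interval_s: float = 135.0
    n_cells_per_well: int = 10
    cell_types: dict[str, KineticParams] = field(default_factory=default_cell_types)
    footprint_sigma: float = 1.3  # biosensor px
    noise_sigma: float = 10.0  # pm
    drift_pm: float = 0.0  # peak of a linear global baseline drift over the adhesion phase
    true_scale: float = 10.0  # microscope px per biosensor px
    true_translation: tuple[float, float] = (6.0, 9.0)
    pipette_gap_s: float = 1800.0
    seed: int = 0
    min_cell_separation: float = 6.0  # biosensor px between centroids
    edge_margin: float = 8.0  # centroid distance from well border
    overlap_retries: int = 500

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if self.n_wells > rows * cols:
            raise ValueError(f"{self.n_wells} wells do not fit a {self.grid} grid")
        if self.n_cells_per_well < 0:
            raise ValueError("n_cells_per_well must be >= 0")
        if self.footprint_sigma <= 0 or self.noise_sigma < 0:
            raise ValueError("footprint_sigma must be > 0 and noise_sigma >= 0")
        if self.true_scale <= 1:
            raise ValueError("true_scale must exceed 1 (microscope is finer)")
        if self.n_frames < 1 or self.n_baseline_frames < 1:
            raise ValueError("need at least one baseline and one adhesion frame")
        for name, kp in self.cell_types.items():
            if not isinstance(kp, KineticParams):
                raise TypeError(f"cell type {name!r} must map to KineticParams")

    @property
    def transform(self) -> ProjectionTransform:
        return ProjectionTransform(
            scale=self.true_scale, translation=np.asarray(self.true_translation)
        )


@dataclass
class GroundTruth:
    """Everything the generator knows about the experiment it built."""

    cells: pd.DataFrame  # well_row, well_col, cell_id, cell_type, b_row, b_col, m_row, m_col
    footprints_biosensor: dict[tuple[WellId, int], np.ndarray]  # 75 pm superlevel sets
    footprints_microscope: dict[tuple[WellId, int], np.ndarray]  # ellipse pixel sets
    transform: ProjectionTransform
    adhesion_start_index: int


@dataclass
class SyntheticExperiment:
    video: np.ndarray  # (T', 240, 320) float32 pm
    timeline: np.ndarray  # (T',) seconds
    microscope_images: dict[WellId, np.ndarray]
    masks: dict[WellId, LabelMask]
    truth: GroundTruth
    config: SyntheticConfig


def _place_centroids(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Sample non-overlapping cell centroids inside one well."""
    lo, hi = cfg.edge_margin, WELL_SHAPE[0] - cfg.edge_margin
    placed: list[np.ndarray] = []
    for _ in range(cfg.n_cells_per_well):
        for _attempt in range(cfg.overlap_retries):
            p = rng.uniform(lo, hi, size=2)
            if all(np.linalg.norm(p - q) >= cfg.min_cell_separation for q in placed):
                placed.append(p)
                break
        else:
            raise RuntimeError(
                "could not place non-overlapping cells; lower n_cells_per_well "
                "or min_cell_separation"
            )
    return np.array(placed).reshape(-1, 2)


def _kinetic_footprint(centroid: np.ndarray, amplitude: float, sigma: float) -> np.ndarray:
    """Pixels whose noiseless end-of-recording signal exceeds 75 pm."""
    rr, cc = np.mgrid[0 : WELL_SHAPE[0], 0 : WELL_SHAPE[1]]
    d2 = (rr - centroid[0]) ** 2 + (cc - centroid[1]) ** 2
    level = amplitude * np.exp(-d2 / (2 * sigma**2))
    rows, cols = np.nonzero(level >= FOREGROUND_THRESHOLD_PM)
    return np.column_stack([rows, cols])


def _build_timeline(cfg: SyntheticConfig) -> tuple[np.ndarray, int]:
    nb, nf, dt = cfg.n_baseline_frames, cfg.n_frames, cfg.frame_interval_s
    base = np.arange(nb) * dt
    adhesion = base[-1] + cfg.pipette_gap_s + np.arange(nf) * dt
    return np.concatenate([base, adhesion]), nb


def generate_experiment(config: SyntheticConfig) -> SyntheticExperiment:
    """Build a full synthetic experiment with known ground truth.

    Bit-identical output for identical configs (including seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid_rows, grid_cols = cfg.grid
    mosaic_shape = (grid_rows * WELL_SHAPE[0], grid_cols * WELL_SHAPE[1])
    timeline, start = _build_timeline(cfg)
    T_total = len(timeline)
    t_min = (timeline[start:] - timeline[start]) / 60.0  # minutes since adhesion start

    video = np.zeros((T_total,) + mosaic_shape, dtype=np.float64)
    type_names = list(cfg.cell_types)
    records: list[dict] = []
    fp_b: dict[tuple[WellId, int], np.ndarray] = {}
    fp_m: dict[tuple[WellId, int], np.ndarray] = {}
    micro_images: dict[WellId, np.ndarray] = {}
    mask_images: dict[WellId, LabelMask] = {}
    transform = cfg.transform

    # microscope frame large enough to hold the projected sensor area
    m_extent = int(np.ceil(cfg.true_scale * (WELL_SHAPE[0] - 0.5) + max(cfg.true_translation) + 2))
    m_shape = (m_extent, m_extent)

    well_ids = [
        (i, j) for i in range(grid_rows) for j in range(grid_cols)
    ][: cfg.n_wells]

    rr_w, cc_w = np.mgrid[0 : WELL_SHAPE[0], 0 : WELL_SHAPE[1]]
    for well_id in well_ids:
        wi, wj = well_id
        centroids = _place_centroids(rng, cfg)
        micro = rng.normal(30.0, 2.0, size=m_shape)
        labels = np.zeros(m_shape, dtype=np.int32)
        well_signal = np.zeros((cfg.n_frames,) + WELL_SHAPE)
        for cell_idx in range(cfg.n_cells_per_well):
            cid = cell_idx + 1
            ctype = type_names[int(rng.integers(len(type_names)))]
            kp = cfg.cell_types[ctype]
            b_cent = centroids[cell_idx]
            m_cent = transform.forward(b_cent)
            onset = rng.uniform(0.0, kp.onset_jitter_min) if kp.onset_jitter_min else 0.0
            kinetic = kp.amplitude_pm * (1.0 - np.exp(-kp.rate_per_min * np.clip(t_min - onset, 0, None)))
            kinetic[t_min < onset] = 0.0
            d2 = (rr_w - b_cent[0]) ** 2 + (cc_w - b_cent[1]) ** 2
            G = np.exp(-d2 / (2 * cfg.footprint_sigma**2))
            well_signal += kinetic[:, None, None] * G[None]
            # microscope ellipse sized to match the 75 pm kinetic footprint
            r75 = cfg.footprint_sigma * np.sqrt(
                2 * max(np.log(kp.amplitude_pm / FOREGROUND_THRESHOLD_PM), 0.05)
            )
            ax_r = cfg.true_scale * r75 * rng.uniform(0.9, 1.1)
            ax_c = cfg.true_scale * r75 * rng.uniform(0.9, 1.1)
            err, ecc = draw_ellipse(
                m_cent[0], m_cent[1], ax_r, ax_c,
                rotation=rng.uniform(0, np.pi), shape=m_shape,
            )
            labels[err, ecc] = cid
            micro[err, ecc] = rng.normal(120.0, 4.0, size=len(err))
            reached = kp.amplitude_pm * (
                1.0 - np.exp(-kp.rate_per_min * max(t_min[-1] - onset, 0.0))
            )
            fp_b[(well_id, cid)] = _kinetic_footprint(b_cent, reached, cfg.footprint_sigma)
            fp_m[(well_id, cid)] = np.column_stack([err, ecc])
            records.append(
                {
                    "well_row": wi, "well_col": wj, "cell_id": cid, "cell_type": ctype,
                    "b_row": b_cent[0], "b_col": b_cent[1],
                    "m_row": m_cent[0], "m_col": m_cent[1],
                }
            )
        r0, c0 = wi * WELL_SHAPE[0], wj * WELL_SHAPE[1]
        video[start:, r0 : r0 + WELL_SHAPE[0], c0 : c0 + WELL_SHAPE[1]] += well_signal
        micro_images[well_id] = np.clip(micro, 0, 255).astype(np.uint8)
        mask_images[well_id] = LabelMask(labels)

    if cfg.drift_pm and cfg.n_frames > 1:
        ramp = cfg.drift_pm * np.arange(cfg.n_frames) / (cfg.n_frames - 1)
        video[start:] += ramp[:, None, None]
    if cfg.noise_sigma:
        video += rng.normal(0.0, cfg.noise_sigma, size=video.shape)

    columns = ["well_row", "well_col", "cell_id", "cell_type", "b_row", "b_col", "m_row", "m_col"]
    cells = pd.DataFrame(records, columns=columns)
    truth = GroundTruth(
        cells=cells,
        footprints_biosensor=fp_b,
        footprints_microscope=fp_m,
        transform=transform,
        adhesion_start_index=start,
    )
    return SyntheticExperiment(
        video=video.astype(np.float32),
        timeline=timeline,
        microscope_images=micro_images,
        masks=mask_images,
        truth=truth,
        config=cfg,
    )


def generate_cell_samples(
    cell_types: dict[str, KineticParams],
    n_per_type: int,
    n_frames: int = 40,
    frame_interval_s: float = 135.0,
    footprint_sigma: float = 1.3,
    noise_sigma: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled (t, 8, 8) single-cell samples directly.

    A fast path for classifier experiments: each sample is one cell
    centered (with sub-pixel jitter) in its own 8 x 8 crop, following the
    same signal model as :func:`generate_experiment`, without building a
    mosaic. Returns ``(X, y)`` with X of shape (N, t, 8, 8) and y integer
    labels ordered like ``cell_types``.
    """
    rng = np.random.default_rng(seed)
    t_min = np.arange(n_frames) * frame_interval_s / 60.0
    rr, cc = np.mgrid[0:8, 0:8]
    X, y = [], []
    for label, (name, kp) in enumerate(cell_types.items()):
        for _ in range(n_per_type):
            cent = np.array([3.0, 3.0]) + rng.uniform(-0.5, 0.5, size=2)
            onset = rng.uniform(0.0, kp.onset_jitter_min) if kp.onset_jitter_min else 0.0
            kinetic = kp.amplitude_pm * (1.0 - np.exp(-kp.rate_per_min * np.clip(t_min - onset, 0, None)))
            kinetic[t_min < onset] = 0.0
            d2 = (rr - cent[0]) ** 2 + (cc - cent[1]) ** 2
            G = np.exp(-d2 / (2 * footprint_sigma**2))
            sample = kinetic[:, None, None] * G[None]
            if noise_sigma:
                sample = sample + rng.normal(0.0, noise_sigma, size=sample.shape)
            X.append(sample)
            y.append(label)
    order = rng.permutation(len(X))
    return np.asarray(X, dtype=np.float32)[order], np.asarray(y)[order]


def write_experiment(exp: SyntheticExperiment, directory: str | Path) -> dict:
    """Write an experiment to disk; returns the file manifest.

    Layout: ``mosaic.tiff`` (multi-frame float32), ``timeline.csv``,
    ``well_r{i}c{j}_microscope.tiff`` / ``_mask.tiff`` per well,
    ``ground_truth.csv``, ``transform.json`` and ``manifest.json``.
    Round-trip through :func:`read_experiment` is bit-exact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"wells": [], "n_frames": int(exp.video.shape[0])}

    tifffile.imwrite(directory / "mosaic.tiff", exp.video)
    manifest["mosaic"] = "mosaic.tiff"
    pd.DataFrame(
        {"frame_index": np.arange(len(exp.timeline)), "t_seconds": exp.timeline}
    ).to_csv(directory / "timeline.csv", index=False)
    manifest["timeline"] = "timeline.csv"

    for well_id, img in exp.microscope_images.items():
        wi, wj = well_id
        img_name = f"well_r{wi}c{wj}_microscope.tiff"
        mask_name = f"well_r{wi}c{wj}_mask.tiff"
        tifffile.imwrite(directory / img_name, img)
        write_mask(exp.masks[well_id], directory / mask_name)
        manifest["wells"].append(
            {"well_row": wi, "well_col": wj, "microscope": img_name, "mask": mask_name}
        )

    exp.truth.cells.to_csv(directory / "ground_truth.csv", index=False)
    manifest["ground_truth"] = "ground_truth.csv"
    exp.truth.transform.to_json(directory / "transform.json")
    manifest["transform"] = "transform.json"
    manifest["adhesion_start_index"] = int(exp.truth.adhesion_start_index)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_experiment(directory: str | Path) -> dict:
    """Read back the files written by :func:`write_experiment`."""
    from .masks import read_mask

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = {
        "video": tifffile.imread(directory / manifest["mosaic"]),
        "timeline": pd.read_csv(directory / manifest["timeline"])["t_seconds"].to_numpy(),
        "cells": pd.read_csv(directory / manifest["ground_truth"]),
        "transform": ProjectionTransform.from_json(directory / manifest["transform"]),
        "adhesion_start_index": manifest["adhesion_start_index"],
        "microscope_images": {},
        "masks": {},
    }
    for well in manifest["wells"]:
        wid = (well["well_row"], well["well_col"])
        out["microscope_images"][wid] = tifffile.imread(directory / well["microscope"])
        out["masks"][wid] = read_mask(directory / well["mask"])
    return out
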