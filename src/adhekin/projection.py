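"""Scale-plus-translation registration between biosensor and microscope planes.

The two imaging planes view the same wells at very different pitches (the
biosensor at 25 um/px, the microscope typically an order of magnitude
finer). Because both instruments image the sample without rotating it, the
mapping is restricted to an isotropic scale and a translation:

    m = s * b + t

with ``b`` a biosensor point (row, col), ``m`` the matching microscope
point, ``s > 0`` a scalar and ``t`` a 2-vector. ``s`` is estimated from
the ratio of Euclidean distances between user-picked corresponding points;
``t`` from the mean residual. All coordinates are (row, col), 0-based,
with pixel centers at integer positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .masks import LabelMask


@dataclass
class CoordinatePairs:
    """Paired point picks on the microscope (m) and biosensor (b) planes."""

    m: np.ndarray  # (N, 2) microscope (row, col)
    b: np.ndarray  # (N, 2) biosensor (row, col)

    def __post_init__(self) -> None:
        self.m = np.atleast_2d(np.asarray(self.m, dtype=float))
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        if self.m.shape != self.b.shape or self.m.shape[1] != 2:
            raise ValueError("m and b must both have shape (N, 2)")
        if len(self.m) < 1:
            raise ValueError("at least one coordinate pair is required")

    def __len__(self) -> int:
        return len(self.m)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoordinatePairs":
        df = pd.read_csv(path)
        return cls(
            m=df[["m_row", "m_col"]].to_numpy(float),
            b=df[["b_row", "b_col"]].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "m_row": self.m[:, 0],
                "m_col": self.m[:, 1],
                "b_row": self.b[:, 0],
                "b_col": self.b[:, 1],
            }
        ).to_csv(path, index=False)


@dataclass
class ProjectionTransform:
    """m = scale * b + translation; no rotation or shear."""

    scale: float
    translation: np.ndarray  # (row, col) in microscope px

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)

    def forward(self, points: np.ndarray) -> np.ndarray:
        """Biosensor -> microscope."""
        return self.scale * np.asarray(points, dtype=float) + self.translation

    def inverse(self, points: np.ndarray) -> np.ndarray:
        """Microscope -> biosensor."""
        return (np.asarray(points, dtype=float) - self.translation) / self.scale

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"scale": self.scale, "translation": self.translation.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ProjectionTransform":
        d = json.loads(Path(path).read_text())
        return cls(scale=d["scale"], translation=np.asarray(d["translation"]))


def estimate_transform(
    pairs: CoordinatePairs, nominal_scale: float | None = None
) -> ProjectionTransform:
    """Estimate the scale+translation mapping from point correspondences.

    The scale is the mean, over all unordered pairs of picks (i, j), of the
    microscope/biosensor Euclidean distance ratio ||m_i - m_j|| / ||b_i - b_j||.
    The translation is the mean residual (1/N) sum_i (m_i - s*b_i). With a
    single pick only the translation can be estimated and ``nominal_scale``
    (from device pixel pitches) is required.

    Pairs with coincident biosensor picks (zero denominator) are skipped;
    if every pair is degenerate an error is raised.
    """
    m, b = pairs.m, pairs.b
    if len(pairs) < 2:
        if nominal_scale is None:
            raise ValueError("a single pair needs nominal_scale for the scale term")
        scale = float(nominal_scale)
    else:
        ratios = []
        for i, j in combinations(range(len(pairs)), 2):
            denom = np.linalg.norm(b[i] - b[j])
            if denom == 0.0:
                continue
            ratios.append(np.linalg.norm(m[i] - m[j]) / denom)
        if not ratios:
            raise ValueError("all biosensor point pairs are coincident; cannot scale")
        scale = float(np.mean(ratios))
    translation = (m - scale * b).mean(axis=0)
    return ProjectionTransform(scale=scale, translation=translation)


def project_points(
    points: np.ndarray, transform: ProjectionTransform, direction: str = "b2m"
) -> np.ndarray:
    """Map points between planes; ``direction`` is 'b2m' or 'm2b'."""
    if direction == "b2m":
        return transform.forward(points)
    if direction == "m2b":
        return transform.inverse(points)
    raise ValueError(f"direction must be 'b2m' or 'm2b', got {direction!r}")


def project_mask_to_biosensor(
    mask: LabelMask,
    transform: ProjectionTransform,
    sensor_shape: tuple[int, int] = (80, 80),
) -> tuple[dict[int, np.ndarray], LabelMask]:
    """Project a microscope label mask down to the biosensor grid.

    A biosensor pixel (r, c) covers the unit square [r-0.5, r+0.5) x
    [c-0.5, c+0.5). A pixel belongs to cell k iff at least one microscope
    pixel center of label k inverse-maps into that square. Where two cells
    land on the same biosensor pixel, both cells' pixel sets include it,
    but the single-valued biosensor label image is won by the cell
    contributing more microscope pixels.

    Returns
    -------
    cover : dict cell_id -> (n, 2) int array of biosensor (row, col) pixels
    sensor_mask : LabelMask on the biosensor grid
    """
    H, W = sensor_shape
    counts: dict[tuple[int, int, int], int] = {}
    cover: dict[int, set[tuple[int, int]]] = {}
    for cid in mask.cell_ids:
        pix = mask.pixel_set(cid).astype(float)
        bpix = transform.inverse(pix)
        idx = np.floor(bpix + 0.5).astype(int)  # nearest pixel center
        inside = (idx[:, 0] >= 0) & (idx[:, 0] < H) & (idx[:, 1] >= 0) & (idx[:, 1] < W)
        idx = idx[inside]
        pixset = cover.setdefault(int(cid), set())
        for r, c in idx:
            pixset.add((int(r), int(c)))
            counts[(int(cid), int(r), int(c))] = counts.get((int(cid), int(r), int(c)), 0) + 1
    sensor = np.zeros(sensor_shape, dtype=np.int32)
    best = np.zeros(sensor_shape, dtype=int)
    for (cid, r, c), n in sorted(counts.items()):
        if n > best[r, c]:
            best[r, c] = n
            sensor[r, c] = cid
    cover_arrays = {
        cid: np.array(sorted(pixset), dtype=int).reshape(-1, 2)
        for cid, pixset in cover.items()
        if pixset
    }
    return cover_arrays, LabelMask(sensor)


@dataclass
class SensorCrop:
    """Microscope image cropped to the projected sensor area."""

    image: np.ndarray
    offset: np.ndarray  # (row, col) of the crop origin in the original image
    transform: ProjectionTransform  # adjusted so crop coords = scale*b + translation


def crop_to_sensor(
    image: np.ndarray,
    transform: ProjectionTransform,
    sensor_shape: tuple[int, int] = (80, 80),
) -> SensorCrop:
    """Cut the microscope image to the forward-projected sensor rectangle.

    The sensor extent is the union of its pixel squares,
    [-0.5, H-0.5] x [-0.5, W-0.5] on the biosensor plane. The crop offset
    is folded into the returned transform so projecting points into the
    cropped image stays consistent.
    """
    H, W = sensor_shape
    corners = np.array([[-0.5, -0.5], [H - 0.5, W - 0.5]])
    mcorners = transform.forward(corners)
    r0 = int(np.floor(max(mcorners[0, 0], 0)))
    c0 = int(np.floor(max(mcorners[0, 1], 0)))
    r1 = int(np.ceil(min(mcorners[1, 0], image.shape[0])))
    c1 = int(np.ceil(min(mcorners[1, 1], image.shape[1])))
    if r1 <= r0 or c1 <= c0:
        raise ValueError("projected sensor rectangle does not intersect the image")
    offset = np.array([r0, c0], dtype=float)
    adjusted = ProjectionTransform(
        scale=transform.scale, translation=transform.translation - offset
    )
    return SensorCrop(image=image[r0:r1, c0:c1], offset=offset, transform=adjusted)
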