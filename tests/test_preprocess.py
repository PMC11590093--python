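"""Biosensor preprocessing: well splitting, trimming, corrections."""

import numpy as np
import pytest

from adhekin.preprocess import (
    RawRecording,
    WellVideo,
    correct_background,
    detect_adhesion_start,
    mask_outliers,
    offset_correct,
    preprocess_recording,
    select_background_pixels,
    split_wells,
    trim_well,
)


def _recording(video):
    return RawRecording(video=video, timeline=np.arange(len(video), dtype=float))


def test_split_produces_12_wells_and_reassembles():
    rng = np.random.default_rng(0)
    video = rng.normal(size=(4, 240, 320))
    wells = split_wells(_recording(video))
    assert len(wells) == 12
    assert all(w.video.shape == (4, 80, 80) for w in wells)
    rebuilt = np.zeros_like(video)
    for w in wells:
        i, j = w.well_id
        rebuilt[:, 80 * i : 80 * (i + 1), 80 * j : 80 * (j + 1)] = w.video
    assert np.array_equal(rebuilt, video)


def test_split_well_indexing_matches_mosaic_arithmetic():
    # encode (row, col) in the pixel value and check well corners directly
    rr, cc = np.mgrid[0:240, 0:320]
    video = (rr * 1000 + cc)[None].astype(float)
    for w in split_wells(_recording(video)):
        i, j = w.well_id
        assert w.video[0, 0, 0] == 80 * i * 1000 + 80 * j
        assert w.video[0, 79, 79] == (80 * i + 79) * 1000 + 80 * j + 79


def test_split_rejects_wrong_shape():
    with pytest.raises(ValueError, match="240, 320"):
        RawRecording(video=np.zeros((3, 100, 100)), timeline=np.arange(3.0))


@pytest.mark.parametrize(
    "intervals, expected",
    [
        ([3.0] * 39 + [600.0] + [3.0] * 20, 40),  # one gap before frame 40
        ([3.0] * 10 + [100.0] + [3.0] * 10 + [900.0] + [3.0] * 5, 22),  # largest wins
    ],
)
def test_detect_adhesion_start(intervals, expected):
    timeline = np.concatenate([[0.0], np.cumsum(intervals)])
    assert detect_adhesion_start(timeline) == expected


def test_detect_adhesion_start_requires_gap():
    with pytest.raises(ValueError, match="start index manually"):
        detect_adhesion_start(np.arange(50, dtype=float) * 3.0)


def test_offset_correct_matches_per_pixel_subtraction():
    rng = np.random.default_rng(1)
    video = rng.normal(size=(6, 80, 80))
    well = WellVideo(well_id=(0, 0), video=video, timeline=np.arange(6.0))
    out = offset_correct(well)
    assert np.array_equal(out.video, video - video[0])
    assert np.all(out.video[0] == 0)
    constant = WellVideo(well_id=(0, 0), video=np.ones((4, 80, 80)) * 7,
                         timeline=np.arange(4.0))
    assert np.all(offset_correct(constant).video == 0)


def test_mask_outliers_flags_extreme_pixel_and_is_monotone_in_k():
    rng = np.random.default_rng(2)
    video = rng.normal(0, 1, size=(5, 80, 80))
    video[:, 10, 10] = 1e6
    well = WellVideo(well_id=(0, 0), video=video, timeline=np.arange(5.0))
    masked3 = mask_outliers(well, k=3)
    assert masked3.outlier_mask[10, 10]
    masked4 = mask_outliers(well, k=4)
    assert np.all(masked4.outlier_mask <= masked3.outlier_mask)  # k=3 superset


def test_mask_outliers_uniform_image_masks_nothing():
    well = WellVideo(well_id=(0, 0), video=np.full((3, 80, 80), 5.0),
                     timeline=np.arange(3.0))
    assert not mask_outliers(well).outlier_mask.any()


def test_background_selection_distances_threshold_determinism():
    rng = np.random.default_rng(3)
    video = rng.normal(0, 1, size=(5, 80, 80))
    video[:, 40:46, 40:46] = 200.0  # a foreground patch
    well = WellVideo(well_id=(0, 0), video=video, timeline=np.arange(5.0))
    pix = select_background_pixels(well, n=50, min_dist_fg=2, min_dist_bg=2, seed=9)
    assert len(pix) == 50
    ref = well.reference_image()
    assert np.all(ref[pix[:, 0], pix[:, 1]] < 75.0)
    d = np.linalg.norm(pix[:, None] - pix[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 2.0
    # min_dist_fg from the foreground patch
    fg = np.column_stack(np.nonzero(ref >= 75.0))
    dfg = np.linalg.norm(pix[:, None] - fg[None], axis=-1).min()
    assert dfg >= 2.0
    assert np.array_equal(pix, select_background_pixels(well, n=50, seed=9))
    assert not np.array_equal(pix, select_background_pixels(well, n=50, seed=10))


def test_background_selection_errors_when_confluent():
    video = np.full((3, 80, 80), 500.0)
    video[0] = 0.0
    well = WellVideo(well_id=(0, 0), video=video, timeline=np.arange(3.0))
    with pytest.raises(ValueError, match="confluent"):
        select_background_pixels(well)


def test_correct_background_shifts_and_preserves_contrast():
    rng = np.random.default_rng(4)
    video = rng.normal(size=(6, 80, 80))
    pix = np.array([[0, 0], [0, 1], [1, 0]])
    video[:, pix[:, 0], pix[:, 1]] = 5.0
    well = WellVideo(well_id=(0, 0), video=video, timeline=np.arange(6.0))
    out = correct_background(well, pix)
    assert np.allclose(out.video, video - 5.0)
    # per-frame background mean is zero afterwards
    bg_mean = out.video[:, pix[:, 0], pix[:, 1]].mean(axis=1)
    assert np.abs(bg_mean).max() < 1e-6
    # foreground-background contrast untouched
    contrast_before = video[:, 50, 50] - video[:, pix[:, 0], pix[:, 1]].mean(axis=1)
    contrast_after = out.video[:, 50, 50] - bg_mean
    assert np.allclose(contrast_before, contrast_after)


def test_pipeline_removes_injected_drift():
    """Per-frame drift is removed to below noise_sigma / sqrt(n_bg)."""
    from adhekin.synthetic import SyntheticConfig, generate_experiment

    noise_sigma = 5.0
    cfg = SyntheticConfig(n_wells=1, n_cells_per_well=4, noise_sigma=noise_sigma,
                          drift_pm=10.0, seed=6)
    exp = generate_experiment(cfg)
    raw = RawRecording(video=exp.video, timeline=exp.timeline)
    wells = preprocess_recording(raw, seed=6)
    well = wells[0]
    pix = well.background_pixels
    residual = well.video[:, pix[:, 0], pix[:, 1]].mean(axis=1)
    assert np.abs(residual).max() < 1e-6  # exactly zeroed at the background pixels
    # independent quiet pixels (not in the background set) also end near zero
    ref = well.reference_image()
    quiet = (ref < 20.0) & ~well.outlier_mask
    quiet[pix[:, 0], pix[:, 1]] = False
    resid = np.abs(well.video[:, quiet].mean(axis=1))
    assert resid.max() < noise_sigma / np.sqrt(len(pix)) * 4 + 0.5


def test_noiseless_foreground_matches_ground_truth_footprints(noiseless_experiment):
    exp = noiseless_experiment
    raw = RawRecording(video=exp.video, timeline=exp.timeline)
    start = detect_adhesion_start(raw.timeline)
    assert start == exp.truth.adhesion_start_index
    wells = split_wells(raw)
    for well in wells[:2]:
        corrected = offset_correct(trim_well(well, start))
        fg = np.column_stack(np.nonzero(corrected.reference_image() >= 75.0))
        truth_pixels = set()
        for (wid, cid), pix in exp.truth.footprints_biosensor.items():
            if wid == well.well_id:
                truth_pixels |= {tuple(p) for p in pix}
        assert {tuple(p) for p in fg} == truth_pixels
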