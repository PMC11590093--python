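"""Single-cell selection: maxima, watershed, candidates, crops, export."""

import numpy as np
import pytest

from adhekin.extraction import (
    build_candidates,
    export_samples,
    extract_sample,
    filter_candidates,
    find_local_maxima,
    load_samples,
    watershed_segment,
)
from adhekin.preprocess import WellVideo


def _well(video):
    video = np.asarray(video, dtype=float)
    return WellVideo(well_id=(0, 0), video=video,
                     timeline=np.arange(len(video)) * 60.0)


def _gauss(shape, center, amp, sigma=1.5):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


def brute_force_maxima(img, lo, hi, min_distance):
    """Reference implementation: explicit neighborhood scan."""
    H, W = img.shape
    out = []
    for r in range(H):
        for c in range(W):
            v = img[r, c]
            if not (lo <= v <= hi):
                continue
            is_max = True
            for rr in range(H):
                for cc in range(W):
                    if (rr, cc) == (r, c):
                        continue
                    if (rr - r) ** 2 + (cc - c) ** 2 <= min_distance**2:
                        if img[rr, cc] > v or (img[rr, cc] == v and (rr, cc) < (r, c)
                                               and (rr, cc) in out):
                            is_max = False
                            break
                if not is_max:
                    break
            if is_max:
                out.append((r, c))
    return out


def test_flat_image_has_no_maxima():
    assert len(find_local_maxima(np.zeros((20, 20)), lower_threshold=1.0)) == 0


def test_two_gaussians_found_at_peaks():
    img = _gauss((40, 40), (10, 10), 150) + _gauss((40, 40), (10, 20), 150)
    peaks = find_local_maxima(img, lower_threshold=75, min_distance=3)
    assert {tuple(p) for p in peaks} == {(10, 10), (10, 20)}


def test_maxima_match_brute_force_on_random_images():
    rng = np.random.default_rng(0)
    for _ in range(5):
        img = np.round(rng.uniform(0, 200, size=(20, 20)), 1)
        got = {tuple(p) for p in find_local_maxima(img, 50, 180, min_distance=2)}
        expected = set(brute_force_maxima(img, 50, 180, 2))
        assert got == expected


def test_maxima_threshold_bounds_respected():
    img = _gauss((30, 30), (15, 15), 300)
    assert len(find_local_maxima(img, lower_threshold=75, upper_threshold=200)) == 0
    assert len(find_local_maxima(img, lower_threshold=75)) == 1


def test_watershed_single_blob_single_label():
    img = _gauss((40, 40), (20, 20), 200, sigma=3)
    mask = watershed_segment(img, np.array([[20, 20]]), lower_threshold=75)
    assert mask.n_cells == 1
    assert np.array_equal(mask.labels > 0, img >= 75)


def test_watershed_splits_dumbbell_at_neck():
    img = np.maximum(_gauss((40, 40), (20, 12), 200, sigma=3),
                     _gauss((40, 40), (20, 28), 200, sigma=3))
    mask = watershed_segment(img, np.array([[20, 12], [20, 28]]), lower_threshold=75)
    assert mask.n_cells == 2
    left = mask.labels[:, :20]
    right = mask.labels[:, 20:]
    assert set(np.unique(left)) <= {0, 1}
    assert set(np.unique(right)) <= {0, 2}
    # regions partition the foreground and hold exactly one seed each
    assert np.array_equal(mask.labels > 0, img >= 75)


def test_watershed_no_seeds_empty_mask():
    img = _gauss((30, 30), (15, 15), 200)
    assert watershed_segment(img, np.empty((0, 2)), 75).n_cells == 0


def test_watershed_region_count_equals_seed_count(noiseless_experiment):
    from adhekin.preprocess import (RawRecording, detect_adhesion_start,
                                    offset_correct, split_wells, trim_well)

    exp = noiseless_experiment
    raw = RawRecording(video=exp.video, timeline=exp.timeline)
    start = detect_adhesion_start(raw.timeline)
    well = offset_correct(trim_well(split_wells(raw)[0], start))
    kin = well.reference_image()
    seeds = find_local_maxima(kin, lower_threshold=75, min_distance=2)
    mask = watershed_segment(kin, seeds, 75)
    assert mask.n_cells == len(seeds) == exp.config.n_cells_per_well


def test_build_candidates_counts_and_max_adhesion():
    rng = np.random.default_rng(1)
    video = rng.normal(0, 1, size=(10, 80, 80))
    well = _well(video)
    sets = {1: np.array([[10, 10], [10, 11]]), 5: np.array([[40, 40]])}
    cands = build_candidates(well, sets, "M")
    assert [c.cell_id for c in cands] == [1, 5]
    for c in cands:
        pix = sets[c.cell_id]
        assert c.max_adhesion == pytest.approx(video[:, pix[:, 0], pix[:, 1]].max())
        assert c.area == len(pix)
    assert cands[0].centroid == (10, 10) or cands[0].centroid == (10, 11)
    assert build_candidates(well, {}, "M") == []


def test_filter_candidates_bounds_and_order():
    well = _well(np.zeros((5, 80, 80)))
    sets = {i: np.array([[i, i]]) for i in range(1, 6)}  # edge distance = i
    cands = build_candidates(well, sets, "W")
    assert filter_candidates(cands, min_edge_distance=0, min_area=0) == cands
    survivors = filter_candidates(cands, min_edge_distance=4)
    assert [c.cell_id for c in survivors] == [4, 5]  # column<4 centroids removed
    with pytest.raises(ValueError):
        filter_candidates(cands, min_area=5, max_area=2)


def test_extract_sample_slicing_matches_oracle():
    rng = np.random.default_rng(2)
    video = rng.normal(size=(12, 80, 80))
    well = _well(video)
    for centroid in [(3, 3), (40, 25), (75, 75)]:
        cand = build_candidates(well, {1: np.array([centroid])}, "M")[0]
        sample = extract_sample(well, cand)
        r, c = centroid
        assert np.array_equal(sample.video, video[:, r - 3 : r + 5, c - 3 : c + 5])
        assert sample.video.shape == (12, 8, 8)
    # corner case: centroid (3,3) crops rows/cols 0:8
    cand = build_candidates(well, {1: np.array([[3, 3]])}, "M")[0]
    assert np.array_equal(extract_sample(well, cand).video, video[:, 0:8, 0:8])


def test_extract_sample_rejects_border_centroid():
    well = _well(np.zeros((5, 80, 80)))
    cand = build_candidates(well, {1: np.array([[1, 40]])}, "M")[0]
    with pytest.raises(ValueError, match="border"):
        extract_sample(well, cand)


def test_timespan_variants_are_prefixes():
    rng = np.random.default_rng(3)
    video = rng.normal(size=(90, 80, 80))
    well = _well(video)  # one frame per minute
    cand = build_candidates(well, {1: np.array([[40, 40]])}, "M")[0]
    s30 = extract_sample(well, cand, timespan_min=30)
    s60 = extract_sample(well, cand, timespan_min=60)
    s90 = extract_sample(well, cand, timespan_min=90)
    assert len(s30.video) < len(s60.video) < len(s90.video)
    assert np.array_equal(s60.video[: len(s30.video)], s30.video)
    assert np.array_equal(s90.video[: len(s60.video)], s60.video)


def test_export_round_trip_and_manifest(tmp_path):
    rng = np.random.default_rng(4)
    video = rng.normal(size=(10, 80, 80)).astype(np.float32)
    well = _well(video)
    sets = {i: np.array([[10 * i, 10 * i]]) for i in range(1, 4)}
    cands = build_candidates(well, sets, "M")
    samples = [extract_sample(well, c, label=f"type{c.cell_id}") for c in cands]
    manifest = export_samples(samples, tmp_path)
    assert len(manifest) == 3
    X, labels = load_samples(tmp_path)
    assert labels == ["type1", "type2", "type3"]
    for sample, back in zip(samples, X):
        assert np.array_equal(back, sample.video.astype(np.float32))


def test_strategy_m_recovers_synthetic_cells(noiseless_experiment):
    """Cover-pixel candidates from ground-truth masks find every cell."""
    from adhekin.preprocess import (RawRecording, detect_adhesion_start,
                                    offset_correct, split_wells, trim_well)
    from adhekin.projection import project_mask_to_biosensor

    exp = noiseless_experiment
    raw = RawRecording(video=exp.video, timeline=exp.timeline)
    start = detect_adhesion_start(raw.timeline)
    wells = {w.well_id: w for w in split_wells(raw)}
    for wid, mask in exp.masks.items():
        well = offset_correct(trim_well(wells[wid], start))
        cover, _ = project_mask_to_biosensor(mask, exp.truth.transform)
        cands = build_candidates(well, cover, "M")
        assert len(cands) == exp.config.n_cells_per_well
        truth = exp.truth.cells.query("well_row == @wid[0] and well_col == @wid[1]")
        for cand in cands:
            row = truth[truth.cell_id == cand.cell_id].iloc[0]
            assert abs(cand.centroid[0] - row.b_row) <= 1.5
            assert abs(cand.centroid[1] - row.b_col) <= 1.5
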