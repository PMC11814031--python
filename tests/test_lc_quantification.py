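"""LC contrast extraction: normalization, tri-section, subset search, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcnm.core import GridError, ImageVolume
from lcnm.lc_quantification import (
    SUBREGIONS,
    compute_nm_contrast,
    extract_brightest_connected,
    normalize_slices,
    quantify_subject,
    split_axial_thirds,
    trisect_roi,
)
from lcnm.synthetic_data import apply_slice_gain, generate_cohort

from oracles import brightest_connected_oracle


# ---------------------------------------------------------------------------
# slice normalization
# ---------------------------------------------------------------------------

def test_normalize_uniform_volume_is_identity():
    vol = ImageVolume(np.full((8, 8, 8), 7.0))
    out = normalize_slices(vol, np.ones((8, 8, 8), bool))
    np.testing.assert_allclose(out.data, vol.data)


def test_normalize_equalizes_perturbed_slice(rng):
    data = rng.normal(100, 5, (10, 10, 6))
    data[:, :, 3] *= 2.0
    mask = np.ones(data.shape, bool)
    out = normalize_slices(ImageVolume(data), mask)
    slice_means = [out.data[:, :, k][mask[:, :, k]].mean() for k in range(6)]
    np.testing.assert_allclose(slice_means, slice_means[0])
    # global in-mask mean preserved
    assert out.data[mask].mean() == pytest.approx(data[mask].mean())


def test_normalize_requires_nonempty_mask():
    vol = ImageVolume(np.ones((4, 4, 4)))
    with pytest.raises(ValueError):
        normalize_slices(vol, np.zeros((4, 4, 4), bool))


def test_gain_roundtrip_recovers_contrast_exactly(clean_cohort, rng):
    """Random per-slice gains then normalization leave contrasts at truth to 1e-6."""
    recs, vols, rois, truth = clean_cohort
    sid = recs[0].subject_id
    vol = vols[sid]["nm"]
    gains = rng.uniform(0.9, 1.1, vol.shape[2])
    perturbed = apply_slice_gain(vol, gains)
    res = quantify_subject(perturbed, rois)   # quantify_subject normalizes internally
    for sub in SUBREGIONS:
        want = truth.contrasts[sid]["left"][sub]
        assert res.averaged[sub] == pytest.approx(want, abs=1e-6)


# ---------------------------------------------------------------------------
# tri-section
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_slices, sizes", [(9, (3, 3, 3)), (8, (3, 3, 2)), (7, (3, 2, 2)), (3, (1, 1, 1))])
def test_trisection_block_sizes_remainder_rostral_first(n_slices, sizes):
    blocks = split_axial_thirds(np.arange(10, 10 + n_slices))
    assert (len(blocks["rostral"]), len(blocks["middle"]), len(blocks["caudal"])) == sizes
    # rostral is the superior (highest-index) block
    assert blocks["rostral"].min() > blocks["middle"].max() > blocks["caudal"].max()


def test_trisect_partition_property(rng):
    mask = np.zeros((6, 6, 11), bool)
    mask[2:4, 2:4, 1:9] = rng.random((2, 2, 8)) > 0.3
    mask[2, 2, 1:9] = True  # ensure every slice occupied
    parts = trisect_roi(mask)
    union = parts["rostral"] | parts["middle"] | parts["caudal"]
    np.testing.assert_array_equal(union, mask)
    assert not (parts["rostral"] & parts["middle"]).any()
    assert not (parts["middle"] & parts["caudal"]).any()
    assert not (parts["rostral"] & parts["caudal"]).any()


def test_trisect_needs_three_slices():
    mask = np.zeros((4, 4, 4), bool)
    mask[1, 1, :2] = True
    with pytest.raises(GridError):
        trisect_roi(mask)


# ---------------------------------------------------------------------------
# brightest connected subset
# ---------------------------------------------------------------------------

def test_exact_roi_of_five_returns_all():
    vol = np.zeros((5, 5, 5))
    mask = np.zeros((5, 5, 5), bool)
    mask[1, 1, 0:5] = True
    vol[1, 1, 0:5] = [10, 20, 30, 40, 50]
    res = extract_brightest_connected(vol, mask, k=5)
    assert res.mean_intensity == pytest.approx(30.0)
    assert len(res.voxels) == 5 and res.flag == "undersized"


def test_bright_column_found_among_background():
    vol = np.full((7, 7, 7), 100.0)
    mask = np.zeros((7, 7, 7), bool)
    mask[2:5, 2:5, 1:6] = True
    vol[3, 3, 1:6] = 200.0
    res = extract_brightest_connected(vol, mask, k=5)
    assert res.mean_intensity == pytest.approx(200.0)
    assert sorted(map(tuple, res.voxels)) == [(3, 3, z) for z in range(1, 6)]


def test_undersized_roi_flagged():
    vol = np.arange(27.0).reshape(3, 3, 3)
    mask = np.zeros((3, 3, 3), bool)
    mask[0, 0, :3] = True
    res = extract_brightest_connected(vol, mask, k=5)
    assert res.flag == "undersized"
    assert len(res.voxels) == 3


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_exact_matches_bruteforce_oracle(connectivity, rng):
    """Branch-and-bound equals exhaustive combination enumeration."""
    for _ in range(12):
        shape = tuple(rng.integers(3, 6, 3))
        mask = rng.random(shape) < 0.7
        coords = np.argwhere(mask)
        if len(coords) < 8:
            continue
        if len(coords) > 18:
            keep = rng.choice(len(coords), 18, replace=False)
            mask = np.zeros(shape, bool)
            mask[tuple(coords[keep].T)] = True
        vol = rng.normal(100, 10, shape)
        try:
            want = brightest_connected_oracle(vol, mask, k=5, connectivity=connectivity)
        except AssertionError:
            continue  # fragmented mask with no connected 5-subset
        res = extract_brightest_connected(vol, mask, k=5, connectivity=connectivity)
        assert res.mean_intensity == pytest.approx(want, abs=1e-9)


def test_greedy_never_beats_exact(rng):
    for _ in range(10):
        vol = rng.normal(100, 10, (5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.5
        if mask.sum() < 8:
            continue
        exact = extract_brightest_connected(vol, mask, k=5, method="exact")
        greedy = extract_brightest_connected(vol, mask, k=5, method="greedy")
        assert greedy.mean_intensity <= exact.mean_intensity + 1e-9


def test_monotonicity_brightening_tube_increases_contrast(clean_cohort):
    recs, vols, rois, truth = clean_cohort
    sid = recs[0].subject_id
    vol = vols[sid]["nm"]
    base = quantify_subject(vol, rois)
    brighter = vol.with_data(np.where(truth.subregion_masks["left_middle"], vol.data + 5.0, vol.data))
    res = quantify_subject(brighter, rois)
    assert res.measures[("left", "middle")].contrast > base.measures[("left", "middle")].contrast
    for side, sub in [("left", "rostral"), ("left", "caudal"), ("right", "middle")]:
        assert res.measures[(side, sub)].contrast == pytest.approx(base.measures[(side, sub)].contrast)


def test_extraction_input_validation():
    vol = np.ones((4, 4, 4))
    with pytest.raises(ValueError):
        extract_brightest_connected(vol, np.zeros((4, 4, 4), bool))
    with pytest.raises(ValueError):
        extract_brightest_connected(vol, np.ones((4, 4, 4), bool), k=0)
    with pytest.raises(ValueError):
        extract_brightest_connected(vol, np.ones((4, 4, 4), bool), connectivity=10)


# ---------------------------------------------------------------------------
# contrast ratio
# ---------------------------------------------------------------------------

def test_contrast_formula_examples():
    assert compute_nm_contrast(125.0, 100.0) == pytest.approx(0.25)
    assert compute_nm_contrast(100.0, 100.0) == 0.0
    with pytest.raises(ValueError):
        compute_nm_contrast(10.0, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    roi=st.floats(1.0, 1e4),
    bg=st.floats(1.0, 1e4),
    scale=st.floats(1e-3, 1e3),
)
def test_contrast_scale_invariance(roi, bg, scale):
    assert compute_nm_contrast(scale * roi, scale * bg) == pytest.approx(
        compute_nm_contrast(roi, bg), rel=1e-9, abs=1e-12)


def test_quantify_scale_invariant_and_lr_average(clean_cohort):
    recs, vols, rois, _ = clean_cohort
    sid = recs[0].subject_id
    vol = vols[sid]["nm"]
    res = quantify_subject(vol, rois)
    res10 = quantify_subject(vol.with_data(vol.data * 10.0), rois)
    for key in res.measures:
        assert res10.measures[key].contrast == pytest.approx(res.measures[key].contrast, abs=1e-12)
    for sub in SUBREGIONS:
        lr = 0.5 * (res.measures[("left", sub)].contrast + res.measures[("right", sub)].contrast)
        assert res.averaged[sub] == pytest.approx(lr, abs=1e-15)
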