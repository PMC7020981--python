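"""Segmentation metrics: volumes, Dice, weighted Dice, surface distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dixonct as dx


def _mask(vox, spacing=(1.0, 1.0, 1.0)):
    return dx.BinaryMask(np.asarray(vox, bool), spacing)


def test_mask_volume_cc():
    vox = np.zeros((20, 20, 20), bool)
    vox[:10, :10, :10] = True
    assert dx.mask_volume_cc(_mask(vox)) == pytest.approx(1.0)
    assert dx.mask_volume_cc(_mask(np.zeros((5, 5, 5)))) == 0.0
    block = np.zeros((12, 12, 12), bool)
    block[:10, :10, :10] = True
    assert dx.mask_volume_cc(_mask(block, (1.29, 1.60, 4.0))) == pytest.approx(8.256)


def test_dice_examples_and_symmetry():
    a = np.zeros((10, 10, 10), bool)
    a[:5] = True
    assert dx.dice(_mask(a), _mask(a)) == 1.0
    b = np.zeros((10, 10, 10), bool)
    b[5:] = True
    assert dx.dice(_mask(a), _mask(b)) == 0.0
    # |A|=100, |B|=100, |A∩B|=60 -> 0.6... constructed by brute-force count
    a2 = np.zeros((10, 10, 10), bool)
    b2 = np.zeros((10, 10, 10), bool)
    a2.flat[:100] = True
    b2.flat[40:140] = True
    inter = int((a2 & b2).sum())
    assert inter == 60
    assert dx.dice(_mask(a2), _mask(b2)) == pytest.approx(2 * 60 / 200)
    assert dx.dice(_mask(b2), _mask(a2)) == dx.dice(_mask(a2), _mask(b2))
    assert dx.dice(_mask(np.zeros((3, 3, 3))), _mask(np.zeros((3, 3, 3)))) == 1.0


def test_dice_grid_mismatch():
    with pytest.raises(dx.PreconditionError):
        dx.dice(_mask(np.ones((3, 3, 3))), _mask(np.ones((3, 3, 3)), (2, 1, 1)))


def test_volume_ratio():
    a = np.zeros((10, 10, 10), bool)
    a[:4] = True
    assert dx.volume_ratio(_mask(a), _mask(a)) == 1.0
    b = np.zeros((10, 10, 10), bool)
    b[:2] = True
    assert dx.volume_ratio(_mask(a), _mask(b)) == pytest.approx(2.0)
    with pytest.raises(dx.PreconditionError):
        dx.volume_ratio(_mask(a), _mask(np.zeros((10, 10, 10))))
    # magnitudes like 47/37 cm^3 come out as expected
    assert 47.0 / 37.0 == pytest.approx(1.27, abs=0.005)


def test_surface_distance_identical_masks():
    vox = np.zeros((10, 10, 10), bool)
    vox[3:7, 3:7, 3:7] = True
    mean, sd, mx = dx.surface_distance_stats(_mask(vox), _mask(vox))
    assert (mean, sd, mx) == (0.0, 0.0, 0.0)


def test_surface_distance_parallel_plates():
    a = np.zeros((20, 20, 20), bool)
    b = np.zeros((20, 20, 20), bool)
    a[:, :, 4] = True
    b[:, :, 14] = True  # 10 mm apart at unit spacing
    mean, sd, mx = dx.surface_distance_stats(_mask(a), _mask(b))
    assert mean == pytest.approx(10.0)
    assert sd == pytest.approx(0.0, abs=1e-9)
    assert mx == pytest.approx(10.0)


def _brute_force_surface_stats(a, b, spacing):
    """Exhaustive oracle: boundary voxels by 6-neighborhood scan, all-pairs
    nearest distances, pooled mean/SD/max."""
    def boundary(m):
        pts = []
        nx, ny, nz = m.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not m[i, j, k]:
                        continue
                    edge = False
                    for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        ii, jj, kk = i + di, j + dj, k + dk
                        if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz) \
                                or not m[ii, jj, kk]:
                            edge = True
                            break
                    if edge:
                        pts.append((i * spacing[0], j * spacing[1], k * spacing[2]))
        return np.array(pts)

    pa, pb = boundary(a), boundary(b)
    d_ab = [min(np.sqrt(((p - q) ** 2).sum()) for q in pb) for p in pa]
    d_ba = [min(np.sqrt(((p - q) ** 2).sum()) for q in pa) for p in pb]
    pooled = np.array(d_ab + d_ba)
    return pooled.mean(), pooled.std(), pooled.max()


def test_surface_distance_matches_exhaustive_oracle():
    rng = np.random.default_rng(21)
    spacing = (1.29, 1.60, 4.0)
    for _ in range(5):
        a = rng.random((8, 8, 8)) > 0.6
        b = rng.random((8, 8, 8)) > 0.6
        if not a.any() or not b.any():
            continue
        got = dx.surface_distance_stats(_mask(a, spacing), _mask(b, spacing))
        want = _brute_force_surface_stats(a, b, spacing)
        np.testing.assert_allclose(got, want, atol=1e-9)


def test_surface_distance_empty_mask_rejected():
    vox = np.ones((4, 4, 4), bool)
    with pytest.raises(dx.PreconditionError):
        dx.surface_distance_stats(_mask(vox), _mask(np.zeros((4, 4, 4))))


# ------------------------------------------------------------ weighted Dice

VOLUNTEER_ROWS = {
    # manual volumes (cm^3) and Dice for air, fat, lungs, high-density, spine
    1: ([37, 4884, 1236, 12077, 415], [0.238, 0.920, 0.947, 0.957, 0.786], 0.941),
    2: ([32, 2081, 1696, 6098, 230], [0.830, 0.935, 0.973, 0.964, 0.787], 0.955),
    3: ([13, 1587, 1559, 6111, 223], [0.596, 0.844, 0.980, 0.953, 0.786], 0.935),
    4: ([189, 3674, 1459, 6546, 241], [0.823, 0.880, 0.971, 0.928, 0.763], 0.914),
    5: ([98, 1468, 396, 5794, 227], [0.587, 0.891, 0.939, 0.958, 0.791], 0.936),
}


@pytest.mark.parametrize("volunteer", [1, 2, 3, 4, 5])
def test_weighted_dice_reproduces_reference_rows(volunteer):
    """The volume-weighted Dice of each reference subject follows from its
    per-class volumes and Dice values; subject 5 carries a slightly wider
    band because the published value was computed from unrounded internals."""
    vols, dices, expected = VOLUNTEER_ROWS[volunteer]
    got = dx.weighted_dice(zip(vols, dices))
    tol = 0.002 if volunteer == 5 else 0.001
    assert got == pytest.approx(expected, abs=tol)


def test_weighted_dice_simple_cases():
    assert dx.weighted_dice([(10.0, 0.73)]) == pytest.approx(0.73)
    assert dx.weighted_dice([(5.0, 0.8), (5.0, 0.6)]) == pytest.approx(0.7)
    with pytest.raises(dx.PreconditionError):
        dx.weighted_dice([(0.0, 0.5), (0.0, 0.5)])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.01, 1e4), st.floats(0, 1)),
                min_size=1, max_size=8))
def test_weighted_dice_bounds_and_permutation_invariance(pairs):
    s = dx.weighted_dice(pairs)
    dices = [d for _, d in pairs]
    assert min(dices) - 1e-12 <= s <= max(dices) + 1e-12
    assert dx.weighted_dice(list(reversed(pairs))) == pytest.approx(s)


# ------------------------------------------------------------------ report

def test_report_identity():
    rng = np.random.default_rng(6)
    labels = rng.integers(0, 6, (12, 12, 8)).astype(np.uint8)
    lm = dx.LabelMap(labels, (1.0, 1.0, 2.0))
    rep = dx.build_report(lm, lm)
    assert rep.weighted_dice == pytest.approx(1.0)
    for r in rep.records:
        assert r.dice == 1.0
        assert r.volume_ratio == pytest.approx(1.0)
        assert r.surface_mean_mm == 0.0 and r.surface_max_mm == 0.0


def test_report_missing_manual_class():
    auto = np.full((6, 6, 6), dx.CLASS_CODES["fat"], dtype=np.uint8)
    manual = np.full((6, 6, 6), dx.CLASS_CODES["fat"], dtype=np.uint8)
    auto[0, 0, 0] = dx.CLASS_CODES["air"]  # auto finds air, manual has none
    rep = dx.build_report(dx.LabelMap(auto, (1, 1, 1)), dx.LabelMap(manual, (1, 1, 1)))
    air = rep.record("air")
    assert air.volume_ratio is None
    assert air.dice == 0.0
    assert np.isfinite(rep.weighted_dice)


def test_report_grid_mismatch():
    a = dx.LabelMap(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
    b = dx.LabelMap(np.zeros((4, 4, 4), np.uint8), (2, 1, 1))
    with pytest.raises(dx.PreconditionError):
        dx.build_report(a, b)


def test_report_on_phantom_pipeline(noise_free_run):
    rep = noise_free_run.report
    for r in rep.records:
        assert 0.0 <= r.dice <= 1.0
        assert r.manual_volume_cc >= 0 and r.auto_volume_cc >= 0
    assert 0.0 <= rep.weighted_dice <= 1.0
    # serialization round trips
    d = rep.to_dict()
    assert set(d["classes"]) == set(dx.FIVE_CLASSES)
    assert "Weighted Dice" in rep.to_table()
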