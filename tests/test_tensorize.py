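"""Histogram workflow: masking, aggregation, limits, binning, assembly."""

import numpy as np
import pytest
import shapely.geometry as sgeom
from hypothesis import given, settings, strategies as st

import histoyield as hy
from histoyield.bands import default_bands
from histoyield.calendar import TimeNode, composite_calendar
from histoyield.geo import Raster
from histoyield.simulate import degenerate_county
from histoyield.tensorize import (BU_AC_TO_KG_HA, CountyScene, aggregate_daily,
                                  assemble_dataset, build_tensor, convert_yield,
                                  estimate_limits, histogram32, mask_pixels, truncate)

from conftest import brute_force_histogram


# ---------------------------------------------------------------- histogram32

def test_histogram_degenerate_mass_at_lower_limit():
    h = histogram32(np.full(7, 0.0), (0.0, 4.0), 4)
    assert h[0] == 1.0 and h[1:].sum() == 0


def test_histogram_empty_pixel_set_is_zero_vector():
    assert histogram32(np.array([]), (0, 1), 32).sum() == 0


def test_histogram_uniform_spread():
    h = histogram32(np.array([0.5, 1.5, 2.5, 3.5]), (0, 4), 4)
    assert np.allclose(h, 0.25)


def test_histogram_clamps_out_of_range_mass():
    h = histogram32(np.array([-10.0, 10.0]), (0, 4), 4)
    assert np.allclose(h, [0.5, 0, 0, 0.5])


def test_histogram_upper_limit_lands_in_last_bin():
    h = histogram32(np.array([4.0]), (0, 4), 4)
    assert h[-1] == 1.0


def test_histogram_invalid_inputs():
    with pytest.raises(ValueError):
        histogram32(np.array([1.0]), (2.0, 2.0), 4)
    with pytest.raises(ValueError):
        histogram32(np.array([1.0]), (0.0, 1.0), 1)


@settings(max_examples=300, deadline=None)
@given(
    pixels=st.lists(st.floats(-1e4, 1e4, allow_nan=False), min_size=0, max_size=60),
    lo=st.floats(-100, 100),
    width=st.floats(0.1, 500),
    n_bins=st.integers(2, 48),
)
def test_histogram_matches_brute_force_oracle(pixels, lo, width, n_bins):
    """Vectorized binning agrees exactly with a per-pixel loop, and every
    non-empty histogram sums to 1."""
    px = np.array(pixels)
    limits = (lo, lo + width)
    h = histogram32(px, limits, n_bins)
    assert np.array_equal(h, brute_force_histogram(px, limits, n_bins))
    if px.size:
        assert abs(h.sum() - 1.0) < 1e-12


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=40),
       st.randoms(use_true_random=False))
def test_histogram_permutation_invariant(pixels, rnd):
    px = np.array(pixels)
    shuffled = px.copy()
    rnd.shuffle(shuffled)
    assert np.array_equal(histogram32(px, (0, 100), 16),
                          histogram32(shuffled, (0, 100), 16))


# ------------------------------------------------------------ aggregate_daily

def test_aggregate_constant_daily_series():
    cal = composite_calendar(2011, (1, 1), (1, 24))
    daily = np.full(24, 5.0)
    assert np.allclose(aggregate_daily(daily, cal), 5.0)


def test_aggregate_arithmetic_mean():
    cal = composite_calendar(2011, (1, 1), (1, 8))
    assert aggregate_daily(np.arange(1.0, 9.0), cal)[0] == 4.5


def test_aggregate_skips_missing_days():
    cal = composite_calendar(2011, (1, 1), (1, 8))
    daily = np.full(8, np.nan)
    daily[[1, 3, 5]] = [2.0, 4.0, 6.0]
    assert aggregate_daily(daily, cal)[0] == 4.0


def test_aggregate_all_missing_window_is_nan():
    cal = composite_calendar(2011, (1, 1), (1, 8))
    assert np.isnan(aggregate_daily(np.full(8, np.nan), cal)[0])


# -------------------------------------------------------------- mask_pixels

def _unit_raster(data, cell=1.0):
    ny = np.asarray(data).shape[0]
    return Raster(np.asarray(data, dtype=float), (0.0, ny * cell), cell)


def test_mask_all_zero_mask_gives_empty():
    band = _unit_raster(np.arange(16.0).reshape(4, 4))
    mask = _unit_raster(np.zeros((4, 4)))
    poly = sgeom.box(0, 0, 4, 4)
    assert mask_pixels(band, mask, poly).size == 0


def test_mask_identity_when_everything_covered():
    band = _unit_raster(np.arange(16.0).reshape(4, 4))
    mask = _unit_raster(np.ones((4, 4)))
    poly = sgeom.box(0, 0, 4, 4)
    assert sorted(mask_pixels(band, mask, poly)) == list(range(16))


def test_mask_polygon_and_mask_intersection():
    """Polygon over the left half, crop mask over the top half: only the
    top-left 2x2 quadrant of a 4x4 raster survives."""
    band = _unit_raster(np.arange(16.0).reshape(4, 4))
    mask_data = np.zeros((4, 4))
    mask_data[:2, :] = 1  # top half (rows 0-1)
    mask = _unit_raster(mask_data)
    poly = sgeom.box(0, 0, 2, 4)  # left half
    got = sorted(mask_pixels(band, mask, poly))
    assert got == [0.0, 1.0, 4.0, 5.0]


def test_mask_disjoint_extent_is_empty_not_error():
    band = _unit_raster(np.ones((4, 4)))
    mask = _unit_raster(np.ones((4, 4)))
    poly = sgeom.box(100, 100, 104, 104)
    assert mask_pixels(band, mask, poly).size == 0


def test_mask_multiresolution_sampling():
    """A coarse band sampled against a fine mask: each coarse center reads
    the fine-mask cell it falls into, with no band resampling."""
    band = _unit_raster(np.arange(4.0).reshape(2, 2), cell=2.0)
    fine = np.zeros((4, 4))
    fine[:, :2] = 1  # left half cropped at fine resolution
    mask = _unit_raster(fine)
    poly = sgeom.box(0, 0, 4, 4)
    assert sorted(mask_pixels(band, mask, poly)) == [0.0, 2.0]


# ------------------------------------------------------------ estimate_limits

def test_limits_full_range_quantiles():
    lo, hi = estimate_limits(np.arange(1.0, 101.0), quantiles=(0.0, 1.0))
    assert (lo, hi) == (1.0, 100.0)


def test_limits_default_table_constants():
    bands = {b.name: b for b in default_bands()}
    assert bands["sr_b1"].limits == (1.0, 5000.0)
    assert bands["lst_day"].limits == (12400.0, 15600.0)
    assert bands["precipitation"].limits == (0.0, 35.0)
    assert bands["vapor_pressure"].limits == (0.0, 3200.0)


def test_limits_normal_sample_quantiles():
    rng = np.random.default_rng(0)
    lo, hi = estimate_limits(rng.standard_normal(100_000), quantiles=(0.01, 0.99))
    assert abs(lo + 2.326) < 0.05
    assert abs(hi - 2.326) < 0.05


def test_limits_empty_pool_raises():
    with pytest.raises(ValueError):
        estimate_limits(np.array([]))


# ------------------------------------------------- build_tensor / truncate

def _toy_scene(t=4, n_pix=5, seed=0):
    rng = np.random.default_rng(seed)
    bands = default_bands()
    cal = composite_calendar(2011, (4, 1), (5, 3))
    assert len(cal) == t
    pixels = {}
    for spec in bands:
        lo, hi = spec.limits
        pixels[spec.name] = [rng.uniform(lo, hi, n_pix) for _ in range(t)]
    return CountyScene("X", 2011, pixels), bands, cal


def test_tensor_shape_and_normalization():
    scene, bands, cal = _toy_scene()
    t = hy.build_tensor(scene, bands, cal)
    assert t.shape == (4, 32, 11)
    assert np.allclose(t.values.sum(axis=1), 1.0)


def test_tensor_missing_band_raises_with_name():
    scene, bands, cal = _toy_scene()
    del scene.pixels["lst_day"]
    with pytest.raises(KeyError, match="lst_day"):
        build_tensor(scene, bands, cal)


def test_tensor_full_season_shape(small_dataset):
    assert small_dataset.tensors[0].shape == (34, 32, 11)


def test_truncate_identity_and_jun2(small_dataset):
    full = small_dataset.tensors[0]
    unchanged = truncate(full, TimeNode("DEC-27", 12, 27))
    assert unchanged.shape == (34, 32, 11)
    assert np.array_equal(unchanged.values, full.values)
    assert truncate(full, TimeNode("JUN-2", 6, 2)).shape == (8, 32, 11)
    assert truncate(full, TimeNode("AUG-21", 8, 21)).shape == (18, 32, 11)


# ------------------------------------------------------------ assembly rules

def test_degenerate_county_scene_is_empty_everywhere():
    cfg = hy.SimConfig(n_counties=1, years=(2011,), seed=0)
    scene = degenerate_county(cfg)
    assert scene.masked_count() == 0


def test_assemble_drops_unlabeled_and_empty():
    scene, bands, cal = _toy_scene()
    full = build_tensor(scene, bands, cal)
    labeled2 = hy.HistogramTensor("Y", 2011, full.values.copy(), cal, full.band_order)
    unlabeled = hy.HistogramTensor("Z", 2011, full.values.copy(), cal, full.band_order)
    empty_scene = degenerate_county(hy.SimConfig(n_counties=1, years=(2011,),
                                                 season=((4, 1), (5, 3)), seed=0))
    empty = build_tensor(empty_scene, bands, cal)
    records = [hy.YieldRecord("X", 2011, 2500.0), hy.YieldRecord("Y", 2011, 2600.0),
               hy.YieldRecord(empty.county_id, 2011, 2700.0)]
    ds, report = assemble_dataset([full, labeled2, unlabeled, empty], records, bands)
    assert len(ds) == 2
    assert report.no_label == [("Z", 2011)]
    assert report.no_crop_pixels == [(empty.county_id, 2011)]
    assert "no crop pixels" in report.summary() and "no label" in report.summary()


def test_single_crop_pixel_county_is_retained():
    scene, bands, cal = _toy_scene(n_pix=5)
    # one band / one period with a single pixel, all else empty
    for name in scene.pixels:
        scene.pixels[name] = [np.empty(0) for _ in range(4)]
    scene.pixels["sr_b1"][0] = np.array([1234.0])
    t = build_tensor(scene, bands, cal)
    ds, report = assemble_dataset([t], [hy.YieldRecord("X", 2011, 2000.0)], bands)
    assert len(ds) == 1 and report.n_dropped == 0


def test_assemble_duplicate_labels_raise():
    scene, bands, cal = _toy_scene()
    t = build_tensor(scene, bands, cal)
    recs = [hy.YieldRecord("X", 2011, 2000.0), hy.YieldRecord("X", 2011, 2100.0)]
    with pytest.raises(ValueError, match="duplicate"):
        assemble_dataset([t], recs, bands)


def test_bushel_conversion():
    assert convert_yield(50.0, "bu/ac") == pytest.approx(3362.5)
    assert BU_AC_TO_KG_HA == pytest.approx(67.25, abs=0.01)
    # independent unit-arithmetic oracle: 60 lb/bu, kg per lb, acres per ha
    assert BU_AC_TO_KG_HA == pytest.approx(60 * 0.45359237 / 0.40468564, rel=1e-4)


def test_restrict_bands_feature_groups(small_dataset):
    refl = small_dataset.restrict_bands([n for n in small_dataset.band_order
                                         if n.startswith("sr_")])
    assert refl.tensors[0].shape == (34, 32, 7)
    env = small_dataset.restrict_bands(["lst_day", "lst_night",
                                        "precipitation", "vapor_pressure"])
    assert env.tensors[0].shape == (34, 32, 4)
    with pytest.raises(KeyError):
        small_dataset.restrict_bands(["nope"])
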