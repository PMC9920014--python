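"""Detection metrics: SCR, SMR, MMR, FWHM, LE, peak finding."""

import numpy as np
import pytest

from axmwi.beamform import EnergyMap, ImagingGrid
from axmwi.metrics import (
    distinguishable,
    evaluate_map,
    find_peaks,
    fwhm,
    localization_error,
    mmr,
    scr,
    smr,
    truth_region,
)
from axmwi.phantom import TargetTruth

PITCH = 0.5
GRID = ImagingGrid(x0_mm=0.0, d0_mm=0.0, pitch_mm=PITCH, n_d=80, n_x=120)


def make_map(values) -> EnergyMap:
    return EnergyMap(values=np.asarray(values, dtype=float), grid=GRID, method="DAS")


def make_truth(center_dm, radius_mm=3.0, status="metastasized", long_axis=12.0) -> TargetTruth:
    """Disk-shaped stand-in truth mask on the map grid."""
    dd, xx = np.meshgrid(GRID.ds_mm, GRID.xs_mm, indexing="ij")
    mask = np.hypot(dd - center_dm[0], xx - center_dm[1]) <= radius_mm
    # mask indexed like the grid: dx = pitch, no air gap offset shift needed
    return TargetTruth(
        center_mm=center_dm, mask=mask, status=status, long_axis_mm=long_axis,
        dx_mm=PITCH, air_gap_mm=-0.0,
    )


def gaussian_blob(center_dm, sigma_mm, amplitude=1.0):
    dd, xx = np.meshgrid(GRID.ds_mm, GRID.xs_mm, indexing="ij")
    r2 = (dd - center_dm[0]) ** 2 + (xx - center_dm[1]) ** 2
    return amplitude * np.exp(-r2 / (2 * sigma_mm**2))


TRUTH = make_truth((20.0, 30.0))


class TestScrSmr:
    def test_single_hot_pixel_inside(self):
        v = np.full(GRID.shape, 1e-6)
        v[40, 60] = 1.0  # depth 20.25, x 30.25 -> inside the truth region
        emap = make_map(v)
        assert scr(emap, TRUTH) == pytest.approx(10 * np.log10(1.0 / 1e-6))
        assert smr(emap, TRUTH) == pytest.approx(10 * np.log10(1.0 / 1e-6))

    def test_inside_twice_outside_gives_3db(self):
        v = np.ones(GRID.shape)
        v[40, 60] = 2.0
        assert scr(make_map(v), TRUTH) == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_flat_map_gives_zero_db(self):
        emap = make_map(np.ones(GRID.shape))
        assert scr(emap, TRUTH) == pytest.approx(0.0)
        assert smr(emap, TRUTH) == pytest.approx(0.0)

    def test_smr_100x_mean_is_20db(self):
        v = np.ones(GRID.shape)
        v[40, 60] = 100.0
        assert smr(make_map(v), TRUTH) == pytest.approx(20.0, abs=0.01)

    def test_smr_never_below_scr(self):
        rng = np.random.default_rng(0)
        v = rng.random(GRID.shape)
        emap = make_map(v)
        assert smr(emap, TRUTH) >= scr(emap, TRUTH)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.random(GRID.shape)
        assert scr(make_map(v), TRUTH) == pytest.approx(scr(make_map(7.0 * v), TRUTH))
        assert smr(make_map(v), TRUTH) == pytest.approx(smr(make_map(7.0 * v), TRUTH))


class TestMmr:
    MET = make_truth((20.0, 20.0), status="metastasized")
    HEA = make_truth((20.0, 45.0), status="healthy")

    def test_equal_maxima_zero_db(self):
        v = gaussian_blob((20.0, 20.0), 2.0) + gaussian_blob((20.0, 45.0), 2.0)
        assert mmr(make_map(v), self.MET, self.HEA) == pytest.approx(0.0, abs=1e-9)

    def test_ten_times_is_10db(self):
        v = 10 * gaussian_blob((20.0, 20.0), 2.0) + gaussian_blob((20.0, 45.0), 2.0)
        assert mmr(make_map(v), self.MET, self.HEA) == pytest.approx(10.0, abs=0.05)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        emap = make_map(rng.random(GRID.shape) + 0.1)
        assert mmr(emap, self.MET, self.HEA) == pytest.approx(-mmr(emap, self.HEA, self.MET))

    def test_overlapping_regions_rejected(self):
        near = make_truth((20.0, 24.0), status="healthy")
        with pytest.raises(ValueError):
            mmr(make_map(np.ones(GRID.shape)), self.MET, near)


class TestFwhm:
    def test_isotropic_gaussian_matches_closed_form(self):
        sigma = 3.0
        emap = make_map(gaussian_blob((20.0, 30.0), sigma))
        expected = 2 * sigma * np.sqrt(2 * np.log(2))
        assert fwhm(emap) == pytest.approx(expected, abs=PITCH)

    def test_single_pixel_spike(self):
        v = np.zeros(GRID.shape)
        v[40, 60] = 1.0
        assert fwhm(make_map(v)) <= 2 * PITCH

    def test_amplitude_invariance(self):
        blob = gaussian_blob((20.0, 30.0), 2.5)
        assert fwhm(make_map(blob)) == pytest.approx(fwhm(make_map(5 * blob)))


class TestLocalizationError:
    def test_peak_at_center_is_zero(self):
        emap = make_map(gaussian_blob((20.25, 30.25), 2.0))  # centred on a pixel
        t = make_truth((20.25, 30.25))
        assert localization_error(emap, t) == pytest.approx(0.0, abs=1e-12)

    def test_one_pixel_offset_is_half_mm(self):
        v = np.zeros(GRID.shape)
        v[40, 61] = 1.0  # one pixel lateral of (20.25, 30.25)
        t = make_truth((20.25, 30.25))
        assert localization_error(make_map(v), t) == pytest.approx(0.5, abs=1e-9)

    def test_scale_invariance(self):
        emap = make_map(gaussian_blob((22.0, 40.0), 2.0))
        t = make_truth((20.0, 30.0))
        assert localization_error(emap, t) == pytest.approx(
            localization_error(make_map(9 * emap.values), t)
        )


class TestFindPeaks:
    def test_two_separated_blobs_recovered(self):
        v = gaussian_blob((20.25, 20.25), 2.0) + 0.8 * gaussian_blob((20.25, 45.25), 2.0)
        peaks, complete = find_peaks(make_map(v), 2, 10.0)
        assert complete
        assert peaks[0][:2] == pytest.approx((20.25, 20.25), abs=PITCH)
        assert peaks[1][:2] == pytest.approx((20.25, 45.25), abs=PITCH)

    def test_single_target_is_global_max(self):
        rng = np.random.default_rng(3)
        v = rng.random(GRID.shape)
        peaks, _ = find_peaks(make_map(v), 1)
        i, j = np.unravel_index(np.argmax(v), v.shape)
        assert peaks[0][:2] == pytest.approx(GRID.pixel_to_mm(i, j))

    def test_merged_ridge_reports_incomplete(self):
        v = gaussian_blob((20.0, 30.0), 6.0) + gaussian_blob((20.0, 33.0), 6.0)
        peaks, complete = find_peaks(make_map(v), 2, 20.0)
        assert len(peaks) == 1 and not complete


class TestDistinguishable:
    def test_two_clean_blobs_distinguishable(self):
        t1 = make_truth((20.25, 20.25))
        t2 = make_truth((20.25, 45.25))
        v = gaussian_blob((20.25, 20.25), 2.0) + 0.9 * gaussian_blob((20.25, 45.25), 2.0)
        assert distinguishable(make_map(v), [t1, t2])

    def test_ghost_dominating_one_node_fails(self):
        t1 = make_truth((20.25, 20.25))
        t2 = make_truth((20.25, 45.25))
        v = gaussian_blob((20.25, 45.25), 2.0) + 1.2 * gaussian_blob((28.0, 32.0), 2.0)
        assert not distinguishable(make_map(v), [t1, t2])


def test_evaluate_map_excludes_other_target_from_clutter():
    met = make_truth((20.0, 20.0), status="metastasized")
    hea = make_truth((20.0, 45.0), status="healthy")
    v = gaussian_blob((20.0, 20.0), 2.0) + 0.5 * gaussian_blob((20.0, 45.0), 2.0) + 1e-4
    table = evaluate_map(make_map(v), [met, hea])
    assert len(table) == 2
    # the healthy blob (0.5 peak) must not count as the metastasised node's clutter
    row_met = table[table.status == "metastasized"].iloc[0]
    assert row_met.scr_db > 10.0
    assert row_met.mmr_db == pytest.approx(10 * np.log10(1 / 0.5), abs=0.1)
    assert row_met.le_mm <= PITCH


def test_truth_region_dilation_grows_with_margin():
    a = truth_region(make_map(np.ones(GRID.shape)), TRUTH, 0.0)
    b = truth_region(make_map(np.ones(GRID.shape)), TRUTH, 2.0)
    assert b.sum() > a.sum()
    assert (b | a).sum() == b.sum()
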