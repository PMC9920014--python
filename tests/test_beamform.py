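"""Beamformers: delays, rank weights, DAS/DMAS oracles, dispatch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.constants import c as C0

from axmwi.beamform import (
    ImagingGrid,
    compute_delays,
    das,
    default_speed,
    dmas,
    rank_weights,
    reconstruct,
)
from axmwi.fdtd import ChannelData
from axmwi.phantom import ALNSpec, PhantomConfig, build_phantom
from axmwi.pulse import PulseSpec, differentiated_gaussian

DT = 2e-12
SPEED = default_speed()


def make_channels(signals, xy) -> ChannelData:
    return ChannelData(
        signals=np.asarray(signals, dtype=float),
        dt=DT,
        antenna_xy_mm=np.asarray(xy, dtype=float),
        meta={},
    )


def point_target_channels(grid, xy, target_dm, pulse_len=75):
    """Analytic channels: one pulse per channel placed exactly at the
    monostatic delay of the target point (no FDTD)."""
    xy = np.asarray(xy, dtype=float)
    n_t = 2048
    pulse = differentiated_gaussian(np.arange(pulse_len) * DT, PulseSpec(sigma=20e-12, delay_sigmas=0.0 + 6))
    sigs = np.zeros((len(xy), n_t))
    for m, (ax, ad) in enumerate(xy):
        dist = np.hypot(target_dm[1] - ax, target_dm[0] - ad)
        k = int(round(2 * dist * 1e-3 / SPEED / DT))
        sigs[m, k : k + pulse_len] = pulse
    return make_channels(sigs, xy)


GRID = ImagingGrid(x0_mm=20.0, d0_mm=5.0, pitch_mm=0.5, n_d=60, n_x=160)
ARRAY = np.column_stack([np.linspace(20, 100, 16), np.zeros(16)])


class TestDelays:
    def test_pixel_coincident_with_antenna_has_zero_delay(self):
        grid = ImagingGrid(x0_mm=0.0, d0_mm=0.0, pitch_mm=1.0, n_d=3, n_x=3)
        xy = [[grid.xs_mm[1], grid.ds_mm[1]]]
        table = compute_delays(grid, np.asarray(xy), SPEED)
        assert table.delays[0, 1, 1] == 0.0

    def test_hand_computed_delay_20mm_below_antenna(self):
        grid = ImagingGrid(x0_mm=9.75, d0_mm=19.75, pitch_mm=0.5, n_d=1, n_x=1)
        table = compute_delays(grid, np.asarray([[10.0, 0.0]]), C0 / np.sqrt(4.3))
        assert table.delays[0, 0, 0] == pytest.approx(2 * 0.020 * np.sqrt(4.3) / C0, rel=1e-9)

    def test_delays_increase_with_depth(self):
        table = compute_delays(GRID, ARRAY, SPEED)
        assert (np.diff(table.delays, axis=1) > 0).all()


class TestRankWeights:
    def test_uniform_distances_give_unit_weights(self):
        w = rank_weights(np.full(8, 3.0))
        assert w == pytest.approx(np.ones(8))

    def test_three_channel_linear_rule(self):
        w = rank_weights(np.array([10.0, 20.0, 30.0]))
        assert w == pytest.approx([1.5, 1.0, 0.5])

    def test_permutation_equivariance(self):
        d = np.array([5.0, 1.0, 9.0, 3.0])
        w = rank_weights(d)
        perm = np.array([2, 0, 3, 1])
        assert rank_weights(d[perm]) == pytest.approx(w[perm])

    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(np.float64, st.integers(2, 16),
               elements=st.floats(1.0, 100.0, allow_nan=False))
    )
    def test_rank_weights_invariants_hold_for_any_distances(self, d):
        w = rank_weights(d)
        assert w.sum() == pytest.approx(len(d))
        assert (w > 0).all()
        # non-increasing in distance: sorting distances sorts weights inversely
        order = np.argsort(d)
        assert (np.diff(w[order]) <= 1e-12).all()

    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(np.float64, st.integers(2, 16),
               elements=st.floats(-10.0, 10.0, allow_nan=False))
    )
    def test_pair_sum_identity_for_any_samples(self, a):
        brute = sum(a[i] * a[j] for i in range(len(a)) for j in range(i + 1, len(a)))
        identity = 0.5 * (a.sum() ** 2 - (a**2).sum())
        assert identity == pytest.approx(brute, abs=1e-9)

    def test_weights_sum_to_channel_count(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(1, 50, size=(16, 100))
        w = rank_weights(d, axis=0)
        assert w.sum(axis=0) == pytest.approx(np.full(100, 16.0))
        assert (w > 0).all()


class TestDasOracles:
    def test_single_channel_window_one_is_squared_sample(self):
        grid = ImagingGrid(x0_mm=0.0, d0_mm=0.0, pitch_mm=1.0, n_d=2, n_x=2)
        sig = np.arange(100.0)[None, :]
        ch = make_channels(sig, [[0.5, -10.0]])
        table = compute_delays(grid, ch.antenna_xy_mm, SPEED)
        emap = das(ch, table, window=1)
        idx = np.rint(table.delays[0] / DT).astype(int)
        assert emap.values == pytest.approx(sig[0][idx] ** 2)

    def test_point_target_peak_at_target(self):
        target = (20.0, 60.0)
        ch = point_target_channels(GRID, ARRAY, target)
        table = compute_delays(GRID, ch.antenna_xy_mm, SPEED)
        emap = das(ch, table)
        pd_, px = emap.peak_mm()
        assert abs(pd_ - target[0]) <= GRID.pitch_mm
        assert abs(px - target[1]) <= GRID.pitch_mm

    def test_quadratic_homogeneity(self):
        ch = point_target_channels(GRID, ARRAY, (15.0, 50.0))
        table = compute_delays(GRID, ch.antenna_xy_mm, SPEED)
        base = das(ch, table).values
        ch2 = ch.copy()
        ch2.signals = 3.0 * ch.signals
        assert das(ch2, table).values == pytest.approx(9.0 * base, rel=1e-12)


class TestDmasOracles:
    def test_pair_sum_identity_matches_brute_force(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(16)
        brute = sum(a[i] * a[j] for i in range(16) for j in range(i + 1, 16))
        identity = 0.5 * (a.sum() ** 2 - (a**2).sum())
        assert identity == pytest.approx(brute, rel=1e-12)

    def test_two_channels_reduce_to_product(self):
        grid = ImagingGrid(x0_mm=0.0, d0_mm=0.0, pitch_mm=1.0, n_d=2, n_x=2)
        rng = np.random.default_rng(8)
        sig = rng.standard_normal((2, 200))
        ch = make_channels(sig, [[0.0, 0.0], [2.0, 0.0]])
        table = compute_delays(grid, ch.antenna_xy_mm, SPEED)
        emap = dmas(ch, table, window=1)
        idx = np.rint(table.delays / DT).astype(int)
        expected = np.array(
            [[(sig[0, idx[0, i, j]] * sig[1, idx[1, i, j]]) ** 2 for j in range(2)] for i in range(2)]
        )
        assert emap.values == pytest.approx(expected, rel=1e-12)

    def test_uniform_weights_equal_plain_dmas_exactly(self):
        ch = point_target_channels(GRID, ARRAY, (20.0, 60.0))
        table = compute_delays(GRID, ch.antenna_xy_mm, SPEED)
        plain = dmas(ch, table)
        weighted = dmas(ch, table, weights=np.ones((16, GRID.n_d * GRID.n_x)))
        assert np.array_equal(plain.values, weighted.values)

    def test_single_channel_rejected(self):
        ch = make_channels(np.ones((1, 50)), [[0.0, 0.0]])
        grid = ImagingGrid(x0_mm=0.0, d0_mm=0.0, pitch_mm=1.0, n_d=1, n_x=1)
        with pytest.raises(ValueError):
            dmas(ch, compute_delays(grid, ch.antenna_xy_mm, SPEED))


def naive_das(sig, idx, w, n_win):
    M, nd, nx = idx.shape
    out = np.zeros((nd, nx))
    for i in range(nd):
        for j in range(nx):
            for k in range(n_win):
                s = sum(w[m] * sig[m, idx[m, i, j] + k] for m in range(M))
                out[i, j] += s * s
    return out


def naive_dmas(sig, idx, w, n_win):
    M, nd, nx = idx.shape
    out = np.zeros((nd, nx))
    for i in range(nd):
        for j in range(nx):
            for k in range(n_win):
                p = 0.0
                for a in range(M):
                    for b in range(a + 1, M):
                        p += (w[a] * sig[a, idx[a, i, j] + k]) * (w[b] * sig[b, idx[b, i, j] + k])
                out[i, j] += p * p
    return out


@pytest.mark.parametrize("pair_mode", [False, True])
def test_kernels_match_naive_triple_loop(pair_mode):
    rng = np.random.default_rng(11)
    grid = ImagingGrid(x0_mm=10.0, d0_mm=5.0, pitch_mm=1.0, n_d=15, n_x=18)
    xy = np.column_stack([np.linspace(5, 35, 4), np.zeros(4)])
    sig = rng.standard_normal((4, 1500))
    ch = make_channels(sig, xy)
    table = compute_delays(grid, xy, SPEED)
    w1d = np.array([1.3, 0.9, 0.6, 1.2])
    w = np.tile(w1d[:, None], (1, grid.n_d * grid.n_x))
    n_win = 8
    fn = dmas if pair_mode else das
    emap = fn(ch, table, weights=w, window=n_win)
    idx = np.rint(table.delays / DT).astype(int)
    ref = (naive_dmas if pair_mode else naive_das)(sig, idx, w1d, n_win)
    assert np.abs(emap.values - ref).max() <= 1e-10 * np.abs(ref).max()


def test_dmas_has_less_offpeak_clutter_than_das():
    ch = point_target_channels(GRID, ARRAY, (20.0, 60.0))
    table = compute_delays(GRID, ch.antenna_xy_mm, SPEED)
    maps = {name: fn(ch, table) for name, fn in (("das", das), ("dmas", dmas))}
    rel = {}
    for name, emap in maps.items():
        v = emap.values / emap.values.max()
        i, j = np.unravel_index(np.argmax(v), v.shape)
        mask = np.ones_like(v, dtype=bool)
        mask[max(0, i - 6) : i + 7, max(0, j - 6) : j + 7] = False
        rel[name] = v[mask].mean()
    assert rel["dmas"] < rel["das"]


@pytest.fixture(scope="module")
def pipeline():
    cfg = PhantomConfig(
        depth_mm=40.0, width_mm=60.0, alns=(ALNSpec(depth_mm=15.0, long_axis_mm=8.0),),
        n_antennas=4, span_mm=30.0,
    )
    ph = build_phantom(cfg)
    rng = np.random.default_rng(2)
    ch = make_channels(rng.standard_normal((4, 4000)), ph.antenna_xy_mm)
    return ph, ch


class TestReconstructDispatch:
    def test_case_insensitive_method_names(self, pipeline):
        ph, ch = pipeline
        a = reconstruct(ch, ph, "cr-dmas")
        b = reconstruct(ch, ph, "CR-DMAS")
        assert np.array_equal(a.values, b.values)

    def test_unknown_method_rejected(self, pipeline):
        ph, ch = pipeline
        with pytest.raises(ValueError):
            reconstruct(ch, ph, "MUSIC")

    def test_deterministic(self, pipeline):
        ph, ch = pipeline
        a = reconstruct(ch, ph, "DMAS")
        b = reconstruct(ch, ph, "DMAS")
        assert np.array_equal(a.values, b.values)

    def test_all_methods_nonnegative_finite(self, pipeline):
        ph, ch = pipeline
        for method in ("DAS", "DMAS", "CR-DAS", "CR-DMAS"):
            v = reconstruct(ch, ph, method).values
            assert np.isfinite(v).all() and (v >= 0).all()

    def test_excessive_delay_flags_invalid_pixels(self, pipeline):
        ph, _ = pipeline
        rng = np.random.default_rng(3)
        short = make_channels(rng.standard_normal((4, 120)), ph.antenna_xy_mm)
        emap = reconstruct(short, ph, "DAS")
        assert emap.meta["n_invalid_pixels"] > 0
        assert (emap.values.reshape(-1)[-1]) == 0.0  # deepest corner unreachable
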