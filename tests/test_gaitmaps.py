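import numpy as np
import pytest

from gaitrep import gaitmaps as gm
from gaitrep import preprocess as pp
from .conftest import random_blob


def _cps(frames):
    frames = np.stack([np.asarray(f, dtype=np.uint8) for f in frames])
    return pp.CroppedPaddedSequence(frames=frames, per_frame_sizes=[None] * len(frames))


def _translated_cycle(rng, n=5, shape=(48, 48)):
    """Cycle of one blob rigidly translated; all traces equal length."""
    blob = random_blob(rng, shape=(32, 32))
    frames = []
    for i in range(n):
        canvas = np.zeros(shape, dtype=np.uint8)
        dy, dx = 4 + (i % 3), 4 + 2 * (i % 4)
        canvas[dy : dy + 32, dx : dx + 32] = blob
        frames.append(canvas)
    return frames


class TestGEI:
    def test_static_cycle_reproduces_silhouette(self, rng):
        blob = random_blob(rng)
        m = gm.gei(_cps([blob] * 5))
        assert np.array_equal(m.pixels, blob.astype(float))

    def test_disjoint_halves_average_to_half(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[:, :2] = 1
        b = np.zeros((4, 4), dtype=np.uint8)
        b[:, 2:] = 1
        m = gm.gei(_cps([a, b]))
        assert np.allclose(m.pixels, 0.5)

    def test_matches_bruteforce_mean(self, rng):
        frames = [(rng.random((6, 6)) > 0.5).astype(np.uint8) for _ in range(5)]
        m = gm.gei(_cps(frames))
        expected = sum(f.astype(float) for f in frames) / 5
        assert np.allclose(m.pixels, expected)
        assert 0 <= m.pixels.min() and m.pixels.max() <= 1


class TestTGBI:
    def test_static_cycle_boundary_value_closed_form(self, rng):
        """N identical frames: boundary pixels get (1+..+N)/N = (N+1)/2."""
        blob = random_blob(rng)
        cps = _cps([blob] * 3)
        traces = [pp.trace_boundary(f) for f in cps.frames]
        m = gm.tgbi(cps, traces)
        on = m.pixels[m.pixels > 0]
        assert np.allclose(on, 2.0)
        bset = {(x, y) for x, y in traces[0].points}
        assert {(x, y) for y, x in zip(*np.nonzero(m.pixels))} == bset

    def test_single_frame_boundary_value_one(self, rng):
        blob = random_blob(rng)
        cps = _cps([blob])
        m = gm.tgbi(cps, [pp.trace_boundary(blob)])
        assert np.allclose(m.pixels[m.pixels > 0], 1.0)

    def test_matches_bruteforce_weighted_accumulation(self, rng):
        frames = _translated_cycle(rng, n=4)
        cps = _cps(frames)
        traces = [pp.trace_boundary(f) for f in cps.frames]
        m = gm.tgbi(cps, traces)
        expected = np.zeros(cps.shape)
        for n, t in enumerate(traces, start=1):
            b = np.zeros(cps.shape)
            b[t.ys, t.xs] = 1
            expected += n * b
        assert np.allclose(m.pixels, expected / 4)

    def test_trace_count_mismatch_errors(self, rng):
        blob = random_blob(rng)
        cps = _cps([blob, blob])
        with pytest.raises(ValueError, match="mismatch"):
            gm.tgbi(cps, [pp.trace_boundary(blob)])


class TestCGEI:
    def test_three_frames_one_per_channel(self, rng):
        frames = [(rng.random((5, 5)) > 0.5).astype(np.uint8) for _ in range(3)]
        m = gm.cgei(_cps(frames))
        for c in range(3):
            assert np.allclose(m.pixels[..., c], frames[c] / 3)

    def test_channel_sum_equals_gei_when_divisible_by_three(self, rng):
        frames = [(rng.random((5, 5)) > 0.5).astype(np.uint8) for _ in range(6)]
        cps = _cps(frames)
        m = gm.cgei(cps)
        assert np.allclose(m.pixels.sum(axis=-1), gm.gei(cps).pixels)

    def test_floor_rule_segment_boundaries_for_n7(self, rng):
        frames = [(rng.random((4, 4)) > 0.5).astype(np.uint8) for _ in range(7)]
        m = gm.cgei(_cps(frames))
        # segments: frames 1-2 (red), 3-4 (green), 5-7 (blue), each / 7
        assert np.allclose(m.pixels[..., 0], (frames[0] + frames[1]) / 7)
        assert np.allclose(m.pixels[..., 1], (frames[2] + frames[3]) / 7)
        assert np.allclose(m.pixels[..., 2], (frames[4] + frames[5] + frames[6]) / 7)

    def test_too_few_frames_errors(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            gm.cgei(_cps([random_blob(rng)] * 2))


class TestTGDI:
    def test_static_cycle_is_identically_zero(self, rng):
        m = gm.tgdi(_cps([random_blob(rng)] * 4))
        assert not m.pixels.any()

    def test_single_shift_red_and_blue_halves(self):
        a = np.zeros((3, 4), dtype=np.uint8)
        a[:, 1] = 1
        b = np.zeros((3, 4), dtype=np.uint8)
        b[:, 2] = 1
        m = gm.tgdi(_cps([a, b]))
        assert np.allclose(m.pixels[:, 2, 0], 0.5)  # newly covered -> red
        assert np.allclose(m.pixels[:, 1, 2], 0.5)  # vacated -> blue
        assert not m.pixels[..., 1].any()

    def test_matches_bruteforce_accumulation(self, rng):
        frames = []
        for i in range(6):  # oscillating bar
            f = np.zeros((5, 8), dtype=np.uint8)
            f[:, 2 + (i % 2) * 2] = 1
            frames.append(f)
        m = gm.tgdi(_cps(frames))
        expected = np.zeros((5, 8, 3))
        for i in range(5):
            d = frames[i + 1].astype(int) - frames[i].astype(int)
            expected[..., 0] += (i + 1) * (d > 0)
            expected[..., 2] += (i + 1) * (d < 0)
        assert np.allclose(m.pixels, expected / 6)
        # total mass identity: (1/N) sum n * |changed pixels|
        mass = sum((i + 1) * np.abs(frames[i + 1].astype(int) - frames[i]).sum() for i in range(5))
        assert m.pixels[..., 0].sum() + m.pixels[..., 2].sum() == pytest.approx(mass / 6)

    def test_single_frame_errors(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            gm.tgdi(_cps([random_blob(rng)]))


class TestCBIT:
    def test_square_block_single_column(self):
        m5 = np.zeros((5, 5), dtype=np.uint8)
        m5[1:4, 1:4] = 1
        trace = pp.trace_boundary(m5)
        m = gm.cbit([trace], (5, 5))
        assert m.pixels.shape == (8, 1, 3)
        assert np.allclose(m.pixels[:, 0, 0], trace.xs / 4)
        assert np.allclose(m.pixels[:, 0, 2], trace.ys / 4)
        assert not m.pixels[..., 1].any()

    def test_identical_traces_identical_columns(self, rng):
        blob = random_blob(rng)
        t = pp.trace_boundary(blob)
        m = gm.cbit([t] * 4, blob.shape)
        for j in range(1, 4):
            assert np.array_equal(m.pixels[:, j], m.pixels[:, 0])

    def test_roundtrip_recovers_masks(self, rng):
        frames = _translated_cycle(rng, n=6)
        traces = [pp.trace_boundary(f) for f in frames]
        assert len({len(t) for t in traces}) == 1  # no resampling involved
        m = gm.cbit(traces, frames[0].shape)
        recovered = gm.decode_cbit(m)
        for orig, rec in zip(frames, recovered):
            assert np.array_equal(rec, orig)

    def test_normalized_coordinates_in_unit_interval(self, rng):
        traces = [pp.trace_boundary(random_blob(rng)) for _ in range(3)]
        m = gm.cbit(traces, (48, 48))
        assert m.pixels.min() >= 0 and m.pixels.max() <= 1
        assert m.meta["n_boundary"] == max(len(t) for t in traces)


class TestBuildAll:
    def test_five_kinds_produced(self, rng):
        frames = _translated_cycle(rng, n=6)
        cps = _cps(frames)
        traces = [pp.trace_boundary(f) for f in cps.frames]
        maps = gm.build_all(cps, traces)
        assert [m.kind for m in maps] == list(gm.MAP_KINDS)

    def test_static_cycle_identities(self, rng):
        blob = random_blob(rng)
        cps = _cps([blob] * 6)
        traces = [pp.trace_boundary(f) for f in cps.frames]
        maps = {m.kind: m for m in gm.build_all(cps, traces)}
        assert not maps["tGDI"].pixels.any()
        assert np.array_equal(maps["GEI"].pixels, blob.astype(float))

    def test_unknown_kind_rejected(self, rng):
        blob = random_blob(rng)
        with pytest.raises(ValueError, match="unknown map kinds"):
            gm.build_all(_cps([blob]), [pp.trace_boundary(blob)], kinds=("GEI", "XYZ"))

    def test_deterministic_bitwise(self, rng):
        frames = _translated_cycle(rng, n=5)
        cps = _cps(frames)
        traces = [pp.trace_boundary(f) for f in cps.frames]
        a = gm.build_all(cps, traces)
        b = gm.build_all(cps, traces)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.pixels, mb.pixels)
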