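"""Acoustic feature formulas vs independent brute-force evaluation, and
fundamental-frequency tracking on constructed calls."""

import math

import numpy as np
import pytest

from usvsex import features as ft
from usvsex import segment as sg
from usvsex import synth as sy

# ---------------------------------------------------------------------------
# brute-force oracles: plain loops, independent of the implementation


def brute_wiener_entropy(spec):
    vals = []
    F, T = spec.shape
    for t in range(T):
        col = [spec[f, t] for f in range(F)]
        m = sum(col) / F
        if m <= 0:
            continue
        if any(v <= 0 for v in col):
            vals.append(0.0)
        else:
            logs = sum(math.log(v) for v in col) / F
            vals.append(math.exp(logs) / m)
    return sum(vals) / len(vals)


def brute_spectral_purity(spec):
    vals = []
    F, T = spec.shape
    for t in range(T):
        col = sorted(spec[f, t] for f in range(F))
        mx = col[-1]
        if mx <= 0:
            continue
        if F % 2:
            med = col[F // 2]
        else:
            med = 0.5 * (col[F // 2 - 1] + col[F // 2])
        if med <= 0:
            med = min(v for v in col if v > 0)
        vals.append(mx / med)
    return sum(vals) / len(vals)


def brute_salience_sequence(x):
    n = len(x)
    mean = sum(x) / n
    xc = [v - mean for v in x]
    ac = []
    for lag in range(n):
        ac.append(sum(xc[i] * xc[i + lag] for i in range(n - lag)))
    if ac[0] <= 0:
        return 0.0
    best = 0.0
    for lag in range(1, n - 1):
        if ac[lag] > ac[lag - 1] and ac[lag] >= ac[lag + 1]:
            best = max(best, ac[lag])
    return best / ac[0]


def brute_spectral_salience(spec):
    vals = []
    F, T = spec.shape
    for t in range(T):
        col = [spec[f, t] for f in range(F)]
        if max(col) <= 0:
            continue
        vals.append(brute_salience_sequence(col))
    return sum(vals) / len(vals)


def brute_weighted_mean_freq(spec, freq):
    vals = []
    F, T = spec.shape
    for t in range(T):
        s = sum(spec[f, t] for f in range(F))
        if s <= 0:
            continue
        vals.append(sum(freq[f] * spec[f, t] for f in range(F)) / s)
    return sum(vals) / len(vals)


def brute_direction(ff):
    diffs = [ff[i + 1] - ff[i] for i in range(len(ff) - 1)]
    m = sum(diffs) / len(diffs)
    return 0 if abs(m) < 1e-9 else (1 if m > 0 else -1)


BRUTE = {
    "wiener_entropy": (brute_wiener_entropy, ft.wiener_entropy),
    "spectral_purity": (brute_spectral_purity, ft.spectral_purity),
    "spectral_salience": (brute_spectral_salience, ft.spectral_salience),
}


class TestFormulaOracles:
    @pytest.mark.parametrize("name", sorted(BRUTE))
    def test_matches_brute_force_on_random_matrices(self, name):
        brute, impl = BRUTE[name]
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = rng.uniform(0.1, 10.0, size=(20, 20))
            a, b = brute(m), impl(m)
            assert b == pytest.approx(a, rel=1e-9)

    def test_weighted_mean_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            m = rng.uniform(0.0, 10.0, size=(20, 20))
            freq = np.linspace(25, 125, 20)
            assert ft.weighted_mean_frequency(m, freq) == pytest.approx(
                brute_weighted_mean_freq(m, freq), rel=1e-9)

    def test_direction_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            ff = rng.uniform(30, 100, size=12)
            assert ft.direction_of(ff) == brute_direction(list(ff))


class TestWienerEntropy:
    def test_flat_frame_is_one(self):
        assert ft.wiener_entropy(np.full((8, 3), 2.0)) == pytest.approx(1.0)

    def test_zero_bin_gives_zero(self):
        m = np.ones((4, 1))
        m[2, 0] = 0.0
        assert ft.wiener_entropy(m) == 0.0

    def test_two_bin_frame(self):
        # G = sqrt(1*4) = 2, mean = 2.5 -> WE = 0.8
        m = np.array([[1.0], [4.0]])
        assert ft.wiener_entropy(m) == pytest.approx(0.8)

    def test_bounds_on_random(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = rng.uniform(0, 5, size=(15, 10))
            we = ft.wiener_entropy(m)
            assert 0.0 <= we <= 1.0


class TestSpectralPurity:
    def test_flat_frame(self):
        assert ft.spectral_purity(np.full((9, 2), 3.0)) == pytest.approx(1.0)

    def test_max_over_median(self):
        col = np.ones(9)
        col[0] = 10.0
        assert ft.spectral_purity(col[:, None]) == pytest.approx(10.0)

    def test_average_over_frames(self):
        # frames engineered to purities 2 and 4 -> average 3
        f1 = np.array([1.0, 1.0, 2.0])
        f2 = np.array([1.0, 1.0, 4.0])
        m = np.stack([f1, f2], axis=1)
        assert ft.spectral_purity(m) == pytest.approx(3.0)

    def test_at_least_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            assert ft.spectral_purity(rng.uniform(0.1, 1, (11, 7))) >= 1.0


class TestSalience:
    def test_periodic_ripple_detected(self):
        f = np.arange(40)
        col = 1.0 + np.cos(2 * np.pi * f / 5)  # period 5 bins
        val = ft._salience_of_sequence(col)
        assert val == pytest.approx(brute_salience_sequence(list(col)),
                                    rel=1e-9)
        assert val > 0.5

    def test_white_noise_low(self):
        rng = np.random.default_rng(17)
        vals = [ft._salience_of_sequence(rng.uniform(0, 1, 233))
                for _ in range(20)]
        assert np.mean(vals) < 0.2

    def test_identical_frames_average(self):
        col = 1.0 + np.cos(2 * np.pi * np.arange(30) / 6)
        m = np.stack([col, col], axis=1)
        assert ft.spectral_salience(m) == pytest.approx(
            ft._salience_of_sequence(col))


class TestTremolo:
    def _track(self, ff):
        ff = np.asarray(ff, dtype=float)
        return ft.FundamentalTrack(ff_khz=ff, fe=np.where(ff > 0, 1.0, 0.0))

    def test_sinusoidal_modulation_high(self):
        t = np.arange(40)
        ff = 60 + 5 * np.sin(2 * np.pi * t / 8)
        assert ft.tremolo_score(self._track(ff)) > 0.5

    def test_constant_ff_zero(self):
        assert ft.tremolo_score(self._track(np.full(20, 60.0))) == 0.0

    def test_sweep_below_sinusoid(self):
        t = np.arange(40)
        sweep = 50 + 0.5 * t
        sinus = 60 + 5 * np.sin(2 * np.pi * t / 8)
        assert ft.tremolo_score(self._track(sweep)) < \
            ft.tremolo_score(self._track(sinus))

    def test_short_track_undefined(self):
        assert math.isnan(ft.tremolo_score(self._track([60, 60, 61])))


class TestDenoise:
    def test_constant_matrix_unchanged(self):
        m = np.full((30, 30), 4.0)
        out = ft.denoise_curvature_flow(m, 10)
        assert np.allclose(out, m)

    def test_salt_noise_energy_reduced(self):
        rng = np.random.default_rng(0)
        m = np.zeros((60, 60))
        idx = rng.integers(0, 60, size=(80, 2))
        m[idx[:, 0], idx[:, 1]] = 5.0
        out = ft.denoise_curvature_flow(m, 10)
        assert out.sum() <= 0.1 * m.sum()

    def test_ridge_track_preserved(self, flat_call_patch):
        patch = ft.to_millisecond_patch(flat_call_patch.values) ** 2
        out = ft.denoise_curvature_flow(patch, 10)
        t_pre = np.argmax(patch, axis=0)
        t_post = np.argmax(out, axis=0)
        assert np.mean(np.abs(t_pre - t_post) <= 1) >= 0.95


class TestFundamentalTrack:
    def _patch(self, spec):
        wave = sy.synthesize_call(spec)
        cfg = sg.SegmentationConfig()
        sp = sg.stft_magnitude(wave, cfg)
        return ft.to_millisecond_patch(sp.values) ** 2

    def test_flat_call_tracked(self, flat_call_spec):
        patch = self._patch(flat_call_spec)
        track = ft.extract_fundamental(ft.denoise_curvature_flow(patch))
        voiced = track.ff_khz[track.voiced]
        assert len(voiced) == track.n_frames  # no spurious breaks
        assert np.all(np.abs(voiced - 60.0) <= 0.7)

    def test_break_yields_zero_run(self):
        spec = sy.TrajectorySpec(
            duration_ms=50.0,
            segments=(sy.TrajectorySegment("flat", 60.0, 60.0),),
            breaks=((22.0, 5.0),))
        patch = self._patch(spec)
        track = ft.extract_fundamental(ft.denoise_curvature_flow(patch))
        assert track.n_breaks == 1
        z = np.flatnonzero(~track.voiced)
        assert len(z) >= 2 and np.all(np.diff(z) == 1)

    def test_outlier_replaced(self):
        freq = 10.8 + np.arange(233) * 0.6
        patch = np.zeros((233, 9))
        row60 = int(round((60 - 10.8) / 0.6))
        row70 = int(round((70 - 10.8) / 0.6))
        patch[row60, :] = 5.0
        patch[row60, 4] = 0.0
        patch[row70, 4] = 6.0  # single-frame 10 kHz spike
        track = ft.extract_fundamental(patch, freq)
        assert track.ff_khz[4] == pytest.approx(track.ff_khz[3], abs=0.7)

    def test_empty_patch_raises(self):
        with pytest.raises(ValueError):
            ft.extract_fundamental(np.zeros((233, 10)))


class TestMarginals:
    def test_flat_call_single_bin(self):
        ff = np.full(30, 60.0)
        track = ft.FundamentalTrack(ff_khz=ff, fe=np.full(30, 2.5))
        marg = ft.spectral_marginal(track)
        nz = np.flatnonzero(marg)
        assert len(nz) == 1
        assert marg[nz[0]] == pytest.approx(2.5)

    def test_sweep_support(self):
        freq = 10.8 + np.arange(233) * 0.6
        ff = freq[50] + (freq[80] - freq[50]) * np.linspace(0, 1, 200)
        track = ft.FundamentalTrack(ff_khz=ff, fe=np.ones(200))
        marg = ft.spectral_marginal(track)
        nz = np.flatnonzero(marg)
        assert nz[0] == 50 and nz[-1] == 80
        assert np.all(marg[50:81] > 0)

    def test_all_break_zero_vector(self):
        track = ft.FundamentalTrack(ff_khz=np.array([60.0, 0, 0, 60.0]),
                                    fe=np.array([0.0, 0, 0, 0.0]))
        assert ft.spectral_marginal(track).sum() == 0

    def test_fixed_dimensions(self):
        ff = np.full(130, 60.0)  # longer than 100 ms -> cut
        track = ft.FundamentalTrack(ff_khz=ff, fe=np.ones(130))
        assert len(ft.ff_line_100(track)) == 100
        assert len(ft.time_marginal_100(track)) == 100
        assert len(ft.spectral_marginal(track)) == 233


class TestScalarFeatures:
    def test_flat_call_degenerate_values(self):
        ff = np.full(50, 60.0)
        track = ft.FundamentalTrack(ff_khz=ff, fe=np.full(50, 1.0))
        row = int(round((60 - 10.8) / 0.6))
        spec = np.zeros((233, 50))
        spec[row] = 1.0
        s = ft.scalar_features(track, spec)
        assert s["spectral_width_khz"] == 0.0
        assert s["direction"] == 0
        for key in ("start_freq_khz", "end_freq_khz", "min_freq_khz",
                    "max_freq_khz", "mean_freq_ff_khz"):
            assert s[key] == pytest.approx(60.0)
        assert s["duration_ms"] == pytest.approx(50.0)

    def test_direction_sign_of_mean_step(self):
        # diffs (+2, -1) -> mean +0.5 -> direction +1
        assert ft.direction_of(np.array([50.0, 52.0, 51.0])) == 1

    def test_weighted_mean_symmetric(self):
        freq = 10.8 + np.arange(233) * 0.6
        spec = np.zeros((233, 4))
        r40 = np.argmin(np.abs(freq - 40.0))
        r80 = np.argmin(np.abs(freq - 80.0))
        spec[r40] = spec[r80] = 1.0
        assert ft.weighted_mean_frequency(spec, freq) == pytest.approx(
            (freq[r40] + freq[r80]) / 2)

    def test_bounds_invariants(self):
        rng = np.random.default_rng(23)
        ff = rng.uniform(40, 90, size=30)
        track = ft.FundamentalTrack(ff_khz=ff,
                                    fe=rng.uniform(0.5, 2, size=30))
        spec = rng.uniform(0.01, 1.0, size=(233, 30))
        s = ft.scalar_features(track, spec)
        assert s["min_freq_khz"] <= s["mean_freq_ff_khz"] \
            <= s["max_freq_khz"]
        assert s["spectral_width_khz"] >= 0
        assert 0 <= s["wiener_entropy"] <= 1
        assert s["spectral_purity"] >= 1


class TestExtendedVector:
    def _parts(self):
        scalars = {k: float(i) for i, k in enumerate(ft.SCALAR_NAMES)}
        scores = {k: 0.0 for k in ft.HUMAN_NAMES}
        return scalars, scores

    def test_length_457(self):
        scalars, scores = self._parts()
        vec = ft.assemble_extended_vector(scalars, scores, np.zeros(100),
                                          np.zeros(233), np.zeros(100))
        assert len(vec) == 457

    def test_zero_marginals_zero_tail(self):
        scalars, scores = self._parts()
        vec = ft.assemble_extended_vector(scalars, scores, np.zeros(100),
                                          np.zeros(233), np.zeros(100))
        assert np.all(vec[24:] == 0)

    def test_dimension_mismatch_raises(self):
        scalars, scores = self._parts()
        with pytest.raises(ValueError):
            ft.assemble_extended_vector(scalars, scores, np.zeros(99),
                                        np.zeros(233), np.zeros(100))

    def test_round_trip_is_bit_identical(self, tmp_path):
        scalars, scores = self._parts()
        rng = np.random.default_rng(1)
        vec = ft.assemble_extended_vector(
            scalars, scores, rng.uniform(size=100), rng.uniform(size=233),
            rng.uniform(size=100))
        path = tmp_path / "vec.npy"
        np.save(path, vec)
        assert np.array_equal(np.load(path), vec)
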