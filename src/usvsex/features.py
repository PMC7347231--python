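"""Acoustic property extraction for single ultrasonic vocalizations.

Works on a full-band spectrogram patch S(f, t) of one call (233 frequency
rows at 600 Hz spacing, time resampled to 1 ms frames, power units
S = |STFT|^2).  The pipeline is:

1. min/max level-set curvature-flow denoising (removes isolated speckle
   while preserving the high-energy ridge of the call),
2. fundamental-frequency tracking: a Prewitt edge map delimits the call's
   temporal extent; within it, FF(t) is the frequency of the maximal bin,
   FF(t) = 0 marks break frames, and single-frame outliers deviating more
   than 5 kHz from both neighbours are interpolated,
3. formula-defined scalar features (Wiener entropy, spectral purity,
   spectral salience, tremolo, moments, frequency statistics, direction),
4. fixed-dimension marginals (FF line 100, time marginal 100, frequency
   marginal 233) assembled with 24 scalar slots into a 457-dim vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from skimage.filters import prewitt

N_FREQ_ROWS = 233
BIN_KHZ = 0.6
FREQ0_KHZ = 10.8  # frequency of the first of the 233 rows
FF_DIM = 100
OUTLIER_KHZ = 5.0

SCALAR_NAMES = (
    "duration_ms", "spectral_width_khz", "start_freq_khz", "end_freq_khz",
    "min_freq_khz", "max_freq_khz", "mean_freq_ff_khz",
    "mean_freq_weighted_khz", "temporal_skewness", "temporal_kurtosis",
    "spectral_skewness", "spectral_kurtosis", "direction", "wiener_entropy",
    "spectral_salience", "tremolo", "spectral_energy", "spectral_purity",
)
HUMAN_NAMES = ("direction_scored", "n_peaks", "n_breaks", "broadband",
               "tremolo_scored", "complex")
EXTENDED_DIM = len(SCALAR_NAMES) + len(HUMAN_NAMES) + FF_DIM \
    + N_FREQ_ROWS + FF_DIM  # 24 + 100 + 233 + 100 = 457


# ---------------------------------------------------------------------------
# denoising


def denoise_curvature_flow(spec: np.ndarray,
                           n_iterations: int = 5) -> np.ndarray:
    """Min/max level-set curvature flow at pixel scale.

    Motion by curvature is realized by its standard discrete equivalent,
    the median of the 3x3 stencil; the min/max switch compares the local
    neighbourhood average against the global median so that isolated
    bright speckle over background is eroded (min flow) while structure
    darker than its surround is filled (max flow).  Elongated high-energy
    ridges wider than one pixel are fixed points of the stencil median and
    remain nearly unchanged, as do constant regions.
    """
    from scipy.ndimage import median_filter, uniform_filter

    u = np.asarray(spec, dtype=np.float64).copy()
    if u.size == 0 or n_iterations <= 0:
        return u
    thresh = np.median(u)
    for _ in range(n_iterations):
        med = median_filter(u, size=3, mode="nearest")
        local = uniform_filter(u, size=3, mode="nearest")
        u = np.where(local > thresh, np.minimum(u, med),
                     np.maximum(u, med))
        np.clip(u, 0.0, None, out=u)
    return u


# ---------------------------------------------------------------------------
# fundamental frequency tracking


@dataclass
class FundamentalTrack:
    """FF(t)/FE(t) over the call's temporal extent (1 ms frames).

    ``ff_khz`` is 0 on break frames; ``fe`` holds S(FF(t), t) where
    FF(t) > 0 and 0 elsewhere.
    """

    ff_khz: np.ndarray
    fe: np.ndarray
    frame_ms: float = 1.0

    def __post_init__(self):
        if len(self.ff_khz) < 1:
            raise ValueError("track must span at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.ff_khz)

    @property
    def voiced(self) -> np.ndarray:
        return self.ff_khz > 0

    @property
    def n_breaks(self) -> int:
        """Number of contiguous zero-runs (interruptions of the line)."""
        z = ~self.voiced
        return int(np.sum(z[1:] & ~z[:-1]) + (1 if z.size and z[0] else 0))


def edge_map(spec: np.ndarray, rel_threshold: float = 3.0) -> np.ndarray:
    """Binary Prewitt edge map; threshold = rel_threshold x mean gradient
    magnitude (the conventional automatic-threshold heuristic)."""
    g = prewitt(spec)
    g = np.abs(g)
    mean = g.mean()
    if mean <= 0:
        return np.zeros_like(g, dtype=bool)
    return g > rel_threshold * mean


def extract_fundamental(spec: np.ndarray,
                        freq_khz: np.ndarray | None = None,
                        frame_ms: float = 1.0) -> FundamentalTrack:
    """Track the fundamental-frequency line of a denoised call patch.

    The temporal range is limited to frames bearing at least one edge; the
    fundamental per frame is the maximal-amplitude bin.  Interior frames
    without edges are break frames (FF = 0).  Raises if no edges exist.
    """
    spec = np.asarray(spec, dtype=np.float64)
    if freq_khz is None:
        freq_khz = FREQ0_KHZ + np.arange(spec.shape[0]) * BIN_KHZ
    edges = edge_map(spec)
    has_edge = edges.any(axis=0)
    idx = np.flatnonzero(has_edge)
    if idx.size == 0:
        raise ValueError("no edges found: empty track")
    t0, t1 = idx[0], idx[-1]
    sub = spec[:, t0:t1 + 1]
    sub_edge = has_edge[t0:t1 + 1]
    argmax = np.argmax(sub, axis=0)
    ff = np.where(sub_edge, freq_khz[argmax], 0.0)
    # the fundamental is undefined on energy-dead columns (edge frames can
    # carry boundary edges but no signal): treat them as unvoiced
    colmax = sub.max(axis=0)
    ff[colmax <= 1e-6 * colmax.max()] = 0.0
    voiced_idx = np.flatnonzero(ff > 0)
    if voiced_idx.size == 0:
        raise ValueError("no voiced frames: empty track")
    ff = ff[voiced_idx[0]:voiced_idx[-1] + 1]
    sub = sub[:, voiced_idx[0]:voiced_idx[-1] + 1]

    # single-frame >5 kHz outliers are replaced by neighbour interpolation
    ff = ff.copy()
    for t in range(1, len(ff) - 1):
        if ff[t - 1] > 0 and ff[t] > 0 and ff[t + 1] > 0:
            if (abs(ff[t] - ff[t - 1]) > OUTLIER_KHZ
                    and abs(ff[t] - ff[t + 1]) > OUTLIER_KHZ):
                ff[t] = 0.5 * (ff[t - 1] + ff[t + 1])

    bins = np.clip(np.round((ff - freq_khz[0]) / (freq_khz[1] - freq_khz[0])
                            ).astype(int), 0, spec.shape[0] - 1)
    fe = np.where(ff > 0, sub[bins, np.arange(sub.shape[1])], 0.0)
    return FundamentalTrack(ff_khz=ff, fe=fe, frame_ms=frame_ms)


# ---------------------------------------------------------------------------
# marginals


def ff_line_100(track: FundamentalTrack) -> np.ndarray:
    """FF(t) cut/zero-padded to 100 frames (100 ms at 1 ms resolution)."""
    out = np.zeros(FF_DIM)
    n = min(track.n_frames, FF_DIM)
    out[:n] = track.ff_khz[:n]
    return out


def time_marginal_100(track: FundamentalTrack) -> np.ndarray:
    """FE(t) cut/zero-padded to 100 frames."""
    out = np.zeros(FF_DIM)
    n = min(track.n_frames, FF_DIM)
    out[:n] = track.fe[:n]
    return out


def spectral_marginal(track: FundamentalTrack,
                      freq_khz: np.ndarray | None = None) -> np.ndarray:
    """Temporal average of FE per frequency bin on the fixed 233-bin axis.

    Each voiced frame contributes FE(t) to the bin containing FF(t); the
    bin value is the mean of its contributions.
    """
    if freq_khz is None:
        freq_khz = FREQ0_KHZ + np.arange(N_FREQ_ROWS) * BIN_KHZ
    sums = np.zeros(len(freq_khz))
    counts = np.zeros(len(freq_khz))
    step = freq_khz[1] - freq_khz[0]
    for f, e in zip(track.ff_khz, track.fe):
        if f > 0 and e > 0:
            b = int(np.clip(round((f - freq_khz[0]) / step), 0,
                            len(freq_khz) - 1))
            sums[b] += e
            counts[b] += 1
    return sums / np.maximum(counts, 1)


# ---------------------------------------------------------------------------
# formula features


def wiener_entropy(spec: np.ndarray) -> float:
    """Temporal average of per-frame spectral flatness G(S)/mean(S).

    1 for flat (noise-like) frames, 0 whenever a zero bin enters the
    geometric mean; all-zero frames are skipped.
    """
    spec = np.asarray(spec, dtype=np.float64)
    vals = []
    for t in range(spec.shape[1]):
        col = spec[:, t]
        m = col.mean()
        if m <= 0:
            continue
        if np.any(col <= 0):
            vals.append(0.0)
        else:
            g = math.exp(np.mean(np.log(col)))
            vals.append(g / m)
    return float(np.mean(vals)) if vals else float("nan")


def _salience_of_sequence(x: np.ndarray) -> float:
    """Ratio of the largest off-zero local maximum to the zero-lag peak of
    the autocorrelation of the mean-subtracted sequence; 0 if no interior
    peak exists or the sequence is constant."""
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    ac0 = float(np.dot(x, x))
    if ac0 <= 0:
        return 0.0
    n = len(x)
    ac = np.correlate(x, x, mode="full")[n - 1:]  # lags 0..n-1
    best = 0.0
    for lag in range(1, n - 1):
        if ac[lag] > ac[lag - 1] and ac[lag] >= ac[lag + 1]:
            best = max(best, ac[lag])
    return best / ac0


def spectral_salience(spec: np.ndarray) -> float:
    """Temporal average of the across-frequency autocorrelation salience
    (detects periodic spectral structure); zero frames are skipped."""
    spec = np.asarray(spec, dtype=np.float64)
    vals = []
    for t in range(spec.shape[1]):
        col = spec[:, t]
        if col.max() <= 0:
            continue
        vals.append(_salience_of_sequence(col))
    return float(np.mean(vals)) if vals else float("nan")


def tremolo_score(track: FundamentalTrack) -> float:
    """Salience of the voiced FF(t) sequence itself.

    The sequence is mean-subtracted before autocorrelation, so a constant
    fundamental scores exactly 0; fewer than 4 voiced frames -> NaN.
    """
    ff = track.ff_khz[track.voiced]
    if len(ff) < 4:
        return float("nan")
    return _salience_of_sequence(ff)


def spectral_purity(spec: np.ndarray) -> float:
    """Temporal average of max/median across frequency per frame (>= 1 for
    any non-degenerate frame).  A zero median is replaced by the smallest
    positive value in the frame; all-zero frames are skipped."""
    spec = np.asarray(spec, dtype=np.float64)
    vals = []
    for t in range(spec.shape[1]):
        col = spec[:, t]
        mx = col.max()
        if mx <= 0:
            continue
        med = np.median(col)
        if med <= 0:
            med = col[col > 0].min()
        vals.append(mx / med)
    return float(np.mean(vals)) if vals else float("nan")


def weighted_mean_frequency(spec: np.ndarray,
                            freq_khz: np.ndarray | None = None) -> float:
    """Average over frames of the per-frame intensity-weighted frequency
    centroid of the raw spectrogram; zero frames are skipped."""
    spec = np.asarray(spec, dtype=np.float64)
    if freq_khz is None:
        freq_khz = FREQ0_KHZ + np.arange(spec.shape[0]) * BIN_KHZ
    vals = []
    for t in range(spec.shape[1]):
        col = spec[:, t]
        s = col.sum()
        if s <= 0:
            continue
        vals.append(float(np.dot(freq_khz, col)) / s)
    return float(np.mean(vals)) if vals else float("nan")


def direction_of(ff_voiced: np.ndarray) -> int:
    """Sign of the mean single-step difference of the voiced FF sequence."""
    if len(ff_voiced) < 2:
        return 0
    m = float(np.mean(np.diff(ff_voiced)))
    if abs(m) < 1e-9:
        return 0
    return 1 if m > 0 else -1


def _moments(x: np.ndarray, sample: bool = False):
    """(skewness, kurtosis); population (biased) definitions by default,
    Pearson kurtosis (normal -> 3).  Undefined for < 2 points or zero
    variance -> NaN."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2 or np.std(x) == 0:
        return float("nan"), float("nan")
    bias = not sample
    sk = float(sstats.skew(x, bias=bias))
    ku = float(sstats.kurtosis(x, bias=bias, fisher=False))
    return sk, ku


def scalar_features(track: FundamentalTrack, spec: np.ndarray,
                    freq_khz: np.ndarray | None = None,
                    sample_moments: bool = False) -> dict:
    """All 18 automatically extracted scalar properties of one call."""
    voiced = track.ff_khz[track.voiced]
    if voiced.size == 0:
        raise ValueError("track has no voiced frames")
    fe_voiced = track.fe[track.voiced]
    marg = spectral_marginal(track, freq_khz)
    t_skew, t_kurt = _moments(fe_voiced, sample_moments)
    support = marg[marg > 0]
    s_skew, s_kurt = _moments(support, sample_moments) if support.size >= 2 \
        else (float("nan"), float("nan"))
    out = {
        "duration_ms": track.n_frames * track.frame_ms,
        "spectral_width_khz": float(voiced.max() - voiced.min()),
        "start_freq_khz": float(voiced[0]),
        "end_freq_khz": float(voiced[-1]),
        "min_freq_khz": float(voiced.min()),
        "max_freq_khz": float(voiced.max()),
        "mean_freq_ff_khz": float(voiced.mean()),
        "mean_freq_weighted_khz": weighted_mean_frequency(spec, freq_khz),
        "temporal_skewness": t_skew,
        "temporal_kurtosis": t_kurt,
        "spectral_skewness": s_skew,
        "spectral_kurtosis": s_kurt,
        "direction": direction_of(voiced),
        "wiener_entropy": wiener_entropy(spec),
        "spectral_salience": spectral_salience(spec),
        "tremolo": tremolo_score(track),
        "spectral_energy": float(fe_voiced.mean()),
        "spectral_purity": spectral_purity(spec),
    }
    return out


def assemble_extended_vector(scalars: dict, scores: dict,
                             ff_line: np.ndarray, freq_marginal: np.ndarray,
                             time_marginal: np.ndarray) -> np.ndarray:
    """Fixed 457-dim layout: 18 automatic scalars, 6 scored slots, FF line
    (100), frequency marginal (233), time marginal (100)."""
    if len(ff_line) != FF_DIM or len(time_marginal) != FF_DIM \
            or len(freq_marginal) != N_FREQ_ROWS:
        raise ValueError("marginal dimension mismatch")
    head = [scalars[k] for k in SCALAR_NAMES] + [scores[k]
                                                 for k in HUMAN_NAMES]
    vec = np.concatenate([np.asarray(head, dtype=np.float64),
                          ff_line, freq_marginal, time_marginal])
    assert len(vec) == EXTENDED_DIM
    return vec


def to_millisecond_patch(patch: np.ndarray,
                         frame_ms: float = 1000.0 * 250 / 300_000
                         ) -> np.ndarray:
    """Resample a full-resolution patch (233 x T frames of ``frame_ms``) to
    1 ms time pixels, the analysis resolution of this module."""
    from skimage.transform import resize
    n_ms = max(int(round(patch.shape[1] * frame_ms)), 1)
    return resize(patch, (patch.shape[0], n_ms), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def analyze_call(patch: np.ndarray, scores: dict | None = None,
                 freq_khz: np.ndarray | None = None,
                 denoise_iterations: int = 5,
                 frame_ms: float = 1.0):
    """Full per-call analysis: denoise -> track -> scalars + marginals.

    ``patch`` is a full-band power patch (233 x T, 1 ms frames).  Returns
    (scalars dict, FundamentalTrack, marginals dict, extended 457-vector
    when ``scores`` is given else None).
    """
    den = denoise_curvature_flow(patch, denoise_iterations)
    track = extract_fundamental(den, freq_khz, frame_ms)
    scalars = scalar_features(track, den, freq_khz)
    marginals = {
        "ff_line": ff_line_100(track),
        "freq_marginal": spectral_marginal(track, freq_khz),
        "time_marginal": time_marginal_100(track),
    }
    vec = None
    if scores is not None:
        vec = assemble_extended_vector(scalars, scores, marginals["ff_line"],
                                       marginals["freq_marginal"],
                                       marginals["time_marginal"])
    return scalars, track, marginals, vec
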