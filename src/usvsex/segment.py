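"""Detection and extraction of ultrasonic vocalizations from raw audio.

The extraction pipeline operates on 300 kHz recordings:

1. 4th-order Butterworth high-pass at 25 kHz.
2. Magnitude spectrogram, 500-sample (1.67 ms) Hann windows, 50 % overlap
   (frame rate 1.2 kHz); the top 233 of 251 non-negative-frequency bins are
   kept (600 Hz spacing, ~10.8-150 kHz), matching the fixed analysis axis.
3. Sparsification: all bins below the recording-wide 70th percentile are
   zeroed.
4. Candidate intervals are contiguous runs of frames passing an energy gate
   (any bin above the recording-wide 99.8th percentile); candidates must
   additionally pass a spectral-continuity gate (the peak-frequency track
   must somewhere be locally stable) and a frequency gate (energy-weighted
   mean frequency >= 25 kHz).
5. Accepted intervals closer than 15 ms are merged into single calls.
6. Each call is exported as a left-aligned 100x100 uint8 image (1 ms time
   pixels rescaled by 100/233, calls longer than 100 ms truncated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from skimage.transform import resize

SAMPLE_RATE = 300_000


@dataclass(frozen=True)
class SegmentationConfig:
    sample_rate: int = SAMPLE_RATE
    hp_order: int = 4
    hp_cutoff_hz: float = 25_000.0
    win_len: int = 500
    overlap: float = 0.5
    window: str = "hann"
    n_freq_rows: int = 233        # top rows of the 251-bin rFFT axis
    sparsify_percentile: float = 70.0
    energy_quantile: float = 99.8
    continuity_window: int = 4    # accumulated |d(argmax row)| steps
    continuity_threshold: float = 15.0  # frequency-bin units
    min_mean_freq_khz: float = 25.0
    merge_gap_ms: float = 15.0
    min_duration_ms: float = 5.0
    max_duration_ms: float = 100.0
    image_size: int = 100

    def __post_init__(self):
        if not 0 < self.overlap < 1:
            raise ValueError("overlap must be in (0, 1)")
        for p in (self.sparsify_percentile, self.energy_quantile):
            if not 0 < p < 100:
                raise ValueError("percentiles must be in (0, 100)")
        if min(self.merge_gap_ms, self.max_duration_ms, self.win_len) <= 0:
            raise ValueError("durations must be positive")

    @property
    def hop(self) -> int:
        return int(round(self.win_len * (1 - self.overlap)))

    @property
    def frame_rate_hz(self) -> float:
        return self.sample_rate / self.hop

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def bin_hz(self) -> float:
        return self.sample_rate / self.win_len


@dataclass
class SpectrogramMatrix:
    """Non-negative magnitude time-frequency matrix with physical axes."""

    values: np.ndarray    # (F, T), magnitude
    freq_khz: np.ndarray  # (F,)
    time_ms: np.ndarray   # (T,)

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("spectrogram magnitudes must be non-negative")


@dataclass
class SegmentCandidate:
    start_frame: int
    end_frame: int  # inclusive
    onset_ms: float
    offset_ms: float
    passed_energy: bool = True
    passed_continuity: bool | None = None
    passed_frequency: bool | None = None

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class VocImage:
    pixels: np.ndarray  # (100, 100) uint8, freq x time, left-aligned
    n_cols: int         # occupied time columns
    truncated: bool
    onset_ms: float
    offset_ms: float


# ---------------------------------------------------------------------------


def highpass(waveform: np.ndarray, cfg: SegmentationConfig = None,
             order: int = 4, cutoff_hz: float = 25_000.0,
             sample_rate: int = SAMPLE_RATE) -> np.ndarray:
    """4th-order Butterworth high-pass (removes movement noise and DC)."""
    if cfg is not None:
        order, cutoff_hz = cfg.hp_order, cfg.hp_cutoff_hz
        sample_rate = cfg.sample_rate
    if cutoff_hz >= sample_rate / 2:
        raise ValueError("cutoff at or above Nyquist")
    sos = sps.butter(order, cutoff_hz, "highpass", fs=sample_rate,
                     output="sos")
    return sps.sosfilt(sos, waveform)


def stft_magnitude(waveform: np.ndarray,
                   cfg: SegmentationConfig) -> SpectrogramMatrix:
    """Magnitude spectrogram on the fixed 233-row frequency axis.

    Frame count is floor((N - win) / hop) + 1; no padding is applied, so
    the time axis marks window centers of fully valid windows.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    if len(waveform) < cfg.win_len:
        raise ValueError("waveform shorter than one analysis window")
    hop = cfg.hop
    frames = np.lib.stride_tricks.sliding_window_view(
        waveform, cfg.win_len)[::hop]
    win = sps.get_window(cfg.window, cfg.win_len)
    mags = np.abs(np.fft.rfft(frames * win, axis=1)).T  # (251, T)
    n_bins = cfg.win_len // 2 + 1
    row0 = n_bins - cfg.n_freq_rows
    values = np.ascontiguousarray(mags[row0:])
    freq_khz = (row0 + np.arange(cfg.n_freq_rows)) * cfg.bin_hz / 1000.0
    time_ms = (np.arange(values.shape[1]) * hop + cfg.win_len / 2) \
        / cfg.sample_rate * 1000.0
    return SpectrogramMatrix(values=values, freq_khz=freq_khz,
                             time_ms=time_ms)


def sparsify(spec: SpectrogramMatrix,
             percentile: float = 70.0) -> SpectrogramMatrix:
    """Zero all bins strictly below the recording-wide percentile."""
    if spec.values.size == 0:
        raise ValueError("empty spectrogram")
    thr = np.percentile(spec.values, percentile)
    vals = np.where(spec.values < thr, 0.0, spec.values)
    return SpectrogramMatrix(values=vals, freq_khz=spec.freq_khz,
                             time_ms=spec.time_ms)


def energy_gate(spec: SpectrogramMatrix,
                quantile: float = 99.8) -> np.ndarray:
    """Boolean time mask: frame kept iff any bin exceeds the recording-wide
    ``quantile`` of all bin values."""
    thr = np.percentile(spec.values, quantile)
    if spec.values.max() <= 0:
        return np.zeros(spec.values.shape[1], dtype=bool)
    return (spec.values >= thr).any(axis=0) if thr > 0 \
        else (spec.values > thr).any(axis=0)


def candidates_from_mask(mask: np.ndarray,
                         cfg: SegmentationConfig) -> list[SegmentCandidate]:
    """Contiguous runs of gate-passing frames become candidates."""
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits], [idx[-1]]])
    for s, e in zip(starts, ends):
        out.append(SegmentCandidate(
            start_frame=int(s), end_frame=int(e),
            onset_ms=s * cfg.frame_ms, offset_ms=(e + 1) * cfg.frame_ms))
    return out


def continuity_gate(spec: SpectrogramMatrix, cand: SegmentCandidate,
                    window: int = 4, threshold: float = 15.0) -> bool:
    """Spectral-continuity criterion.

    The peak-frequency (argmax row) track is followed across the candidate;
    absolute single-step jumps are accumulated over sliding windows of
    ``window`` steps and the minimum accumulated value must stay below
    ``threshold`` (in frequency-bin units).  Single-frame candidates pass by
    convention.
    """
    sub = spec.values[:, cand.start_frame:cand.end_frame + 1]
    if sub.shape[1] < 2:
        return True
    track = np.argmax(sub, axis=0)
    d = np.abs(np.diff(track)).astype(float)
    w = min(window, len(d))
    acc = np.convolve(d, np.ones(w), mode="valid")
    return float(acc.min()) < threshold


def weighted_mean_freq_khz(spec: SpectrogramMatrix,
                           cand: SegmentCandidate) -> float:
    sub = spec.values[:, cand.start_frame:cand.end_frame + 1]
    total = sub.sum()
    if total <= 0:
        return 0.0
    return float((spec.freq_khz @ sub.sum(axis=1)) / total)


def frequency_gate(spec: SpectrogramMatrix, cand: SegmentCandidate,
                   min_mean_freq_khz: float = 25.0) -> bool:
    """Reject candidates dominated by low-frequency (environmental) energy;
    zero-energy candidates fail."""
    sub = spec.values[:, cand.start_frame:cand.end_frame + 1]
    if sub.sum() <= 0:
        return False
    return weighted_mean_freq_khz(spec, cand) >= min_mean_freq_khz


def merge_candidates(cands: list[SegmentCandidate],
                     gap_ms: float = 15.0,
                     frame_ms: float = 1000.0 * 250 / SAMPLE_RATE
                     ) -> list[SegmentCandidate]:
    """Merge consecutive candidates separated by strictly less than
    ``gap_ms``; idempotent."""
    if not cands:
        return []
    cands = sorted(cands, key=lambda c: c.onset_ms)
    merged = [cands[0]]
    for c in cands[1:]:
        prev = merged[-1]
        if c.onset_ms - prev.offset_ms < gap_ms:
            merged[-1] = SegmentCandidate(
                start_frame=prev.start_frame, end_frame=c.end_frame,
                onset_ms=prev.onset_ms, offset_ms=c.offset_ms)
        else:
            merged.append(c)
    return merged


def patch_to_image(patch: np.ndarray, cfg: SegmentationConfig,
                   frame_ms: float | None = None) -> np.ndarray:
    """Full-resolution (233 x T) patch -> left-aligned 100x100 uint8 image.

    The time axis is first expressed in 1 ms pixels (N = rounded duration),
    truncated at 100 ms, then the N x 233 patch is rescaled to M x 100 with
    M = round(N * 100 / 233), preserving aspect ratio.
    """
    if patch.size == 0 or patch.shape[0] != cfg.n_freq_rows:
        raise ValueError("patch must be non-empty with the full 233-row axis")
    if frame_ms is None:
        frame_ms = cfg.frame_ms
    n_ms = max(int(round(patch.shape[1] * frame_ms)), 1)
    # resample time axis to 1 ms pixels
    at_ms = resize(patch, (cfg.n_freq_rows, n_ms), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
    n = min(n_ms, int(cfg.max_duration_ms))
    at_ms = at_ms[:, :n]
    m = max(int(round(n * cfg.image_size / cfg.n_freq_rows)), 1)
    small = resize(at_ms, (cfg.image_size, m), order=1, mode="edge",
                   anti_aliasing=True, preserve_range=True)
    img = np.zeros((cfg.image_size, cfg.image_size), dtype=np.uint8)
    peak = small.max()
    if peak > 0:
        img[:, :m] = np.clip(small / peak * 255.0, 0, 255).astype(np.uint8)
    return img


def to_fixed_image(spec: SpectrogramMatrix, cand: SegmentCandidate,
                   cfg: SegmentationConfig) -> VocImage:
    """Export one candidate as the fixed-size classifier input image."""
    if cand.n_frames < 1:
        raise ValueError("empty candidate")
    dur_ms = cand.n_frames * cfg.frame_ms
    truncated = dur_ms > cfg.max_duration_ms
    n_frames = min(cand.n_frames,
                   int(round(cfg.max_duration_ms / cfg.frame_ms)))
    patch = spec.values[:, cand.start_frame:cand.start_frame + n_frames]
    img = patch_to_image(patch, cfg)
    n_ms = min(max(int(round(n_frames * cfg.frame_ms)), 1),
               int(cfg.max_duration_ms))
    n_cols = max(int(round(n_ms * cfg.image_size / cfg.n_freq_rows)), 1)
    return VocImage(pixels=img, n_cols=n_cols, truncated=truncated,
                    onset_ms=cand.onset_ms, offset_ms=cand.offset_ms)


# ---------------------------------------------------------------------------
# full pipeline


def detect_candidates(spec: SpectrogramMatrix, cfg: SegmentationConfig
                      ) -> list[SegmentCandidate]:
    """Energy -> run formation -> continuity & frequency gates -> merge ->
    duration pruning.  The continuity and frequency gates are independent
    predicates, so their order does not affect the accepted set."""
    mask = energy_gate(spec, cfg.energy_quantile)
    cands = candidates_from_mask(mask, cfg)
    kept = []
    for c in cands:
        c.passed_continuity = continuity_gate(
            spec, c, cfg.continuity_window, cfg.continuity_threshold)
        c.passed_frequency = frequency_gate(spec, c, cfg.min_mean_freq_khz)
        if c.passed_continuity and c.passed_frequency:
            kept.append(c)
    merged = merge_candidates(kept, cfg.merge_gap_ms, cfg.frame_ms)
    return [c for c in merged
            if c.offset_ms - c.onset_ms >= cfg.min_duration_ms]


def segment_recording(waveform: np.ndarray,
                      cfg: SegmentationConfig | None = None):
    """Run the full extraction pipeline on one recording.

    Returns (list of VocImage, segment table, sparsified spectrogram).
    """
    cfg = cfg or SegmentationConfig()
    filt = highpass(waveform, cfg)
    spec = stft_magnitude(filt, cfg)
    sp = sparsify(spec, cfg.sparsify_percentile)
    cands = detect_candidates(sp, cfg)
    images = [to_fixed_image(sp, c, cfg) for c in cands]
    table = pd.DataFrame(
        [{"onset_ms": c.onset_ms, "offset_ms": c.offset_ms,
          "duration_ms": c.offset_ms - c.onset_ms,
          "truncated": im.truncated}
         for c, im in zip(cands, images)])
    return images, table, sp


def extract_call_patches(spec: SpectrogramMatrix,
                         cands: list[SegmentCandidate]) -> list[np.ndarray]:
    """Full-resolution spectrogram patches for feature extraction."""
    return [np.array(spec.values[:, c.start_frame:c.end_frame + 1])
            for c in cands]


def match_intervals(detected, annotated, min_overlap: float = 0.5):
    """Greedy one-to-one matching of (onset, offset) interval lists.

    A pair matches when their intersection covers at least ``min_overlap``
    of the shorter interval.  Returns (n_match, precision, recall, f1).
    """
    detected = list(detected)
    annotated = list(annotated)
    used = np.zeros(len(detected), dtype=bool)
    n_match = 0
    for a_on, a_off in annotated:
        best, best_ov = -1, 0.0
        for j, (d_on, d_off) in enumerate(detected):
            if used[j]:
                continue
            inter = min(a_off, d_off) - max(a_on, d_on)
            shorter = min(a_off - a_on, d_off - d_on)
            if shorter <= 0:
                continue
            ov = inter / shorter
            if ov > best_ov:
                best, best_ov = j, ov
        if best >= 0 and best_ov >= min_overlap:
            used[best] = True
            n_match += 1
    precision = n_match / len(detected) if detected else 0.0
    recall = n_match / len(annotated) if annotated else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return n_match, precision, recall, f1
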