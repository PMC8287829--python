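"""Morphology and complexity features of bipolar electrograms.

Seven descriptors characterize each trace: active-segment duration (ms) and
peak-to-peak amplitude (mV), sample entropy, Shannon entropy of the
amplitude histogram (bits), normalized spectral entropy, Lempel-Ziv (LZ76)
complexity of the median-binarized signal, and the Higuchi fractal
dimension of the whole trace.  Per-segment features are averaged across a
trace's activity segments; the fractal dimension is computed once on the
full-length signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy import signal as sps

from .errors import NoActivityError, ParameterError
from .processing import ActivitySegment, BipolarTrace, peak_to_peak

#: Canonical feature order, also the tie-break order of greedy selection.
FEATURE_NAMES = (
    "duration",
    "p2p",
    "sample_entropy",
    "shannon_entropy",
    "spectral_entropy",
    "lz_complexity",
    "fractal_dimension",
)

#: Segments shorter than this are padded to a centered 100 ms window before
#: computing the complexity features, stabilizing short-segment estimates.
MIN_COMPLEXITY_SAMPLES = 64
COMPLEXITY_WINDOW_MS = 100.0


@dataclass(frozen=True)
class FeatureVector:
    """The seven per-trace features."""

    duration: float  # ms
    p2p: float  # mV
    sample_entropy: float
    shannon_entropy: float  # bits
    spectral_entropy: float  # in [0, 1]
    lz_complexity: float
    fractal_dimension: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)])

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def sample_entropy(x, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) with A (B) the number of length-m+1 (m)
    template pairs within tolerance r = r_factor * SD under the Chebyshev
    distance, self-matches excluded.

    Returns NaN when either count is zero (undefined).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ParameterError(f"need more than m+1={m + 1} samples")
    r = r_factor * float(np.std(x))

    def _count(mm: int) -> int:
        # both template lengths use the same n-m-1 ... n-m index range
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        # pairwise Chebyshev distances; count i<j pairs within r
        nv = emb.shape[0]
        total = 0
        for i in range(nv - 1):
            d = np.max(np.abs(emb[i + 1 :] - emb[i]), axis=1)
            total += int(np.count_nonzero(d <= r))
        return total

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def shannon_entropy(x, n_bins: int = 64) -> float:
    """Shannon entropy (bits) of the equal-width amplitude histogram over
    the sequence's own range; a constant input has zero entropy."""
    x = np.asarray(x, dtype=float)
    if len(x) < n_bins:
        raise ParameterError(f"need at least n_bins={n_bins} samples")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / len(x)
    return float(-np.sum(p * np.log2(p)))


def spectral_entropy(x, fs: float = 2000.0) -> float:
    """Normalized spectral entropy in [0, 1] of the Welch power spectrum
    (256-sample Hann segments, 50 % overlap; shorter inputs use one segment).

    Returns NaN for zero-power input.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise ParameterError("need at least 64 samples")
    nperseg = min(256, len(x))
    _, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2)
    total = psd.sum()
    if total <= 0:
        return float("nan")
    p = psd / total
    p = p[p > 0]
    if len(p) < 2:
        return 0.0
    return float(-np.sum(p * np.log(p)) / np.log(len(psd)))


def lz76_phrases(bits) -> int:
    """LZ76 exhaustive-history phrase count of a binary sequence.

    The count increments at every innovation, i.e. whenever the scan cannot
    be reproduced by copying from the prior history; a trailing fully
    copyable run adds no phrase, so a constant sequence has complexity 1.
    """
    s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    if n == 0:
        raise ParameterError("empty sequence")
    c = 1
    i = 1  # history length already parsed
    while i < n:
        # longest prefix of s[i:] that occurs in s[0:i+len-1] (allowing overlap)
        length = 0
        while i + length < n and s.find(s[i : i + length + 1], 0, i + length) != -1:
            length += 1
        if i + length >= n:
            break  # copyable tail, no innovation
        c += 1
        i += length + 1
    return c


def lz_complexity(x) -> float:
    """Normalized LZ76 complexity c * log2(n) / n of the median-binarized
    signal; near 1 for an incompressible random sequence."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 16:
        raise ParameterError("need at least 16 samples")
    bits = x >= np.median(x)  # >= keeps two-level inputs (e.g. +-1) binary
    c = lz76_phrases(bits)
    return float(c * np.log2(n) / n)


def fractal_dimension(x, k_max: int = 16) -> float:
    """Higuchi fractal dimension: slope of log mean curve length against
    log(1/k) over k = 1..k_max.  NaN for constant input."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 100:
        raise ParameterError("need at least 100 samples")
    if np.ptp(x) == 0:
        return float("nan")
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    ks = np.arange(1, k_max + 1)
    slope = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)[0]
    return float(slope)


def _complexity_window(x: np.ndarray, seg: ActivitySegment, fs: float) -> np.ndarray:
    """Segment samples, padded to a centered 100 ms window when too short."""
    if seg.n_samples >= MIN_COMPLEXITY_SAMPLES:
        return x[seg.start : seg.end]
    half = int(COMPLEXITY_WINDOW_MS / 1000.0 * fs) // 2
    mid = (seg.start + seg.end) // 2
    lo = max(mid - half, 0)
    hi = min(mid + half, len(x))
    return x[lo:hi]


def extract_features(trace, segments: list, fs: float | None = None) -> FeatureVector:
    """Seven-feature vector of one bipolar trace.

    Duration, p2p, and the four complexity measures are computed per
    activity segment and averaged; the fractal dimension is computed over
    the whole trace.  Raises :class:`NoActivityError` when no segments are
    given (the trace is unusable and should be excluded upstream).
    """
    if isinstance(trace, BipolarTrace):
        x = trace.samples
        fs = trace.fs if fs is None else fs
    else:
        x = np.asarray(trace, dtype=float)
        fs = 2000.0 if fs is None else fs
    if not segments:
        raise NoActivityError("no activity segments; trace excluded")

    durations, p2ps, sampens, shens, spens, lzs = [], [], [], [], [], []
    for seg in segments:
        durations.append(seg.duration_ms)
        p2ps.append(peak_to_peak(x, seg))
        w = _complexity_window(x, seg, fs)
        sampens.append(sample_entropy(w))
        shens.append(shannon_entropy(w, n_bins=min(64, len(w))))
        spens.append(spectral_entropy(w, fs=fs))
        lzs.append(lz_complexity(w))

    def _mean(vals):
        vals = np.asarray(vals, dtype=float)
        good = vals[np.isfinite(vals)]
        return float(good.mean()) if len(good) else float("nan")

    return FeatureVector(
        duration=_mean(durations),
        p2p=_mean(p2ps),
        sample_entropy=_mean(sampens),
        shannon_entropy=_mean(shens),
        spectral_entropy=_mean(spens),
        lz_complexity=_mean(lzs),
        fractal_dimension=fractal_dimension(x),
    )
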