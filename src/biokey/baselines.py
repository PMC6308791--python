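"""Comparison algorithms: RBP, waveform features, wavelets, sparse baseline, PCA.

Four single- and two-dimensional identification schemes used as reference
points for the sparse-matrix methods:

* Reduced binary pattern (RBP) — successive-difference binarization grouped
  into overlapping m-bit words, matched by a rank/frequency-weighted
  dissimilarity in [0, 1].
* Waveform — P/Q/R/S/T fiducial detection and a 19-component feature vector
  (10 amplitude differences, 5 durations, 3 slopes, QRS triangle area).
* Wavelet — R-R cycles resampled to 284 points, 85+43 edge points kept as a
  128-point segment, four segments per group run through a discrete wavelet
  transform whose approximation blocks form the feature vector.
* Sparse baseline / PCA — squared-Euclidean distance between reduced sparse
  matrices, and an eigenvector projection of concatenated ECG+SpO2 sessions.

Every method exposes the same ``fit(train) / score(probe, template_id)``
contract with distance polarity (smaller = more similar), so the evaluation
harness can sweep a single threshold convention across all of them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import butter, find_peaks, sosfiltfilt

from . import mdi, qsmi
from .signal_model import BiosignalRecord, MultiLeadRecord

logger = logging.getLogger(__name__)

# structural constants of the wavelet pipeline: each R-R cycle is resampled
# to 284 points and its 85 leading + 43 trailing points form one segment
CYCLE_POINTS = 284
CYCLE_PARTS = (85, 156, 43)
SEGMENT_POINTS = CYCLE_PARTS[0] + CYCLE_PARTS[2]  # 128
SEGMENTS_PER_GROUP = 4


# ---------------------------------------------------------------------------
# (a) Reduced binary pattern
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RbpProfile:
    """Word frequencies and descending-frequency ranks of one ECG segment.

    ``freqs[d]`` is the relative frequency of word value d among the n-m
    overlapping m-bit words; ``ranks[d]`` the 1-based rank by descending
    frequency (ties broken by ascending word value).
    """

    m: int
    freqs: dict[int, float]
    ranks: dict[int, int]

    def __post_init__(self) -> None:
        if abs(sum(self.freqs.values()) - 1.0) > 1e-9:
            raise ValueError("word frequencies must sum to 1")
        if sorted(self.ranks.values()) != list(range(1, len(self.freqs) + 1)):
            raise ValueError("ranks must be a permutation of 1..#observed words")


def rbp_binarize(x: np.ndarray) -> np.ndarray:
    """Two-state rule: y_i = 1 iff x_{i+1} >= x_i; output length n - 1."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to binarize")
    return (x[1:] >= x[:-1]).astype(np.int64)


def rbp_profile(x: np.ndarray, m: int = 4) -> RbpProfile:
    """Frequencies and ranks of the overlapping m-bit words of a series."""
    x = np.asarray(x, dtype=float)
    if len(x) < m + 1:
        raise ValueError(f"need at least m + 1 = {m + 1} samples")
    y = rbp_binarize(x)
    # word d_k = decimal expansion of bits (y_k ... y_{k+m-1}), MSB first
    powers = 2 ** np.arange(m - 1, -1, -1)
    words = np.lib.stride_tricks.sliding_window_view(y, m) @ powers
    uniq, counts = np.unique(words, return_counts=True)
    freqs = {int(d): c / len(words) for d, c in zip(uniq, counts)}
    # rank by descending frequency, ties by ascending word value
    ordering = sorted(freqs, key=lambda d: (-freqs[d], d))
    ranks = {d: i + 1 for i, d in enumerate(ordering)}
    return RbpProfile(m=m, freqs=freqs, ranks=ranks)


def rbp_distance(S1: RbpProfile, S2: RbpProfile) -> float:
    """Rank/frequency-weighted dissimilarity D_m in [0, 1].

    D_m = (1 / (2^m - 1)) * sum |R1(d) - R2(d)| p1(d) p2(d) / sum p1(d) p2(d)
    over words present in both profiles; disjoint supports score maximal
    dissimilarity 1.
    """
    if S1.m != S2.m:
        raise ValueError(f"word length mismatch: {S1.m} vs {S2.m}")
    common = set(S1.freqs) & set(S2.freqs)
    den = sum(S1.freqs[d] * S2.freqs[d] for d in common)
    if den == 0.0:
        logger.warning("disjoint word supports: defining distance as 1")
        return 1.0
    num = sum(
        abs(S1.ranks[d] - S2.ranks[d]) * S1.freqs[d] * S2.freqs[d] for d in common
    )
    return num / den / (2**S1.m - 1)


# ---------------------------------------------------------------------------
# (b) Waveform fiducials and features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Beat:
    """Fiducial sample indices and amplitudes of one cardiac cycle."""

    indices: dict[str, int]  # P, Q, R, S, T -> sample index
    amplitudes: dict[str, float]


def _bandpass(ecg: np.ndarray, rate: float) -> np.ndarray:
    """0.5-40 Hz zero-phase Butterworth band-pass (pre-processing for the
    waveform baseline only)."""
    nyq = rate / 2.0
    high = min(40.0, 0.99 * nyq)
    sos = butter(2, [0.5 / nyq, high / nyq], btype="band", output="sos")
    return sosfiltfilt(sos, ecg)


def detect_fiducials(ecg: np.ndarray, rate: float) -> list[Beat]:
    """Locate P, Q, R, S, T per beat by windowed extrema around R peaks.

    R peaks are local maxima above an adaptive threshold (60% of the filtered
    signal maximum), at least 0.4 s apart; Q/S are the nearest minima left and
    right of R within a rate-scaled window, P/T the largest maxima in the
    pre-Q and post-S windows.  Beats whose fiducials cannot be strictly
    ordered P < Q < R < S < T are dropped; an empty list (with a warning)
    means no usable beat was found.
    """
    ecg = np.asarray(ecg, dtype=float)
    x = _bandpass(ecg, rate)
    height = 0.6 * x.max() if x.max() > 0 else np.inf
    r_peaks, _ = find_peaks(x, height=height, distance=max(1, int(0.4 * rate)))
    if len(r_peaks) == 0:
        warnings.warn("no R peak found; returning empty beat list")
        return []
    rr = float(np.median(np.diff(r_peaks))) if len(r_peaks) > 1 else 0.8 * rate
    beats = []
    for r in r_peaks:
        q_lo, s_hi = int(r - 0.10 * rr), int(r + 0.10 * rr)
        if q_lo < 0 or s_hi >= len(x):
            continue
        q = q_lo + int(np.argmin(x[q_lo:r])) if r > q_lo else None
        s = r + 1 + int(np.argmin(x[r + 1 : s_hi + 1])) if s_hi > r else None
        if q is None or s is None:
            continue
        p_lo = int(r - 0.30 * rr)
        t_hi = int(r + 0.45 * rr)
        if p_lo < 0 or t_hi >= len(x) or p_lo >= q or s + 1 > t_hi:
            continue
        p = p_lo + int(np.argmax(x[p_lo:q]))
        t = s + 1 + int(np.argmax(x[s + 1 : t_hi + 1]))
        idx = {"P": p, "Q": q, "R": int(r), "S": s, "T": t}
        if not (p < q < r < s < t):
            continue
        beats.append(
            Beat(indices=idx, amplitudes={k: float(x[v]) for k, v in idx.items()})
        )
    if not beats:
        warnings.warn("no beat with strictly ordered fiducials")
    return beats


#: the 19 waveform feature names, grouped by class
AMPLITUDE_PAIRS = ("PQ", "RQ", "TQ", "RT", "PS", "RP", "TS", "RS", "PT", "QS")
DURATION_PAIRS = ("QS", "PR", "QR", "ST", "QT")
SLOPE_PAIRS = ("RS", "ST", "QR")
FEATURE_NAMES = (
    tuple(f"amp_{p}" for p in AMPLITUDE_PAIRS)
    + tuple(f"dur_{p}" for p in DURATION_PAIRS)
    + tuple(f"slope_{p}" for p in SLOPE_PAIRS)
    + ("area_QRS",)
)


@dataclass(frozen=True)
class WaveformFeatures:
    """The 19-component fiducial feature vector, averaged over beats."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (19,):
            raise ValueError("waveform feature vector must have 19 components")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def _beat_features(beat: Beat, rate: float) -> np.ndarray | None:
    idx, amp = beat.indices, beat.amplitudes
    feats = [abs(amp[x] - amp[y]) for x, y in AMPLITUDE_PAIRS]
    durs = [(idx[y] - idx[x]) / rate for x, y in DURATION_PAIRS]
    if any(d <= 0 for d in durs):
        return None  # coincident fiducials: degenerate beat
    feats += durs
    for x, y in SLOPE_PAIRS:
        dt = (idx[y] - idx[x]) / rate
        feats.append((amp[y] - amp[x]) / dt)
    # QRS triangle area by the shoelace formula over (time, amplitude) points
    pts = [(idx[w] / rate, amp[w]) for w in "QRS"]
    (x1, y1), (x2, y2), (x3, y3) = pts
    feats.append(0.5 * abs(x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2)))
    return np.asarray(feats)


def waveform_features(beats: list[Beat], rate: float) -> WaveformFeatures:
    """Average the 19 per-beat features over all non-degenerate beats."""
    if not beats:
        raise ValueError("need at least one beat")
    rows = []
    for beat in beats:
        row = _beat_features(beat, rate)
        if row is None:
            warnings.warn("skipping degenerate beat with coincident fiducials")
            continue
        rows.append(row)
    if not rows:
        raise ValueError("all beats degenerate")
    return WaveformFeatures(np.mean(rows, axis=0))


# ---------------------------------------------------------------------------
# (c) Wavelet pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveletVector:
    """Concatenated approximation blocks of one 4-segment group (averaged
    over complete groups when several are available)."""

    vector: np.ndarray
    level: int
    wavelet: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=float))


def _rr_segments(ecg: np.ndarray, rate: float) -> list[np.ndarray]:
    beats = detect_fiducials(ecg, rate)
    r_peaks = [b.indices["R"] for b in beats]
    if len(r_peaks) < 2:
        # fall back to raw peak picking if the full fiducial chain dropped
        # boundary beats
        x = _bandpass(np.asarray(ecg, dtype=float), rate)
        r_peaks, _ = find_peaks(
            x, height=0.6 * x.max(), distance=max(1, int(0.4 * rate))
        )
        r_peaks = list(r_peaks)
    segments = []
    for a, b in zip(r_peaks[:-1], r_peaks[1:]):
        cycle = np.asarray(ecg[a:b], dtype=float)
        if len(cycle) < 2:
            continue
        # interpolate the R-R cycle onto a fixed 284-point grid
        grid = np.linspace(0, len(cycle) - 1, CYCLE_POINTS)
        resampled = np.interp(grid, np.arange(len(cycle)), cycle)
        segments.append(
            np.concatenate([resampled[: CYCLE_PARTS[0]], resampled[-CYCLE_PARTS[2] :]])
        )
    return segments


def wavelet_vector(
    ecg: np.ndarray, rate: float, level: int = 3, wavelet: str = "db4"
) -> WaveletVector:
    """Wavelet feature vector: 4 approximation blocks per segment group.

    Each R-R cycle is resampled to 284 points; its first 85 and last 43
    points form a 128-point segment.  Segments are grouped in fours; each
    segment's level-``level`` approximation coefficients are concatenated
    into one group vector, and group vectors are averaged.
    """
    segments = _rr_segments(ecg, rate)
    n_groups = len(segments) // SEGMENTS_PER_GROUP
    if n_groups < 1:
        raise ValueError(
            f"need at least {SEGMENTS_PER_GROUP} full R-R cycles "
            f"(got {len(segments)})"
        )
    group_vectors = []
    for g in range(n_groups):
        blocks = []
        for seg in segments[g * SEGMENTS_PER_GROUP : (g + 1) * SEGMENTS_PER_GROUP]:
            coeffs = pywt.wavedec(seg, wavelet, level=level)
            blocks.append(coeffs[0])  # approximation block
        group_vectors.append(np.concatenate(blocks))
    return WaveletVector(
        vector=np.mean(group_vectors, axis=0), level=level, wavelet=wavelet
    )


# ---------------------------------------------------------------------------
# Two-dimensional baselines
# ---------------------------------------------------------------------------


def baseline_sparse_distance(
    SM1: qsmi.SparseCOO, SM2: qsmi.SparseCOO, squared: bool = True
) -> float:
    """Sum of squared element differences over the dense grid.

    The square-root (true Euclidean) variant is available with
    ``squared=False``.
    """
    if SM1.shape != SM2.shape:
        raise ValueError(f"shape mismatch: {SM1.shape} vs {SM2.shape}")
    d1 = qsmi.coo_decode(SM1).entries.astype(float)
    d2 = qsmi.coo_decode(SM2).entries.astype(float)
    b = float(((d1 - d2) ** 2).sum())
    return b if squared else float(np.sqrt(b))


def pca_features(X: np.ndarray, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Project samples onto the top-k eigenvectors of the covariance matrix.

    ``X`` is samples x variables.  Variables are centered; the covariance
    C = (1/n) X~ X~^T (variables x variables, n samples) is eigendecomposed
    and the top-k eigenvectors by descending eigenvalue form the rows of the
    projection P; the return is (Y, P) with Y = samples x k.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be samples x variables")
    n_samples, n_vars = X.shape
    if not 1 <= k <= min(n_samples, n_vars):
        raise ValueError(f"k={k} exceeds available components")
    Xt = X.T - X.T.mean(axis=1, keepdims=True)  # variables x samples, centered
    C = Xt @ Xt.T / n_samples
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1][:k]
    P = eigvecs[:, order].T  # k x variables
    # deterministic sign: largest-magnitude loading positive
    for row in P:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    Y = (P @ Xt).T  # samples x k
    return Y, P


# ---------------------------------------------------------------------------
# Common fit / score harness
# ---------------------------------------------------------------------------


class IdentificationMethod:
    """Common contract: ``fit(train_records)`` then ``score(probe, id)``.

    Scores are distances (smaller = more similar) for every method so the
    evaluation harness sweeps one threshold convention.
    """

    polarity = "distance"

    def fit(self, train_records: list) -> "IdentificationMethod":
        raise NotImplementedError

    def score(self, probe, template_id: str) -> float:
        raise NotImplementedError

    @property
    def individual_ids(self) -> list[str]:
        raise NotImplementedError


class QsmiMethod(IdentificationMethod):
    """QSMI scored as distance 1 - correlation."""

    def __init__(self, n: int = 32, spec: qsmi.QuantizationSpec | None = None):
        self.n = n
        self.spec = spec or qsmi.QuantizationSpec()
        self.template_set: qsmi.TemplateSet | None = None

    def fit(self, train_records: list[BiosignalRecord]) -> "QsmiMethod":
        self.template_set = qsmi.enroll(train_records, n=self.n, spec=self.spec)
        return self

    def score(self, probe: BiosignalRecord, template_id: str) -> float:
        tmpl = self.template_set.by_id(template_id)
        return 1.0 - qsmi.score_probe(probe, tmpl, self.template_set)

    @property
    def individual_ids(self) -> list[str]:
        return [t.individual_id for t in self.template_set.templates]


class MdiMethod(IdentificationMethod):
    """Multi-dimensional DTW distance over sparse element sequences."""

    def __init__(
        self, spec: mdi.ReductionSpec | None = None, include_value: bool = True
    ):
        self.spec = spec or mdi.ReductionSpec()
        self.include_value = include_value
        self.template_set: mdi.MdiTemplateSet | None = None

    def fit(self, train_records: list[MultiLeadRecord]) -> "MdiMethod":
        self.template_set = mdi.enroll_mdi(
            train_records, spec=self.spec, include_value=self.include_value
        )
        return self

    def score(self, probe: MultiLeadRecord, template_id: str) -> float:
        seq = mdi.encode_session(probe, self.spec)
        for ind, tmpl in self.template_set.templates:
            if ind == template_id:
                return mdi.dtw_distance(seq, tmpl, self.include_value)
        raise KeyError(template_id)

    @property
    def individual_ids(self) -> list[str]:
        return [ind for ind, _ in self.template_set.templates]


class _PerIndividualVectors(IdentificationMethod):
    """Shared plumbing: one feature vector per individual, Euclidean score."""

    def __init__(self) -> None:
        self._vectors: dict[str, np.ndarray] = {}

    def _extract(self, record: BiosignalRecord) -> np.ndarray:
        raise NotImplementedError

    def fit(self, train_records: list[BiosignalRecord]):
        self._vectors = {}
        for rec in train_records:
            if rec.individual_id not in self._vectors:
                self._vectors[rec.individual_id] = self._extract(rec)
        return self

    def score(self, probe: BiosignalRecord, template_id: str) -> float:
        v = self._extract(probe)
        return float(np.linalg.norm(v - self._vectors[template_id]))

    @property
    def individual_ids(self) -> list[str]:
        return list(self._vectors)


class RbpMethod(IdentificationMethod):
    """Reduced-binary-pattern rank statistic on the ECG channel."""

    def __init__(self, m: int = 4):
        self.m = m
        self._profiles: dict[str, RbpProfile] = {}

    def fit(self, train_records: list[BiosignalRecord]) -> "RbpMethod":
        self._profiles = {}
        for rec in train_records:
            if rec.individual_id not in self._profiles:
                self._profiles[rec.individual_id] = rbp_profile(rec.ecg, self.m)
        return self

    def score(self, probe: BiosignalRecord, template_id: str) -> float:
        return rbp_distance(
            rbp_profile(probe.ecg, self.m), self._profiles[template_id]
        )

    @property
    def individual_ids(self) -> list[str]:
        return list(self._profiles)


class WaveformMethod(_PerIndividualVectors):
    """Euclidean distance between 19-component fiducial feature vectors."""

    def _extract(self, record: BiosignalRecord) -> np.ndarray:
        beats = detect_fiducials(record.ecg, record.sampling_rate)
        return waveform_features(beats, record.sampling_rate).values


class WaveletMethod(_PerIndividualVectors):
    """Euclidean distance between wavelet approximation vectors."""

    def __init__(self, level: int = 3, wavelet: str = "db4"):
        super().__init__()
        self.level = level
        self.wavelet = wavelet

    def _extract(self, record: BiosignalRecord) -> np.ndarray:
        return wavelet_vector(
            record.ecg, record.sampling_rate, self.level, self.wavelet
        ).vector


class Baseline2DMethod(IdentificationMethod):
    """Squared-Euclidean distance between reduced sparse matrices."""

    def __init__(
        self,
        n: int = 32,
        spec: qsmi.QuantizationSpec | None = None,
        squared: bool = True,
    ):
        self.n = n
        self.spec = spec or qsmi.QuantizationSpec()
        self.squared = squared
        self.template_set: qsmi.TemplateSet | None = None

    def fit(self, train_records: list[BiosignalRecord]) -> "Baseline2DMethod":
        self.template_set = qsmi.enroll(train_records, n=self.n, spec=self.spec)
        return self

    def score(self, probe: BiosignalRecord, template_id: str) -> float:
        tmpl = self.template_set.by_id(template_id)
        M = qsmi.map_to_matrix(
            probe, self.n, ecg_range=tmpl.ecg_range, spo2_range=tmpl.spo2_range
        )
        sm = qsmi.coo_encode(qsmi.quantize_reduce(M, self.spec))
        return baseline_sparse_distance(sm, tmpl.sm, squared=self.squared)

    @property
    def individual_ids(self) -> list[str]:
        return [t.individual_id for t in self.template_set.templates]


class PcaMethod(IdentificationMethod):
    """Euclidean distance in a k-component eigenprojection of the
    concatenated ECG-then-SpO2 session vector."""

    def __init__(self, k: int = 5):
        self.k = k
        self._mean: np.ndarray | None = None
        self._P: np.ndarray | None = None
        self._features: dict[str, np.ndarray] = {}
        self._length: int | None = None

    def _session_vector(self, rec: BiosignalRecord) -> np.ndarray:
        v = np.concatenate([rec.ecg, rec.spo2])
        if self._length is not None:
            if len(v) < self._length:
                raise ValueError("probe session shorter than training sessions")
            v = v[: self._length]
        return v

    def fit(self, train_records: list[BiosignalRecord]) -> "PcaMethod":
        self._length = min(len(r.ecg) + len(r.spo2) for r in train_records)
        first = {}
        for rec in train_records:
            first.setdefault(rec.individual_id, rec)
        X = np.vstack([self._session_vector(r) for r in train_records])
        self._mean = X.mean(axis=0)
        _, self._P = pca_features(X, k=self.k)
        self._features = {
            ind: self._P @ (self._session_vector(rec) - self._mean)
            for ind, rec in first.items()
        }
        return self

    def score(self, probe: BiosignalRecord, template_id: str) -> float:
        y = self._P @ (self._session_vector(probe) - self._mean)
        return float(np.linalg.norm(y - self._features[template_id]))

    @property
    def individual_ids(self) -> list[str]:
        return list(self._features)


METHODS = {
    "qsmi": QsmiMethod,
    "mdi": MdiMethod,
    "rbp": RbpMethod,
    "waveform": WaveformMethod,
    "wavelet": WaveletMethod,
    "baseline2d": Baseline2DMethod,
    "pca": PcaMethod,
}
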