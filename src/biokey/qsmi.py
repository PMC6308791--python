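"""Quantization Sparse Matrix Identification (QSMI).

The basic model maps one session's paired ECG/SpO2 samples into an n x n
co-occurrence counting matrix (each sample pair increments one cell), reduces
it with a non-overlapping m x m quantization mask to a small number of levels,
stores the result in coordinate (COO) sparse form, and scores two sessions by
the Pearson correlation coefficient of their reduced matrices.

Continuous amplitudes become integer matrix indices by affine min-max scaling
to [1, n] with round-half-up and clamping.  By default each record is scaled
over its own range; for cross-session comparability the enrollment pipeline
stores the training session's ranges per individual and maps probes with the
template's ranges.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_model import BiosignalRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """n x n nonnegative integer co-occurrence matrix of (ECG, SpO2) bins."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int64)
        object.__setattr__(self, "entries", entries)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValueError("counting matrix must be square")
        if (entries < 0).any():
            raise ValueError("counting matrix entries must be nonnegative")

    @property
    def size(self) -> int:
        return self.entries.shape[0]

    def total(self) -> int:
        """Number of mapped sample pairs (each pair increments one cell)."""
        return int(self.entries.sum())


@dataclass(frozen=True)
class QuantizationSpec:
    """Mask size and level thresholds for quantize-reduce.

    A tile's entry sum s (plus the sum of the additive bias mask) maps to a
    level: 0 if s <= a, 1 if s <= c, 2 if s <= d, 3 otherwise for four
    levels; with three levels d is unused and level 2 is everything above c.
    The interval boundary b of the published rule is tied to a so the levels
    partition the whole line.
    """

    m: int = 2
    a: float = 0.0
    c: float = 2.0
    d: float | None = None
    n_levels: int = 3
    bias: np.ndarray | None = None  # m x m additive mask, default all-zero

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("mask size m must be >= 1")
        if self.n_levels not in (3, 4):
            raise ValueError("n_levels must be 3 or 4")
        if self.n_levels == 4:
            if self.d is None:
                raise ValueError("4-level quantization needs threshold d")
            if not self.a <= self.c <= self.d:
                raise ValueError("thresholds must satisfy a <= c <= d")
        elif not self.a <= self.c:
            raise ValueError("thresholds must satisfy a <= c")
        if self.bias is not None:
            bias = np.asarray(self.bias, dtype=float)
            if bias.shape != (self.m, self.m):
                raise ValueError(f"bias mask must be {self.m}x{self.m}")
            if (bias < 0).any():
                raise ValueError("bias mask entries must be nonnegative")
            object.__setattr__(self, "bias", bias)

    @property
    def bias_sum(self) -> float:
        return 0.0 if self.bias is None else float(self.bias.sum())


@dataclass(frozen=True)
class ReducedMatrix:
    """q x q matrix of quantization levels in {0, ..., n_levels - 1}."""

    entries: np.ndarray
    n_levels: int = 3

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int64)
        object.__setattr__(self, "entries", entries)
        if entries.ndim != 2:
            raise ValueError("reduced matrix must be 2-D")
        if (entries < 0).any() or (entries >= self.n_levels).any():
            raise ValueError(f"entries must lie in [0, {self.n_levels - 1}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReducedMatrix):
            return NotImplemented
        return self.n_levels == other.n_levels and np.array_equal(
            self.entries, other.entries
        )


@dataclass(frozen=True)
class SparseCOO:
    """COO listing of a reduced matrix: 1-based (row, col, value) triples.

    Triples are kept in column-major order (column ascending, then row) to
    match the conventional printed listing; values are strictly positive and
    coordinates unique.
    """

    triples: tuple[tuple[int, int, int], ...]
    shape: tuple[int, int]
    n_levels: int = 3

    def __post_init__(self) -> None:
        rows, cols = self.shape
        seen = set()
        for r, c, v in self.triples:
            if v <= 0:
                raise ValueError(f"triple ({r},{c},{v}) has non-positive value")
            if not (1 <= r <= rows and 1 <= c <= cols):
                raise ValueError(f"coordinate ({r},{c}) outside shape {self.shape}")
            if (r, c) in seen:
                raise ValueError(f"duplicate coordinate ({r},{c})")
            seen.add((r, c))
        ordered = tuple(sorted(self.triples, key=lambda t: (t[1], t[0])))
        object.__setattr__(self, "triples", ordered)

    def __len__(self) -> int:
        return len(self.triples)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _bin_indices(x: np.ndarray, n: int, rng: tuple[float, float] | None) -> np.ndarray:
    """Affine min-max scale to integer indices 1..n, round half up, clamp."""
    lo, hi = (float(x.min()), float(x.max())) if rng is None else map(float, rng)
    if hi <= lo:
        logger.warning("constant series (zero range): all samples map to index 1")
        return np.ones(len(x), dtype=np.int64)
    scaled = 1.0 + (x - lo) / (hi - lo) * (n - 1)
    idx = np.floor(scaled + 0.5).astype(np.int64)  # round half up
    return np.clip(idx, 1, n)


def map_to_matrix(
    record: BiosignalRecord,
    n: int = 32,
    ecg_range: tuple[float, float] | None = None,
    spo2_range: tuple[float, float] | None = None,
) -> CountMatrix:
    """Count paired (ECG, SpO2) samples into an n x n matrix.

    Row index = binned ECG amplitude, column index = binned SpO2 value; each
    sample pair increments exactly one cell, so the matrix total equals the
    record length.  Explicit ranges override the per-record min-max default.
    """
    if n < 2:
        raise ValueError("matrix size n must be >= 2")
    ei = _bin_indices(record.ecg, n, ecg_range) - 1
    bi = _bin_indices(record.spo2, n, spo2_range) - 1
    entries = np.zeros((n, n), dtype=np.int64)
    np.add.at(entries, (ei, bi), 1)
    return CountMatrix(entries)


def quantize_reduce(M: CountMatrix, spec: QuantizationSpec) -> ReducedMatrix:
    """Tile M into non-overlapping m x m windows and map each sum to a level.

    Ragged right/bottom edges are zero-padded; the bias mask sum is added to
    every window sum before thresholding.
    """
    n, m = M.size, spec.m
    q = math.ceil(n / m)
    padded = np.zeros((q * m, q * m), dtype=np.int64)
    padded[:n, :n] = M.entries
    sums = padded.reshape(q, m, q, m).sum(axis=(1, 3)).astype(float)
    sums += spec.bias_sum
    levels = np.zeros_like(sums, dtype=np.int64)
    levels[sums > spec.a] = 1
    levels[sums > spec.c] = 2
    if spec.n_levels == 4:
        levels[sums > spec.d] = 3
    return ReducedMatrix(levels, n_levels=spec.n_levels)


def coo_encode(RM: ReducedMatrix) -> SparseCOO:
    """List all and only the non-zero entries as 1-based COO triples."""
    rows, cols = np.nonzero(RM.entries)
    triples = tuple(
        (int(r) + 1, int(c) + 1, int(RM.entries[r, c]))
        for c, r in sorted(zip(cols, rows))
    )
    return SparseCOO(triples=triples, shape=RM.shape, n_levels=RM.n_levels)


def coo_decode(SM: SparseCOO) -> ReducedMatrix:
    """Rebuild the dense reduced matrix from its triple list."""
    entries = np.zeros(SM.shape, dtype=np.int64)
    for r, c, v in SM.triples:
        entries[r - 1, c - 1] = v
    return ReducedMatrix(entries, n_levels=SM.n_levels)


def similarity(SM1: SparseCOO, SM2: SparseCOO) -> float:
    """Pearson correlation of the two reduced matrices over the dense grid.

    Returns 0 with a warning when either flattened matrix has zero variance
    (correlation is undefined there).
    """
    if SM1.shape != SM2.shape:
        raise ValueError(f"shape mismatch: {SM1.shape} vs {SM2.shape}")
    x = coo_decode(SM1).entries.ravel().astype(float)
    y = coo_decode(SM2).entries.ravel().astype(float)
    if x.std() == 0.0 or y.std() == 0.0:
        warnings.warn("zero-variance matrix: correlation undefined, returning 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Enrollment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Template:
    """An enrolled individual's stored sparse matrix and amplitude ranges."""

    individual_id: str
    sm: SparseCOO
    ecg_range: tuple[float, float]
    spo2_range: tuple[float, float]


@dataclass
class TemplateSet:
    """Enrolled templates plus the pairwise training similarities.

    ``training_scores`` holds (individual_a, individual_b, similarity)
    for every ordered pair of distinct training templates; the threshold
    sweep in :mod:`biokey.evaluation` consumes them.
    """

    templates: list[Template]
    n: int
    spec: QuantizationSpec
    training_scores: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.templates)

    def by_id(self, individual_id: str) -> Template:
        for t in self.templates:
            if t.individual_id == individual_id:
                return t
        raise KeyError(individual_id)


def _record_template(
    record: BiosignalRecord, n: int, spec: QuantizationSpec
) -> Template:
    ecg_range = (float(record.ecg.min()), float(record.ecg.max()))
    spo2_range = (float(record.spo2.min()), float(record.spo2.max()))
    M = map_to_matrix(record, n, ecg_range=ecg_range, spo2_range=spo2_range)
    sm = coo_encode(quantize_reduce(M, spec))
    return Template(record.individual_id, sm, ecg_range, spo2_range)


def enroll(
    train_records: list[BiosignalRecord],
    n: int = 32,
    spec: QuantizationSpec | None = None,
) -> TemplateSet:
    """Build one template per individual from its training record(s).

    With several training records per individual the first is the stored
    template and the rest only contribute training scores.  Pairwise
    similarities among all training templates are retained so a decision
    threshold can be swept afterwards.
    """
    if not train_records:
        raise ValueError("empty training cohort")
    spec = spec or QuantizationSpec()
    per_record = [_record_template(r, n, spec) for r in train_records]
    templates: list[Template] = []
    seen = set()
    for t in per_record:
        if t.individual_id not in seen:
            templates.append(t)
            seen.add(t.individual_id)
    scores = [
        (a.individual_id, b.individual_id, similarity(a.sm, b.sm))
        for i, a in enumerate(per_record)
        for j, b in enumerate(per_record)
        if i != j
    ]
    return TemplateSet(templates=templates, n=n, spec=spec, training_scores=scores)


def score_probe(
    probe: BiosignalRecord, template: Template, template_set: TemplateSet
) -> float:
    """Similarity of a probe session to one enrolled template.

    The probe is mapped with the template's stored amplitude ranges so both
    sessions share one binning grid.
    """
    M = map_to_matrix(
        probe,
        template_set.n,
        ecg_range=template.ecg_range,
        spo2_range=template.spo2_range,
    )
    sm = coo_encode(quantize_reduce(M, template_set.spec))
    return similarity(sm, template.sm)


# ---------------------------------------------------------------------------
# COO text format
# ---------------------------------------------------------------------------


def write_coo(path: str | Path, SM: SparseCOO) -> None:
    """Write the text COO format: `rows cols n_levels`, then triples."""
    lines = [f"{SM.shape[0]} {SM.shape[1]} {SM.n_levels}"]
    lines += [f"{r} {c} {v}" for r, c, v in SM.triples]
    Path(path).write_text("\n".join(lines) + "\n")


def read_coo(path: str | Path) -> SparseCOO:
    """Read the text COO format back; bit-exact round-trip with write_coo."""
    lines = Path(path).read_text().strip().splitlines()
    rows, cols, n_levels = (int(x) for x in lines[0].split())
    triples = tuple(
        tuple(int(x) for x in line.split()) for line in lines[1:] if line.strip()
    )
    return SparseCOO(triples=triples, shape=(rows, cols), n_levels=n_levels)
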