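"""Multi-Dimensional Identification (MDI).

J-lead ECG sessions are mapped sample-by-sample into a J-dimensional integer
space of side u: each lead value s is reduced to round(s / R + dtheta) and
clamped to [1, u].  The occupied coordinates are summarized as sparse
elements ((d_1, ..., d_J), v) — coordinate plus occupancy count — optionally
coarsened by an m-fold window reduction per axis.  Two sessions are compared
by multi-dimensional dynamic time warping over their canonical sparse-element
sequences: equal-length sequences are scored by the direct position-wise
squared Euclidean sum, unequal lengths by the classic DTW recurrence.

Sparse elements carry no inherent order, so the sequence fed to DTW is a
canonical serialization: lexicographic by coordinate (default) or by time of
first occupancy.  The occupancy count participates in the local cost as an
extra vector component by default; a coordinates-only cost is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .signal_model import MultiLeadRecord

logger = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReductionSpec:
    """Reduction level R, offset dtheta, space bound u and window m.

    ``R`` divides the raw amplitude, ``delta_theta`` shifts the result away
    from zero, ``u`` bounds the integer space (values clamp to [1, u]) and
    ``window_m`` is the per-axis coarsening factor applied to the sparse
    elements.  Defaults are the best-reported configuration: a space of 32
    reduced by a window of 2 at offset 20.
    """

    R: float = 0.1
    delta_theta: float = 20.0
    u: int = 32
    window_m: int = 2

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("reduction level R must be positive")
        if self.delta_theta < 0:
            raise ValueError("delta_theta must be nonnegative")
        if self.u < 1:
            raise ValueError("space bound u must be >= 1")
        if self.window_m < 1:
            raise ValueError("window m must be >= 1")


@dataclass(frozen=True)
class PointSequence:
    """K ordered J-dimensional integer points, coordinates in [1, u]."""

    points: np.ndarray  # shape (K, J)
    u: int

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=np.int64)
        object.__setattr__(self, "points", points)
        if points.ndim != 2:
            raise ValueError("points must be a (K, J) array")
        if points.size and ((points < 1).any() or (points > self.u).any()):
            raise ValueError(f"coordinates must lie in [1, {self.u}]")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n_dims(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class SparseElementSequence:
    """Ordered sparse elements (coordinate, occupancy) of one session.

    ``coords`` is (L, J) with unique rows, ``values`` (L,) with strictly
    positive occupancies summing to the number of mapped samples.  Ordering
    is part of the value: lexicographic by coordinate unless constructed with
    the time-of-first-occupancy order.
    """

    coords: np.ndarray  # (L, J)
    values: np.ndarray  # (L,)
    u: int
    order: str = "lex"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "values", values)
        if coords.ndim != 2 or values.ndim != 1 or len(coords) != len(values):
            raise ValueError("coords must be (L, J) and values (L,)")
        if (values < 1).any():
            raise ValueError("occupancy values must be >= 1")
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("coordinates must be unique")
        if self.order not in ("lex", "time"):
            raise ValueError("order must be 'lex' or 'time'")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def total(self) -> int:
        return int(self.values.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SparseElementSequence):
            return NotImplemented
        return (
            self.u == other.u
            and self.order == other.order
            and np.array_equal(self.coords, other.coords)
            and np.array_equal(self.values, other.values)
        )


# ---------------------------------------------------------------------------
# Mapping and accumulation
# ---------------------------------------------------------------------------


def reduce_map(record: MultiLeadRecord, spec: ReductionSpec) -> PointSequence:
    """Map every sample of every lead into the [1, u]^J integer space.

    d = round(s / R + dtheta), round half up, clamped below at 1 and above
    at u so no point leaves the space.
    """
    raw = record.leads.T / spec.R + spec.delta_theta  # (K, J)
    d = np.floor(raw + 0.5).astype(np.int64)
    d = np.clip(d, 1, spec.u)
    return PointSequence(points=d, u=spec.u)


def _lex_order(coords: np.ndarray) -> np.ndarray:
    # np.lexsort keys run last-to-first; row-lexicographic needs reversed cols
    return np.lexsort(coords.T[::-1])


def accumulate_sparse(
    points: PointSequence, order: str = "lex"
) -> SparseElementSequence:
    """Count occupancy per distinct coordinate; total occupancy = K.

    ``order='lex'`` sorts elements lexicographically by coordinate;
    ``order='time'`` keeps them by time of first occupancy.
    """
    if order == "time":
        coords, first_idx, counts = np.unique(
            points.points, axis=0, return_index=True, return_counts=True
        )
        perm = np.argsort(first_idx)
        return SparseElementSequence(
            coords[perm], counts[perm], u=points.u, order="time"
        )
    coords, counts = np.unique(points.points, axis=0, return_counts=True)
    # np.unique already sorts rows lexicographically
    return SparseElementSequence(coords, counts, u=points.u, order="lex")


def window_reduce(
    seq: SparseElementSequence, m: int, u: int | None = None
) -> SparseElementSequence:
    """Coarsen each axis by factor m: tile index = ceil(coordinate / m).

    Occupancies of merged coordinates are summed; total occupancy is
    conserved.  The reduced space bound is ceil(u / m).
    """
    if m < 1:
        raise ValueError("window m must be >= 1")
    if m == 1:
        return seq
    u = seq.u if u is None else u
    new_u = -(-u // m)
    tiles = -(-seq.coords // m)  # ceil division, stays >= 1
    uniq, inverse = np.unique(tiles, axis=0, return_inverse=True)
    values = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(values, inverse, seq.values)
    if seq.order == "time":
        first = np.full(len(uniq), len(seq), dtype=np.int64)
        np.minimum.at(first, inverse, np.arange(len(seq)))
        perm = np.argsort(first)
        return SparseElementSequence(uniq[perm], values[perm], u=new_u, order="time")
    return SparseElementSequence(uniq, values, u=new_u, order="lex")


# ---------------------------------------------------------------------------
# Multi-dimensional DTW
# ---------------------------------------------------------------------------


@njit(nogil=True)
def _dtw_dp(cost: np.ndarray) -> float:  # pragma: no cover - jitted
    n, m = cost.shape
    big = np.inf
    D = np.empty((n + 1, m + 1))
    D[:, 0] = big
    D[0, :] = big
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost[i - 1, j - 1] + best
    return D[n, m]


def _element_vectors(seq: SparseElementSequence, include_value: bool) -> np.ndarray:
    if include_value:
        return np.hstack([seq.coords, seq.values[:, None]]).astype(float)
    return seq.coords.astype(float)


def dtw_distance(
    X1: SparseElementSequence,
    X2: SparseElementSequence,
    include_value: bool = True,
) -> float:
    """Cumulative squared-Euclidean DTW distance between two sessions.

    Local cost between elements is the squared Euclidean distance over the J
    coordinates, with the occupancy count appended as a (J+1)-th component
    unless ``include_value=False``.  Equal-length sequences are scored by the
    direct position-wise sum with no warping; unequal lengths use the DTW
    recurrence D(i,j) = cost(i,j) + min(D(i-1,j), D(i,j-1), D(i-1,j-1)).
    The result is symmetric, nonnegative and zero on identical inputs.
    """
    if len(X1) == 0 or len(X2) == 0:
        raise ValueError("cannot compare empty sparse element sequences")
    if X1.n_dims != X2.n_dims:
        raise ValueError(f"dimension mismatch: {X1.n_dims} vs {X2.n_dims}")
    if X1.u != X2.u:
        raise ValueError(f"space bound mismatch: {X1.u} vs {X2.u}")
    a = _element_vectors(X1, include_value)
    b = _element_vectors(X2, include_value)
    if len(a) == len(b):
        return float(((a - b) ** 2).sum())
    cost = cdist(a, b, metric="sqeuclidean")
    return float(_dtw_dp(cost))


# ---------------------------------------------------------------------------
# Enrollment and identification
# ---------------------------------------------------------------------------


@dataclass
class MdiTemplateSet:
    """Enrolled per-individual sparse-element sequences and their spec."""

    templates: list[tuple[str, SparseElementSequence]]
    spec: ReductionSpec
    include_value: bool = True
    training_scores: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.templates)


def encode_session(
    record: MultiLeadRecord, spec: ReductionSpec, order: str = "lex"
) -> SparseElementSequence:
    """Full reduce -> map -> accumulate -> window-reduce chain for a session."""
    points = reduce_map(record, spec)
    seq = accumulate_sparse(points, order=order)
    return window_reduce(seq, spec.window_m)


def enroll_mdi(
    train_records: list[MultiLeadRecord],
    spec: ReductionSpec | None = None,
    include_value: bool = True,
    order: str = "lex",
) -> MdiTemplateSet:
    """Encode one template per individual; keep pairwise training distances."""
    if not train_records:
        raise ValueError("empty training cohort")
    spec = spec or ReductionSpec()
    encoded = [(r.individual_id, encode_session(r, spec, order)) for r in train_records]
    templates: list[tuple[str, SparseElementSequence]] = []
    seen = set()
    for ind, seq in encoded:
        if ind not in seen:
            templates.append((ind, seq))
            seen.add(ind)
    scores = [
        (a, b, dtw_distance(sa, sb, include_value))
        for i, (a, sa) in enumerate(encoded)
        for j, (b, sb) in enumerate(encoded)
        if i != j
    ]
    return MdiTemplateSet(
        templates=templates,
        spec=spec,
        include_value=include_value,
        training_scores=scores,
    )


def mdi_identify(
    probe: MultiLeadRecord,
    template_set: MdiTemplateSet,
    threshold: float,
    order: str = "lex",
) -> tuple[str, float, bool]:
    """Identify a probe against all enrolled templates.

    Returns (best individual, distance, accept) where accept means the
    minimum distance does not exceed the threshold.  Distance ties are
    broken by enrollment order (logged).
    """
    if not template_set.templates:
        raise ValueError("template set is empty")
    if probe.n_leads != template_set.templates[0][1].n_dims:
        raise ValueError(
            f"probe has {probe.n_leads} leads but templates were enrolled "
            f"with {template_set.templates[0][1].n_dims}"
        )
    seq = encode_session(probe, template_set.spec, order)
    best_id, best_d = None, np.inf
    for ind, tmpl in template_set.templates:
        d = dtw_distance(seq, tmpl, template_set.include_value)
        if d < best_d:
            best_id, best_d = ind, d
        elif d == best_d:
            logger.info("distance tie at %.6g; keeping first-enrolled %s", d, best_id)
    return best_id, float(best_d), bool(best_d <= threshold)


# ---------------------------------------------------------------------------
# Sparse element text format
# ---------------------------------------------------------------------------


def write_elements(path: str | Path, seq: SparseElementSequence) -> None:
    """Write `J u` header then one `c1 ... cJ v` line per element."""
    lines = [f"{seq.n_dims} {seq.u}"]
    for coord, v in zip(seq.coords, seq.values):
        lines.append(" ".join(str(int(c)) for c in coord) + f" {int(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_elements(path: str | Path) -> SparseElementSequence:
    """Read the text format back; exact round-trip with write_elements."""
    lines = Path(path).read_text().strip().splitlines()
    n_dims, u = (int(x) for x in lines[0].split())
    coords, values = [], []
    for line in lines[1:]:
        parts = [int(x) for x in line.split()]
        if len(parts) != n_dims + 1:
            raise ValueError(f"malformed element line: {line!r}")
        coords.append(parts[:-1])
        values.append(parts[-1])
    return SparseElementSequence(
        np.asarray(coords, dtype=np.int64).reshape(len(values), n_dims),
        np.asarray(values, dtype=np.int64),
        u=u,
        order="lex",
    )
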