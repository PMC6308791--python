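"""FA/FR rates, accuracy, threshold sweeping and method comparison.

A verification trial scores one probe session against one enrolled template;
the trial is *genuine* when probe and template belong to the same individual
and an *impostor* trial otherwise.  For a decision threshold delta:

* FA (false acceptance) = accepted impostor trials / impostor trials,
* FR (false rejection)  = rejected genuine trials / genuine trials,
* Acc = 1 - (FA + FR) / 2.

All methods in this package report distances (smaller = more similar), so a
trial is accepted when score <= delta; a similarity polarity (accept when
score >= delta) is also supported.  The operating threshold is chosen by
sweeping a grid of candidate deltas and keeping the one minimizing
(FA + FR) / 2, ties broken toward the smallest delta.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import qsmi
from .baselines import IdentificationMethod, QsmiMethod
from .signal_model import BiosignalRecord

logger = logging.getLogger(__name__)

#: the default sweep grid: delta from 0.001 to 0.030 in steps of 0.001
DEFAULT_GRID = tuple(np.round(np.arange(1, 31) * 0.001, 3))


@dataclass(frozen=True)
class Trial:
    probe_individual: str
    template_individual: str
    score: float

    @property
    def genuine(self) -> bool:
        return self.probe_individual == self.template_individual


@dataclass(frozen=True)
class ScoreSet:
    """All verification trials of one experiment."""

    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def genuine_scores(self) -> np.ndarray:
        return np.array([t.score for t in self.trials if t.genuine])

    @property
    def impostor_scores(self) -> np.ndarray:
        return np.array([t.score for t in self.trials if not t.genuine])


@dataclass(frozen=True)
class EvalResult:
    """Rates at one operating threshold delta.

    ``acc`` is exactly 1 - (FA + FR)/2; ``per_individual_fa`` maps each
    template individual to its own false-acceptance rate.
    """

    fa: float
    fr: float
    delta: float
    per_individual_fa: dict[str, float] = field(default_factory=dict)

    @property
    def half_sum(self) -> float:
        return (self.fa + self.fr) / 2.0

    @property
    def acc(self) -> float:
        return 1.0 - self.half_sum

    def summary(self) -> str:
        return (
            f"delta={self.delta:.4g}  FA={self.fa:.4f}  FR={self.fr:.4f}  "
            f"(FA+FR)/2={self.half_sum:.4f}  Acc={100 * self.acc:.2f}%"
        )


def _accepted(scores: np.ndarray, delta: float, polarity: str) -> np.ndarray:
    if polarity == "distance":
        return scores <= delta
    if polarity == "similarity":
        return scores >= delta
    raise ValueError(f"unknown polarity {polarity!r}")


def compute_rates(
    scores: ScoreSet, delta: float, polarity: str = "distance"
) -> tuple[float, float]:
    """FA and FR at threshold delta."""
    genuine = scores.genuine_scores
    impostor = scores.impostor_scores
    if len(genuine) == 0 or len(impostor) == 0:
        raise ValueError("need at least one genuine and one impostor trial")
    fa = float(np.mean(_accepted(impostor, delta, polarity)))
    fr = float(np.mean(~_accepted(genuine, delta, polarity)))
    return fa, fr


def accuracy(fa: float, fr: float) -> float:
    """Acc = 1 - (FA + FR) / 2."""
    if not (0.0 <= fa <= 1.0 and 0.0 <= fr <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    return 1.0 - (fa + fr) / 2.0


def per_individual_fa(
    scores: ScoreSet, delta: float, polarity: str = "distance"
) -> dict[str, float]:
    """FA per template individual over its impostor trials.

    Individuals without impostor trials are excluded with a warning.  The
    global FA is the trial-weighted mean of these per-individual rates.
    """
    by_template: dict[str, list[float]] = {}
    for t in scores.trials:
        if not t.genuine:
            by_template.setdefault(t.template_individual, []).append(t.score)
    out = {}
    for t in scores.trials:
        ind = t.template_individual
        if ind in out:
            continue
        if ind not in by_template:
            logger.warning("individual %s has no impostor trials; excluded", ind)
            continue
        arr = np.array(by_template[ind])
        out[ind] = float(np.mean(_accepted(arr, delta, polarity)))
    return out


def sweep_threshold(
    scores: ScoreSet,
    grid: tuple[float, ...] = DEFAULT_GRID,
    polarity: str = "distance",
) -> tuple[float, EvalResult]:
    """Pick the grid delta minimizing (FA + FR)/2, smallest delta on ties."""
    if len(grid) == 0:
        raise ValueError("threshold grid must be non-empty")
    best_delta, best_half = None, np.inf
    for delta in sorted(grid):
        fa, fr = compute_rates(scores, delta, polarity)
        half = (fa + fr) / 2.0
        if half < best_half:
            best_delta, best_half = float(delta), half
    fa, fr = compute_rates(scores, best_delta, polarity)
    result = EvalResult(
        fa=fa,
        fr=fr,
        delta=best_delta,
        per_individual_fa=per_individual_fa(scores, best_delta, polarity),
    )
    return best_delta, result


def adaptive_grid(scores: ScoreSet) -> tuple[float, ...]:
    """Candidate thresholds from the data: midpoints of adjacent distinct
    scores plus flanking values, so every achievable (FA, FR) trade-off on
    this score set is represented."""
    vals = np.unique([t.score for t in scores.trials])
    if len(vals) == 1:
        return (float(vals[0]),)
    mids = (vals[:-1] + vals[1:]) / 2.0
    lo = vals[0] - (vals[1] - vals[0]) / 2.0
    hi = vals[-1] + (vals[-1] - vals[-2]) / 2.0
    return tuple(float(v) for v in np.concatenate([[lo], mids, [hi]]))


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------


def split_cohort(records: list) -> tuple[list, list]:
    """First session per individual for enrollment, the rest for probing."""
    train, test, seen = [], [], set()
    for rec in records:
        if rec.individual_id not in seen:
            train.append(rec)
            seen.add(rec.individual_id)
        else:
            test.append(rec)
    return train, test


def score_all(method: IdentificationMethod, probes: list) -> ScoreSet:
    """All-vs-all trials: every probe session against every template."""
    trials = [
        Trial(p.individual_id, ind, method.score(p, ind))
        for p in probes
        for ind in method.individual_ids
    ]
    return ScoreSet(tuple(trials))


def evaluate_method(
    method: IdentificationMethod,
    train_records: list,
    test_records: list,
    grid: tuple[float, ...] | None = None,
) -> EvalResult:
    """Fit, score all-vs-all, sweep the threshold, report rates.

    With ``grid=None`` the sweep uses the data-driven grid from
    :func:`adaptive_grid`, which covers the achievable trade-offs of the
    observed score range.
    """
    method.fit(train_records)
    scores = score_all(method, test_records)
    grid = adaptive_grid(scores) if grid is None else grid
    _, result = sweep_threshold(scores, grid, method.polarity)
    return result


def compare_quantization(
    cohort: list[BiosignalRecord],
    level_specs: list[qsmi.QuantizationSpec],
    n: int = 32,
    grid: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Run the full QSMI pipeline once per quantization spec on one split.

    Returns a table with one row per spec: mask size, thresholds, number of
    levels, the swept delta and the resulting FA / FR / (FA+FR)/2 / Acc.
    """
    if not level_specs:
        raise ValueError("need at least one quantization spec")
    train, test = split_cohort(cohort)
    rows = []
    for spec in level_specs:
        result = evaluate_method(QsmiMethod(n=n, spec=spec), train, test, grid=grid)
        rows.append(
            {
                "m": spec.m,
                "a": spec.a,
                "c": spec.c,
                "d": spec.d,
                "n_levels": spec.n_levels,
                "delta": result.delta,
                "FA": result.fa,
                "FR": result.fr,
                "half_sum": result.half_sum,
                "Acc": result.acc,
            }
        )
    return pd.DataFrame(rows)


def write_result(path: str | Path, result: EvalResult, **metadata) -> None:
    """Dump an EvalResult (plus run metadata such as the seed) as JSON."""
    payload = {
        "FA": result.fa,
        "FR": result.fr,
        "half_sum": result.half_sum,
        "Acc": result.acc,
        "delta": result.delta,
        "per_individual_FA": result.per_individual_fa,
        **metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
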