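"""Domain types, file I/O and a seeded synthetic biosignal cohort generator.

The identification algorithms in this package assume sessions of paired
ECG/SpO2 samples (single lead) or J-lead ECG sessions whose within-individual
morphology is stable across sessions and distinct across individuals.  The
generator here emulates exactly that structure:

* ECG: a quasi-periodic sum of five Gaussian bumps (P, Q, R, S, T) per
  cardiac cycle, with per-individual amplitudes, widths and timing offsets
  drawn once from a continuous prior, plus white session noise.
* SpO2: a per-individual mean plus a slow bounded random walk, clipped to a
  physiological band.
* Multi-lead sessions: a shared base morphology scaled per lead, with
  independent per-lead noise.

All randomness is funnelled through integer seeds; per-individual and
per-session sub-seeds are derived by fixed arithmetic from the master seed so
that cohorts are reproducible and stable when the cohort size changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: physiological clip band for the SpO2 walk, percent saturation
SPO2_BAND = (85.0, 100.0)


class ValidationError(ValueError):
    """A record violates a structural invariant (lengths, pairing, ranges)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiosignalRecord:
    """One session's paired ECG and SpO2 series for one individual.

    ``ecg`` and ``spo2`` are paired per time index, so they must have equal
    length; SpO2 is in percent saturation, ECG in arbitrary amplitude units.
    """

    individual_id: str
    session_id: str
    ecg: np.ndarray
    spo2: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        ecg = np.asarray(self.ecg, dtype=float)
        spo2 = np.asarray(self.spo2, dtype=float)
        object.__setattr__(self, "ecg", ecg)
        object.__setattr__(self, "spo2", spo2)
        if ecg.ndim != 1 or spo2.ndim != 1:
            raise ValidationError("ecg and spo2 must be 1-D series")
        if len(ecg) != len(spo2) or len(ecg) < 1:
            raise ValidationError(
                f"ecg and spo2 must be paired series of equal length >= 1, "
                f"got {len(ecg)} and {len(spo2)}"
            )
        if not (np.isfinite(ecg).all() and np.isfinite(spo2).all()):
            raise ValidationError("series contain missing/non-finite values")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")

    def __len__(self) -> int:
        return len(self.ecg)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BiosignalRecord):
            return NotImplemented
        return (
            self.individual_id == other.individual_id
            and self.session_id == other.session_id
            and self.sampling_rate == other.sampling_rate
            and np.array_equal(self.ecg, other.ecg)
            and np.array_equal(self.spo2, other.spo2)
        )


@dataclass(frozen=True)
class MultiLeadRecord:
    """One J-lead ECG session (J >= 2 leads of common length K)."""

    individual_id: str
    session_id: str
    leads: np.ndarray  # shape (J, K)
    sampling_rate: float

    def __post_init__(self) -> None:
        leads = np.atleast_2d(np.asarray(self.leads, dtype=float))
        object.__setattr__(self, "leads", leads)
        if leads.shape[0] < 2:
            raise ValidationError("a multi-lead record needs J >= 2 leads")
        if leads.shape[1] < 1:
            raise ValidationError("leads must have length K >= 1")
        if not np.isfinite(leads).all():
            raise ValidationError("leads contain missing/non-finite values")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_leads(self) -> int:
        return self.leads.shape[0]

    def __len__(self) -> int:
        return self.leads.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiLeadRecord):
            return NotImplemented
        return (
            self.individual_id == other.individual_id
            and self.session_id == other.session_id
            and self.sampling_rate == other.sampling_rate
            and np.array_equal(self.leads, other.leads)
        )


@dataclass(frozen=True)
class IndividualParams:
    """Stable per-individual generative parameters.

    ``morphology`` maps each wave name (P, Q, R, S, T) to a triple
    ``(amplitude, width, center)`` where width and center are expressed as
    fractions of the cardiac cycle.  ``lead_scales`` gives per-lead gain
    factors used by the multi-lead generator.
    """

    morphology: dict[str, tuple[float, float, float]]
    heart_rate_hz: float
    spo2_mean: float
    spo2_sd: float
    lead_scales: tuple[float, ...] = field(default_factory=lambda: (1.0,) * 12)

    def __post_init__(self) -> None:
        missing = set(WAVE_NAMES) - set(self.morphology)
        if missing:
            raise ValidationError(f"morphology missing waves: {sorted(missing)}")
        if not self.heart_rate_hz > 0:
            raise ValidationError("heart_rate_hz must be positive")
        if not (SPO2_BAND[0] <= self.spo2_mean <= SPO2_BAND[1]):
            raise ValidationError(f"spo2_mean must lie in {SPO2_BAND}")
        if self.spo2_sd < 0:
            raise ValidationError("spo2_sd must be nonnegative")
        if any(s <= 0 for s in self.lead_scales):
            raise ValidationError("lead_scales must be positive")


# nominal morphology: (amplitude [mV], width, center), widths/centers as
# fractions of the cardiac cycle; R fixed near 0.35 so P..T fit in one cycle
_NOMINAL_MORPHOLOGY = {
    "P": (0.15, 0.030, 0.18),
    "Q": (-0.15, 0.012, 0.31),
    "R": (1.00, 0.016, 0.35),
    "S": (-0.25, 0.013, 0.39),
    "T": (0.35, 0.055, 0.62),
}


def draw_individual(rng: np.random.Generator, n_leads: int = 12) -> IndividualParams:
    """Draw one individual's parameters from the continuous cohort prior.

    Amplitudes and widths get multiplicative jitter, wave centers small
    additive jitter, so two draws almost surely differ in every morphology
    parameter.
    """
    morphology: dict[str, tuple[float, float, float]] = {}
    for name, (amp, width, center) in _NOMINAL_MORPHOLOGY.items():
        a = amp * rng.uniform(0.7, 1.3)
        w = width * rng.uniform(0.8, 1.25)
        c = center + rng.uniform(-0.02, 0.02)
        morphology[name] = (a, w, c)
    return IndividualParams(
        morphology=morphology,
        heart_rate_hz=rng.uniform(0.9, 1.5),
        spo2_mean=rng.uniform(94.0, 99.0),
        spo2_sd=0.3,
        lead_scales=tuple(rng.uniform(0.5, 1.5, size=n_leads)),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _ecg_waveform(params: IndividualParams, n_samples: int, rate: float) -> np.ndarray:
    """Noise-free quasi-periodic P-QRS-T waveform of ``n_samples`` points."""
    t = np.arange(n_samples) / rate
    phase = (t * params.heart_rate_hz) % 1.0
    ecg = np.zeros(n_samples)
    for amp, width, center in params.morphology.values():
        # circular distance on the unit cycle so bumps wrap cleanly
        d = np.abs(phase - center)
        d = np.minimum(d, 1.0 - d)
        ecg += amp * np.exp(-0.5 * (d / width) ** 2)
    return ecg


def _n_samples(duration_s: float, rate: float) -> int:
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration_s and rate must be positive")
    n = int(np.floor(duration_s * rate))
    if n < 1:
        raise ValueError("duration_s * rate must be >= 1 sample")
    return n


def simulate_individual(
    params: IndividualParams,
    duration_s: float = 30.0,
    rate: float = 100.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    individual_id: str = "I0",
    session_id: str = "S0",
) -> BiosignalRecord:
    """Simulate one paired ECG/SpO2 session for one individual.

    The ECG is the individual's five-bump waveform plus white noise of
    standard deviation ``noise_sd``; the SpO2 series is ``spo2_mean`` plus a
    slow random walk clipped to the physiological band.  Identical arguments
    (including ``seed``) give identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    n = _n_samples(duration_s, rate)
    rng = np.random.default_rng(seed)
    ecg = _ecg_waveform(params, n, rate)
    if noise_sd > 0:
        ecg = ecg + rng.normal(0.0, noise_sd, size=n)
    # slow bounded walk around the individual's mean: mean-reverting AR(1)
    # with stationary sd spo2_sd and ~10 s reversion time, discretized at
    # the sampling rate so the walk statistics are rate-independent
    if params.spo2_sd > 0:
        theta = 0.1  # 1/s reversion rate
        phi = max(0.0, 1.0 - theta / rate)
        step_sd = params.spo2_sd * np.sqrt(1.0 - phi**2)
        steps = rng.normal(0.0, step_sd, size=n)
        walk = np.empty(n)
        walk[0] = rng.normal(0.0, params.spo2_sd)
        for k in range(1, n):
            walk[k] = phi * walk[k - 1] + steps[k]
    else:
        walk = np.zeros(n)
    spo2 = np.clip(params.spo2_mean + walk, *SPO2_BAND)
    return BiosignalRecord(
        individual_id=individual_id,
        session_id=session_id,
        ecg=ecg,
        spo2=spo2,
        sampling_rate=rate,
    )


def simulate_multilead(
    params: IndividualParams,
    n_leads: int = 5,
    duration_s: float = 30.0,
    rate: float = 100.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    individual_id: str = "I0",
    session_id: str = "S0",
) -> MultiLeadRecord:
    """Simulate one J-lead session: lead j = lead_scales[j] x base + noise."""
    if not 2 <= n_leads <= 12:
        raise ValueError("n_leads must be between 2 and 12")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if len(params.lead_scales) < n_leads:
        raise ValueError(
            f"params provide {len(params.lead_scales)} lead scales, "
            f"need {n_leads}"
        )
    n = _n_samples(duration_s, rate)
    rng = np.random.default_rng(seed)
    base = _ecg_waveform(params, n, rate)
    scales = np.asarray(params.lead_scales[:n_leads])[:, None]
    leads = scales * base[None, :]
    if noise_sd > 0:
        leads = leads + rng.normal(0.0, noise_sd, size=leads.shape)
    return MultiLeadRecord(
        individual_id=individual_id,
        session_id=session_id,
        leads=leads,
        sampling_rate=rate,
    )


def _individual_seed(seed: int, i: int) -> int:
    # fixed arithmetic so cohorts are stable when n_individuals changes
    return (seed * 1_000_003 + 7_919 * (i + 1)) % (2**31)


def _session_seed(seed: int, i: int, s: int) -> int:
    return (_individual_seed(seed, i) + 104_729 * (s + 1)) % (2**31)


def simulate_cohort(
    n_individuals: int = 18,
    sessions_per_individual: int = 2,
    duration_s: float = 30.0,
    rate: float = 100.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[BiosignalRecord]:
    """Simulate a labelled cohort of paired ECG/SpO2 sessions.

    Each individual receives one parameter draw, reused across its sessions
    with fresh session noise.  The default cohort is 18 individuals with two
    sessions each (one enrollment, one probe).
    """
    if n_individuals < 2 or sessions_per_individual < 2:
        raise ValueError(
            "need >= 2 individuals and >= 2 sessions each (one train, one test)"
        )
    records = []
    for i in range(n_individuals):
        rng = np.random.default_rng(_individual_seed(seed, i))
        params = draw_individual(rng)
        for s in range(sessions_per_individual):
            records.append(
                simulate_individual(
                    params,
                    duration_s=duration_s,
                    rate=rate,
                    noise_sd=noise_sd,
                    seed=_session_seed(seed, i, s),
                    individual_id=f"P{i + 1:02d}",
                    session_id=f"S{s + 1}",
                )
            )
    return records


def simulate_multilead_cohort(
    n_individuals: int = 10,
    sessions_per_individual: int = 2,
    n_leads: int = 5,
    duration_s: float = 30.0,
    rate: float = 100.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[MultiLeadRecord]:
    """Simulate a labelled cohort of J-lead sessions (shared morphology)."""
    if n_individuals < 2 or sessions_per_individual < 2:
        raise ValueError(
            "need >= 2 individuals and >= 2 sessions each (one train, one test)"
        )
    records = []
    for i in range(n_individuals):
        rng = np.random.default_rng(_individual_seed(seed, i))
        params = draw_individual(rng, n_leads=max(n_leads, 12))
        for s in range(sessions_per_individual):
            records.append(
                simulate_multilead(
                    params,
                    n_leads=n_leads,
                    duration_s=duration_s,
                    rate=rate,
                    noise_sd=noise_sd,
                    seed=_session_seed(seed, i, s),
                    individual_id=f"P{i + 1:02d}",
                    session_id=f"S{s + 1}",
                )
            )
    return records


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["individual_id", "session_id", "channel", "index", "value"]
_RATE_CHANNEL = "rate"


def write_records(
    path: str | Path, records: list[BiosignalRecord | MultiLeadRecord]
) -> None:
    """Write records to a long-format CSV.

    Columns: individual_id, session_id, channel, index, value.  Channels are
    ``ecg``/``spo2`` for paired records, ``lead1..leadJ`` for multi-lead
    records, plus one ``rate`` row per session carrying the sampling rate.
    """
    frames = []
    for rec in records:
        if isinstance(rec, BiosignalRecord):
            channels = {"ecg": rec.ecg, "spo2": rec.spo2}
        else:
            channels = {f"lead{j + 1}": rec.leads[j] for j in range(rec.n_leads)}
        for name, series in channels.items():
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": rec.individual_id,
                        "session_id": rec.session_id,
                        "channel": name,
                        "index": np.arange(len(series)),
                        "value": series,
                    }
                )
            )
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": [rec.individual_id],
                    "session_id": [rec.session_id],
                    "channel": [_RATE_CHANNEL],
                    "index": [0],
                    "value": [rec.sampling_rate],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_CSV_COLUMNS)
    )
    # repr gives the shortest exact decimal, so reading back is bit-exact
    df["value"] = [repr(float(v)) for v in df["value"]]
    df.to_csv(path, index=False)


def _session_from_group(
    ind: str, ses: str, group: pd.DataFrame
) -> BiosignalRecord | MultiLeadRecord:
    channels = {}
    rate = None
    for channel, sub in group.groupby("channel", sort=False):
        if channel == _RATE_CHANNEL:
            rate = float(sub["value"].iloc[0])
            continue
        sub = sub.sort_values("index")
        channels[str(channel)] = sub["value"].to_numpy(dtype=float)
    if rate is None:
        raise ParseError(f"session {ind}/{ses}: missing '{_RATE_CHANNEL}' row")
    names = set(channels)
    if names == {"ecg", "spo2"}:
        if len(channels["ecg"]) != len(channels["spo2"]):
            raise ValidationError(
                f"session {ind}/{ses}: ecg length {len(channels['ecg'])} "
                f"!= spo2 length {len(channels['spo2'])}"
            )
        return BiosignalRecord(ind, ses, channels["ecg"], channels["spo2"], rate)
    if names and all(n.startswith("lead") for n in names):
        ordered = sorted(names, key=lambda n: int(n[4:]))
        lengths = {len(channels[n]) for n in ordered}
        if len(lengths) != 1:
            raise ValidationError(f"session {ind}/{ses}: leads differ in length")
        return MultiLeadRecord(
            ind, ses, np.vstack([channels[n] for n in ordered]), rate
        )
    raise ParseError(f"session {ind}/{ses}: unknown channel names {sorted(names)}")


def read_records(path: str | Path) -> list[BiosignalRecord | MultiLeadRecord]:
    """Read records written by :func:`write_records` (exact round-trip).

    Malformed rows raise :class:`ParseError` naming the 1-based file line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna() | df["value"].isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: non-numeric value on line {line}")
    df = df.assign(value=values)
    records: list[BiosignalRecord | MultiLeadRecord] = []
    for (ind, ses), group in df.groupby(
        ["individual_id", "session_id"], sort=False
    ):
        records.append(_session_from_group(str(ind), str(ses), group))
    return records


def read_wfdb_like(header_path: str | Path) -> MultiLeadRecord:
    """Read a plain-text WFDB-style record layout into a MultiLeadRecord.

    The header's first line is ``record_name n_leads sampling_rate
    n_samples``; the signal file ``<record_name>.txt`` next to the header
    holds a whitespace-separated K x J matrix (one sample per row, one lead
    per column).
    """
    header_path = Path(header_path)
    fields = header_path.read_text().strip().splitlines()[0].split()
    if len(fields) < 4:
        raise ParseError(f"{header_path}: header line needs 4 fields, line 1")
    name, n_leads, rate, n_samples = (
        fields[0],
        int(fields[1]),
        float(fields[2]),
        int(fields[3]),
    )
    sig_path = header_path.parent / f"{name}.txt"
    data = np.loadtxt(sig_path, ndmin=2)
    if data.shape != (n_samples, n_leads):
        raise ValidationError(
            f"{sig_path}: expected shape {(n_samples, n_leads)}, got {data.shape}"
        )
    return MultiLeadRecord(
        individual_id=name, session_id="0", leads=data.T, sampling_rate=rate
    )
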