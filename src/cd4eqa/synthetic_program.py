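"""Synthetic multi-session EQA program generator with known ground truth.

Real proficiency-testing submissions are confidential, so every stage of
the pipeline is exercised against generated programs that emulate the
observable structure of a national CD4 EQA scheme:

* three sessions a year, each shipping a two-specimen panel (low and mid
  CD4 level) to a growing roster of laboratories;
* four platform classes (FACSCount, CyFlow, PIMA, other POC/conventional)
  with platform-specific imprecision and a platform-specific set of
  reported quantities (e.g. PIMA reports only the absolute CD4 count);
* per-lab systematic bias plus multiplicative Gaussian measurement noise:
  ``value = nominal × (1 + bias) × (1 + ε)``, ``ε ~ N(0, cv²)``;
* unable-to-report events with the reasons seen in practice (no login,
  broken instrument, missing or expired reagents);
* injected failure causes distributed over the pre-analytical /
  analytical / post-analytical phases (default mix 17.5 / 77.0 / 5.5 %),
  each realised as a concrete data anomaly: whole-panel degradation
  (sample-integrity drift), a single perturbed quantity (pipetting or
  gating surrogate), or a transcription surrogate (swapped values or a
  dropped digit).

Every generated dataset passes :mod:`cd4eqa.io_model` validation and
carries a ground-truth sidecar naming each lab's bias, unable flag and
injected error, so recovery of known effects can be tested end to end.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .error_taxonomy import (
    PHASE_CATEGORIES,
    ErrorCategory,
    ErrorRecord,
    Phase,
    write_error_records,
)
from .io_model import (
    EqaError,
    Instrument,
    Level,
    Marker,
    MarkerReading,
    Quantity,
    Specimen,
    Status,
    Submission,
    UnableReason,
    ValueKind,
    write_panel_manifest,
    write_submissions,
)


class ConfigError(EqaError):
    """Invalid synthetic-program configuration."""


# ---------------------------------------------------------------------------
# Defaults: the stated world
# ---------------------------------------------------------------------------

#: Reporter counts of the 11 evaluated sessions, used as the roster growth schedule.
DEFAULT_GROWTH: tuple[int, ...] = (14, 50, 48, 59, 57, 54, 18, 31, 48, 47, 54)

#: Per-session platform counts matching the published program history
#: (FACSCount, CyFlow, PIMA, Other); conventional cytometers decline while
#: the PIMA point-of-care share grows from 2 to 37 sites.
_MIX_COUNTS: tuple[tuple[int, int, int, int], ...] = (
    (8, 3, 2, 1), (16, 13, 17, 4), (16, 11, 19, 2), (11, 14, 32, 2),
    (9, 13, 33, 2), (11, 8, 33, 2), (6, 2, 9, 1), (9, 5, 15, 2),
    (5, 9, 32, 2), (6, 7, 32, 2), (6, 8, 37, 3),
)

_INSTRUMENT_ORDER = (Instrument.FACSCOUNT, Instrument.CYFLOW, Instrument.PIMA, Instrument.OTHER)

DEFAULT_INSTRUMENT_MIX: tuple[dict[Instrument, float], ...] = tuple(
    {inst: c / sum(counts) for inst, c in zip(_INSTRUMENT_ORDER, counts)}
    for counts in _MIX_COUNTS
)

#: Panel target values (cells/µL and % of lymphocytes).  The program never
#: publishes its panel targets, so these are declared, clinically plausible
#: defaults: a low specimen around 150 CD4 cells/µL and a mid specimen
#: around 500, with CD3/CD8 companions consistent with CD3 ≈ CD4 + CD8.
DEFAULT_NOMINALS: dict[Level, dict[Marker, dict[ValueKind, float]]] = {
    Level.LOW: {
        Marker.CD3: {ValueKind.PERCENT: 72.0, ValueKind.ABSOLUTE: 900.0},
        Marker.CD4: {ValueKind.PERCENT: 12.0, ValueKind.ABSOLUTE: 150.0},
        Marker.CD8: {ValueKind.PERCENT: 56.0, ValueKind.ABSOLUTE: 700.0},
    },
    Level.MID: {
        Marker.CD3: {ValueKind.PERCENT: 75.0, ValueKind.ABSOLUTE: 1400.0},
        Marker.CD4: {ValueKind.PERCENT: 28.0, ValueKind.ABSOLUTE: 500.0},
        Marker.CD8: {ValueKind.PERCENT: 43.0, ValueKind.ABSOLUTE: 800.0},
    },
}

#: Imprecision (CV, fraction of the value) by platform class.
DEFAULT_LAB_CV: dict[Instrument, float] = {
    Instrument.FACSCOUNT: 0.04,
    Instrument.CYFLOW: 0.06,
    Instrument.PIMA: 0.08,
    Instrument.OTHER: 0.05,
}

#: Quantities each platform class reports.
DEFAULT_INSTRUMENT_QUANTITIES: dict[Instrument, tuple[tuple[Marker, ValueKind], ...]] = {
    Instrument.FACSCOUNT: (
        (Marker.CD3, ValueKind.ABSOLUTE),
        (Marker.CD4, ValueKind.ABSOLUTE),
        (Marker.CD8, ValueKind.ABSOLUTE),
    ),
    Instrument.CYFLOW: tuple(
        (m, k) for m in (Marker.CD3, Marker.CD4, Marker.CD8) for k in (ValueKind.PERCENT, ValueKind.ABSOLUTE)
    ),
    Instrument.PIMA: ((Marker.CD4, ValueKind.ABSOLUTE),),
    Instrument.OTHER: tuple(
        (m, k) for m in (Marker.CD3, Marker.CD4, Marker.CD8) for k in (ValueKind.PERCENT, ValueKind.ABSOLUTE)
    ),
}

_UNABLE_REASONS = (
    UnableReason.NO_LOGIN,
    UnableReason.BROKEN_INSTRUMENT,
    UnableReason.NO_REAGENTS,
    UnableReason.EXPIRED_REAGENTS,
)

_PHASE_ORDER = (Phase.PRE_ANALYTICAL, Phase.ANALYTICAL, Phase.POST_ANALYTICAL)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Parameters of the generated program.

    ``p_error`` may be a single probability or a per-session schedule
    (e.g. decreasing over time to emulate the effect of corrective
    actions).  ``lab_bias`` pins the systematic bias of specific labs;
    all other labs draw a persistent bias from ``N(0, bias_sd²)``.
    """

    n_sessions: int = 11
    labs_per_session: tuple[int, ...] = DEFAULT_GROWTH
    instrument_mix: tuple[Mapping[Instrument, float], ...] = DEFAULT_INSTRUMENT_MIX
    nominal_values: Mapping[Level, Mapping[Marker, Mapping[ValueKind, float]]] = field(
        default_factory=lambda: DEFAULT_NOMINALS
    )
    lab_cv: Mapping[Instrument, float] = field(default_factory=lambda: DEFAULT_LAB_CV)
    instrument_quantities: Mapping[Instrument, tuple[tuple[Marker, ValueKind], ...]] = field(
        default_factory=lambda: DEFAULT_INSTRUMENT_QUANTITIES
    )
    bias_sd: float = 0.02
    lab_bias: Mapping[str, float] = field(default_factory=dict)
    p_unable: float = 0.08
    p_error: Union[float, tuple[float, ...]] = 0.12
    phase_mix: tuple[float, float, float] = (0.175, 0.770, 0.055)
    error_magnitude: float = 0.5
    session_start: int = 48  # first session number (ids S48, S49, ...)
    start_year: int = 2014
    seed: int = 0

    def __post_init__(self) -> None:
        self.labs_per_session = tuple(self.labs_per_session)
        self.instrument_mix = tuple(dict(m) for m in self.instrument_mix)
        if isinstance(self.p_error, (list, tuple)):
            self.p_error = tuple(float(p) for p in self.p_error)
        self.validate()

    def validate(self) -> None:
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if len(self.labs_per_session) != self.n_sessions:
            raise ConfigError(
                f"labs_per_session has {len(self.labs_per_session)} entries "
                f"for {self.n_sessions} sessions"
            )
        if len(self.instrument_mix) == 1:
            self.instrument_mix = self.instrument_mix * self.n_sessions
        if len(self.instrument_mix) != self.n_sessions:
            raise ConfigError(
                f"instrument_mix has {len(self.instrument_mix)} entries "
                f"for {self.n_sessions} sessions"
            )
        for mix in self.instrument_mix:
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in mix.values()):
                raise ConfigError(f"instrument mix must be non-negative and sum to 1 (got {mix})")
        probs = [self.p_unable] + (
            list(self.p_error) if isinstance(self.p_error, tuple) else [self.p_error]
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("p_unable and p_error must lie in [0,1]")
        if isinstance(self.p_error, tuple) and len(self.p_error) != self.n_sessions:
            raise ConfigError("per-session p_error schedule length must equal n_sessions")
        if len(self.phase_mix) != 3 or abs(sum(self.phase_mix) - 1.0) > 1e-9:
            raise ConfigError("phase_mix must be three probabilities summing to 1")
        if any(p < 0 for p in self.phase_mix):
            raise ConfigError("phase_mix entries must be non-negative")
        if self.bias_sd < 0 or self.error_magnitude <= 0:
            raise ConfigError("bias_sd must be >= 0 and error_magnitude > 0")
        if any(cv < 0 for cv in self.lab_cv.values()):
            raise ConfigError("lab_cv entries must be >= 0")
        low = self.nominal_values[Level.LOW][Marker.CD4][ValueKind.ABSOLUTE]
        mid = self.nominal_values[Level.MID][Marker.CD4][ValueKind.ABSOLUTE]
        if not low < mid:
            raise ConfigError("nominal CD4 of the low specimen must be below the mid specimen")

    def p_error_for(self, session_index: int) -> float:
        if isinstance(self.p_error, tuple):
            return self.p_error[session_index]
        return self.p_error

    def session_id(self, session_index: int) -> str:
        return f"S{self.session_start + session_index}"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        """Build a config from a YAML key-value file (unknown keys rejected)."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
        kwargs: dict = {}
        for key, value in raw.items():
            if key == "instrument_mix":
                kwargs[key] = tuple(
                    {Instrument(k): float(v) for k, v in mix.items()} for mix in value
                )
            elif key == "lab_cv":
                kwargs[key] = {Instrument(k): float(v) for k, v in value.items()}
            elif key == "nominal_values":
                kwargs[key] = {
                    Level(lv): {
                        Marker(m): {ValueKind(vk): float(x) for vk, x in kinds.items()}
                        for m, kinds in markers.items()
                    }
                    for lv, markers in value.items()
                }
            elif key == "instrument_quantities":
                kwargs[key] = {
                    Instrument(k): tuple((Marker(m), ValueKind(vk)) for m, vk in quants)
                    for k, quants in value.items()
                }
            elif key in ("labs_per_session", "phase_mix"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthEntry:
    """What was injected for one lab in one session."""

    lab_id: str
    session_id: str
    instrument: Instrument
    bias: float
    unable: bool
    error_phase: Optional[Phase] = None
    error_category: Optional[ErrorCategory] = None
    affected_quantities: tuple[Quantity, ...] = ()

    def to_jsonable(self) -> dict:
        return {
            "lab_id": self.lab_id,
            "session_id": self.session_id,
            "instrument": self.instrument.value,
            "bias": self.bias,
            "unable": self.unable,
            "error_phase": self.error_phase.value if self.error_phase else None,
            "error_category": self.error_category.value if self.error_category else None,
            "affected_quantities": [
                [s, m.value, k.value] for s, m, k in self.affected_quantities
            ],
        }


@dataclass
class SessionData:
    submissions: list[Submission]
    manifest: list[Specimen]
    ground_truth: list[GroundTruthEntry]
    error_records: list[ErrorRecord]


@dataclass
class ProgramData:
    """A full generated program: all sessions plus sidecar ground truth."""

    submissions: list[Submission]
    manifest: list[Specimen]
    ground_truth: list[GroundTruthEntry]
    error_records: list[ErrorRecord]
    session_ids: list[str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_submissions(self.submissions, out / "submissions.csv")
        write_panel_manifest(self.manifest, out / "manifest.csv")
        write_error_records(self.error_records, out / "errors.csv")
        payload = {
            "session_ids": self.session_ids,
            "ground_truth": [g.to_jsonable() for g in self.ground_truth],
        }
        (out / "ground_truth.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _session_dates(config: SyntheticConfig, session_index: int) -> datetime.date:
    year = config.start_year + session_index // 3
    month = (1, 5, 9)[session_index % 3]
    return datetime.date(year, month, 15)


def _round_value(kind: ValueKind, value: float) -> float:
    # labs report whole cells/µL and one-decimal percents
    return float(round(value)) if kind is ValueKind.ABSOLUTE else round(float(value), 1)


def _clamp(kind: ValueKind, value: float) -> float:
    if kind is ValueKind.PERCENT:
        return min(100.0, max(0.0, value))
    return max(0.0, value)


def sample_lab_biases(
    config: SyntheticConfig, lab_ids: Sequence[str], rng: np.random.Generator
) -> dict[str, float]:
    """Persistent systematic bias per lab: drawn once, overridden by ``lab_bias``."""
    biases = {}
    for lab_id in lab_ids:
        drawn = float(rng.normal(0.0, config.bias_sd)) if config.bias_sd > 0 else 0.0
        biases[lab_id] = float(config.lab_bias.get(lab_id, drawn))
    return biases


def _inject_error(
    values: dict[tuple[str, Marker, ValueKind], float],
    phase: Phase,
    magnitude: float,
    rng: np.random.Generator,
) -> list[Quantity]:
    """Mutate reported values in place; return the affected quantities."""
    keys = sorted(values, key=lambda q: (q[0], q[1].value, q[2].value))
    if phase is Phase.PRE_ANALYTICAL:
        # sample-integrity drift: the whole panel reads low
        for q in keys:
            values[q] = values[q] * (1.0 - magnitude)
        return list(keys)
    if phase is Phase.ANALYTICAL:
        q = keys[int(rng.integers(len(keys)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        values[q] = values[q] * (1.0 + sign * magnitude)
        return [q]
    # post-analytical transcription surrogate: swap two absolute values on
    # one specimen, or drop the last digit of one value
    abs_keys = [q for q in keys if q[2] is ValueKind.ABSOLUTE]
    by_specimen: dict[str, list[Quantity]] = {}
    for q in abs_keys:
        by_specimen.setdefault(q[0], []).append(q)
    swappable = [qs for qs in by_specimen.values() if len(qs) >= 2]
    if swappable and rng.random() < 0.5:
        qs = swappable[int(rng.integers(len(swappable)))]
        i, j = rng.choice(len(qs), size=2, replace=False)
        qa, qb = qs[int(i)], qs[int(j)]
        values[qa], values[qb] = values[qb], values[qa]
        return [qa, qb]
    q = keys[int(rng.integers(len(keys)))]
    values[q] = float(int(values[q] // 10))
    return [q]


def generate_session(
    config: SyntheticConfig,
    session_index: int,
    rng: np.random.Generator,
    biases: Optional[Mapping[str, float]] = None,
) -> SessionData:
    """Generate one session's panel, submissions and ground truth.

    ``biases`` carries persistent per-lab biases when called from
    :func:`generate_program`; standalone calls sample them from ``rng``.
    """
    if not 0 <= session_index < config.n_sessions:
        raise ConfigError(f"session_index {session_index} out of range")
    session_id = config.session_id(session_index)
    specimens = [
        Specimen(specimen_id=f"{session_id}-LOW", session_id=session_id, level=Level.LOW),
        Specimen(specimen_id=f"{session_id}-MID", session_id=session_id, level=Level.MID),
    ]
    n_labs = config.labs_per_session[session_index]
    lab_ids = [f"LAB{i + 1:03d}" for i in range(n_labs)]
    if biases is None:
        biases = sample_lab_biases(config, lab_ids, rng)

    mix = config.instrument_mix[session_index]
    instruments = list(mix)
    mix_p = np.asarray([mix[i] for i in instruments], dtype=float)
    receipt = _session_dates(config, session_index)
    p_error = config.p_error_for(session_index)

    submissions: list[Submission] = []
    truth: list[GroundTruthEntry] = []
    error_records: list[ErrorRecord] = []

    for lab_id in lab_ids:
        instrument = instruments[int(rng.choice(len(instruments), p=mix_p))]
        bias = float(biases.get(lab_id, 0.0))
        analysis = receipt + datetime.timedelta(days=int(rng.integers(0, 8)))

        if rng.random() < config.p_unable:
            reason = _UNABLE_REASONS[int(rng.integers(len(_UNABLE_REASONS)))]
            for sp in specimens:
                submissions.append(
                    Submission(
                        lab_id=lab_id,
                        session_id=session_id,
                        specimen_id=sp.specimen_id,
                        instrument=instrument,
                        status=Status.UNABLE,
                        unable_reason=reason,
                        receipt_date=receipt,
                    )
                )
            truth.append(
                GroundTruthEntry(
                    lab_id=lab_id, session_id=session_id, instrument=instrument,
                    bias=bias, unable=True,
                )
            )
            continue

        cv = float(config.lab_cv[instrument])
        quantities = config.instrument_quantities[instrument]
        values: dict[tuple[str, Marker, ValueKind], float] = {}
        for sp in specimens:
            nominals = config.nominal_values[sp.level]
            for marker, kind in quantities:
                nominal = float(nominals[marker][kind])
                eps = float(rng.normal(0.0, cv)) if cv > 0 else 0.0
                values[(sp.specimen_id, marker, kind)] = nominal * (1.0 + bias) * (1.0 + eps)
            # biological consistency of the clean value: CD3 >= CD4
            for kind in (ValueKind.PERCENT, ValueKind.ABSOLUTE):
                k3, k4 = (sp.specimen_id, Marker.CD3, kind), (sp.specimen_id, Marker.CD4, kind)
                if k3 in values and k4 in values and values[k3] < values[k4]:
                    values[k3] = values[k4]

        phase: Optional[Phase] = None
        category: Optional[ErrorCategory] = None
        affected: list[Quantity] = []
        if rng.random() < p_error:
            phase = _PHASE_ORDER[int(rng.choice(3, p=np.asarray(config.phase_mix)))]
            cats = PHASE_CATEGORIES[phase]
            category = cats[int(rng.integers(len(cats)))]
            affected = _inject_error(values, phase, config.error_magnitude, rng)
            error_records.append(
                ErrorRecord(
                    lab_id=lab_id, session_id=session_id, category=category,
                    note="synthetic injected error",
                )
            )

        for sp in specimens:
            by_marker: dict[Marker, dict[str, float]] = {}
            for (spec_id, marker, kind), value in values.items():
                if spec_id != sp.specimen_id:
                    continue
                value = _round_value(kind, _clamp(kind, value))
                slot = "percent" if kind is ValueKind.PERCENT else "absolute"
                by_marker.setdefault(marker, {})[slot] = value
            readings = tuple(
                MarkerReading(marker=m, **vals)
                for m, vals in sorted(by_marker.items(), key=lambda kv: kv[0].value)
            )
            submissions.append(
                Submission(
                    lab_id=lab_id,
                    session_id=session_id,
                    specimen_id=sp.specimen_id,
                    instrument=instrument,
                    status=Status.REPORTED,
                    readings=readings,
                    receipt_date=receipt,
                    analysis_date=analysis,
                )
            )
        truth.append(
            GroundTruthEntry(
                lab_id=lab_id, session_id=session_id, instrument=instrument,
                bias=bias, unable=False, error_phase=phase, error_category=category,
                affected_quantities=tuple(affected),
            )
        )

    return SessionData(
        submissions=submissions, manifest=specimens,
        ground_truth=truth, error_records=error_records,
    )


def generate_program(config: SyntheticConfig) -> ProgramData:
    """Generate all sessions with persistent lab biases, reproducibly from the seed."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_sessions + 1)
    bias_rng = np.random.default_rng(children[0])
    roster = [f"LAB{i + 1:03d}" for i in range(max(config.labs_per_session))]
    biases = sample_lab_biases(config, roster, bias_rng)

    submissions: list[Submission] = []
    manifest: list[Specimen] = []
    truth: list[GroundTruthEntry] = []
    errors: list[ErrorRecord] = []
    session_ids: list[str] = []
    for idx in range(config.n_sessions):
        rng = np.random.default_rng(children[idx + 1])
        data = generate_session(config, idx, rng, biases=biases)
        submissions.extend(data.submissions)
        manifest.extend(data.manifest)
        truth.extend(data.ground_truth)
        errors.extend(data.error_records)
        session_ids.append(config.session_id(idx))
    return ProgramData(
        submissions=submissions, manifest=manifest, ground_truth=truth,
        error_records=errors, session_ids=session_ids,
    )
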