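"""Consensus statistics, Standard Deviation Index scoring, and adjudication.

The scoring rule used by interlaboratory CD4 proficiency testing is:

1. For every scored quantity — a (specimen, marker, value-kind) group —
   compute the group mean and sample standard deviation over all reported
   values.
2. Values deviating from that mean by *more than* ``outlier_k`` standard
   deviations (default 2) are outliers and are excluded.
3. The mean and SD are recalculated on the retained values; these trimmed
   consensus statistics define the target.
4. Each lab's Standard Deviation Index is
   ``SDI = (reported − trimmed_mean) / trimmed_sd``; the sign says whether
   the lab read high or low.  Performance on a quantity is satisfactory
   when ``|SDI| <= pass_limit`` (default 2, boundary inclusive).

A lab passes a session only if every quantity it reported, on both panel
specimens, is within the limit; quantities the lab's instrument does not
measure are not held against it.  A registered lab with no reported
submission is adjudicated *unable to report*.  Labs trimmed from the
consensus are still scored against it and adjudicated by the same rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    EqaError,
    Instrument,
    Marker,
    Quantity,
    Specimen,
    Status,
    Submission,
    UnableReason,
    ValidationError,
    ValueKind,
    quantity_sort_key,
)


class InsufficientGroupError(EqaError):
    """Fewer than ``min_group_n`` values available for a consensus group."""


class ConsistencyError(EqaError):
    """Scores and submissions given to the adjudicator disagree."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringConfig:
    """Tunable constants of the scoring rule.

    outlier_k
        Trim threshold in SD units; a value is an outlier when its distance
        from the group mean strictly exceeds ``outlier_k * SD``.
    pass_limit
        Satisfactory-performance bound in SDI units (inclusive).
    min_group_n
        Minimum retained group size for a quantity to be scoreable.
    trim_passes
        Number of trim-and-recompute iterations (the program's rule is a
        single recalculation).
    group_by_instrument
        When true, consensus groups are stratified by platform (peer-group
        scoring) instead of pooling all instruments.
    """

    outlier_k: float = 2.0
    pass_limit: float = 2.0
    min_group_n: int = 3
    trim_passes: int = 1
    group_by_instrument: bool = False

    def __post_init__(self) -> None:
        if self.outlier_k <= 0 or self.pass_limit <= 0:
            raise ValidationError("outlier_k and pass_limit must be strictly positive")
        if self.min_group_n < 2:
            raise ValidationError("min_group_n must be >= 2")
        if self.trim_passes < 1:
            raise ValidationError("trim_passes must be >= 1")


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregateStat:
    """Trimmed consensus mean/SD for one (session, specimen, marker, kind) group."""

    session_id: str
    specimen_id: str
    marker: Marker
    value_kind: ValueKind
    n_initial: int
    n_outliers: int
    trimmed_mean: float
    trimmed_sd: float
    outlier_lab_ids: frozenset[str] = frozenset()
    instrument: Optional[Instrument] = None  # set under peer-group scoring

    @property
    def n_retained(self) -> int:
        return self.n_initial - self.n_outliers


@dataclass(frozen=True)
class SdiScore:
    """One lab's standardized deviation from the trimmed consensus."""

    lab_id: str
    session_id: str
    specimen_id: str
    marker: Marker
    value_kind: ValueKind
    reported_value: float
    residual: float
    sdi: float
    within_limit: bool

    @property
    def quantity(self) -> Quantity:
        return (self.specimen_id, self.marker, self.value_kind)


class Outcome(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    UNABLE = "unable_to_report"


@dataclass(frozen=True)
class LabVerdict:
    """Per-lab, per-session adjudication."""

    lab_id: str
    session_id: str
    instrument: Instrument
    outcome: Outcome
    failing_quantities: frozenset[Quantity] = frozenset()
    scores: tuple[SdiScore, ...] = ()
    unable_reason: Optional[UnableReason] = None
    notes: str = ""


@dataclass
class SessionResult:
    """Everything the scorer produces for one session."""

    session_id: str
    aggregates: list[AggregateStat]
    verdicts: list[LabVerdict]
    unscoreable: list[Quantity] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def compute_trimmed_aggregate(
    values: Sequence[tuple[str, float]],
    config: ScoringConfig = ScoringConfig(),
    *,
    session_id: str = "",
    specimen_id: str = "",
    marker: Marker = Marker.CD4,
    value_kind: ValueKind = ValueKind.ABSOLUTE,
    instrument: Optional[Instrument] = None,
) -> AggregateStat:
    """Trimmed consensus mean and sample SD for one group of lab values.

    ``values`` is a sequence of (lab_id, value).  The full-group mean and
    sample SD (n−1 denominator) are computed; values whose distance from
    the mean strictly exceeds ``outlier_k * SD`` are excluded; mean and SD
    are recomputed on the remainder (``trim_passes`` times).  Raises
    :class:`InsufficientGroupError` when fewer than ``min_group_n`` values
    are supplied or would remain after trimming.
    """
    n_initial = len(values)
    if n_initial < config.min_group_n:
        raise InsufficientGroupError(
            f"group has {n_initial} values; at least {config.min_group_n} required"
        )
    # fixed summation order makes results independent of submission order
    values = sorted(values)
    labs = [lab for lab, _ in values]
    arr = np.asarray([v for _, v in values], dtype=float)
    retained = np.ones(n_initial, dtype=bool)
    for _ in range(config.trim_passes):
        subset = arr[retained]
        mean = float(subset.mean())
        sd = float(subset.std(ddof=1))
        if sd == 0.0:
            break
        new_out = retained & (np.abs(arr - mean) > config.outlier_k * sd)
        if not new_out.any():
            break
        retained &= ~new_out
        if int(retained.sum()) < config.min_group_n:
            raise InsufficientGroupError(
                f"trimming left {int(retained.sum())} values; "
                f"at least {config.min_group_n} required"
            )
    subset = arr[retained]
    outlier_labs = frozenset(lab for lab, keep in zip(labs, retained) if not keep)
    return AggregateStat(
        session_id=session_id,
        specimen_id=specimen_id,
        marker=marker,
        value_kind=value_kind,
        n_initial=n_initial,
        n_outliers=n_initial - int(retained.sum()),
        trimmed_mean=float(subset.mean()),
        trimmed_sd=float(subset.std(ddof=1)),
        outlier_lab_ids=outlier_labs,
        instrument=instrument,
    )


def compute_sdi(
    reported_value: float,
    agg: AggregateStat,
    config: ScoringConfig = ScoringConfig(),
    *,
    lab_id: str = "",
) -> SdiScore:
    """Standard Deviation Index of one reported value against a consensus.

    A zero consensus SD means a unanimous group: a matching value scores
    SDI 0, while any deviation is out of limit and recorded as signed
    infinity.
    """
    residual = reported_value - agg.trimmed_mean
    if agg.trimmed_sd == 0.0:
        if residual == 0.0:
            sdi, within = 0.0, True
        else:
            sdi, within = math.copysign(math.inf, residual), False
    else:
        sdi = residual / agg.trimmed_sd
        within = abs(sdi) <= config.pass_limit
    return SdiScore(
        lab_id=lab_id,
        session_id=agg.session_id,
        specimen_id=agg.specimen_id,
        marker=agg.marker,
        value_kind=agg.value_kind,
        reported_value=reported_value,
        residual=residual,
        sdi=sdi,
        within_limit=within,
    )


def adjudicate_lab(
    submissions: Sequence[Submission],
    scores: Sequence[SdiScore],
    *,
    scoreable: Optional[set[Quantity]] = None,
) -> LabVerdict:
    """Adjudicate one lab's session from its submissions and SDI scores.

    ``scoreable`` (when given) restricts the consistency check to
    quantities that had a scoreable consensus; reported quantities outside
    it are noted as unscored rather than held against the lab.
    """
    if not submissions:
        raise ConsistencyError("adjudicate_lab needs at least one submission")
    lab_ids = {s.lab_id for s in submissions}
    session_ids = {s.session_id for s in submissions}
    if len(lab_ids) != 1 or len(session_ids) != 1:
        raise ConsistencyError("submissions span multiple labs or sessions")
    lab_id, session_id = lab_ids.pop(), session_ids.pop()
    instrument = sorted({s.instrument for s in submissions}, key=lambda i: i.value)[0]

    reported = [s for s in submissions if s.status is Status.REPORTED]
    if not reported:
        reasons = [s.unable_reason for s in submissions if s.unable_reason]
        return LabVerdict(
            lab_id=lab_id,
            session_id=session_id,
            instrument=instrument,
            outcome=Outcome.UNABLE,
            unable_reason=reasons[0] if reasons else None,
        )

    reported_quantities: set[Quantity] = set()
    for sub in reported:
        for marker, kind, _ in sub.quantities():
            reported_quantities.add((sub.specimen_id, marker, kind))
    extraneous = [sc.quantity for sc in scores if sc.quantity not in reported_quantities]
    if extraneous:
        raise ConsistencyError(
            f"scores reference quantities the lab never reported: {sorted(extraneous, key=quantity_sort_key)}"
        )

    failing = frozenset(sc.quantity for sc in scores if not sc.within_limit)
    notes = ""
    if not scores:
        # every reported quantity fell in an unscoreable consensus group
        notes = "unscored"
    elif scoreable is not None:
        unscored = sorted(
            (reported_quantities & scoreable) ^ reported_quantities, key=quantity_sort_key
        )
        if unscored:
            notes = "unscored quantities: " + "; ".join(
                f"{s}:{m.value}:{k.value}" for s, m, k in unscored
            )
    ordered = tuple(sorted(scores, key=lambda sc: quantity_sort_key(sc.quantity)))
    return LabVerdict(
        lab_id=lab_id,
        session_id=session_id,
        instrument=instrument,
        outcome=Outcome.FAIL if failing else Outcome.PASS,
        failing_quantities=failing,
        scores=ordered,
        notes=notes,
    )


def score_session(
    submissions: Sequence[Submission],
    manifest: Sequence[Specimen],
    config: ScoringConfig = ScoringConfig(),
) -> SessionResult:
    """Score one full session: consensus, SDI for every reporting lab, verdicts.

    Labs trimmed as outliers are excluded from the consensus but still
    scored against it.  Quantities whose group is smaller than
    ``min_group_n`` (before or after trimming) are flagged unscoreable and
    not held against any lab.
    """
    session_ids = {s.session_id for s in submissions} | {sp.session_id for sp in manifest}
    if len(session_ids) != 1:
        raise ConsistencyError(f"score_session expects exactly one session, got {sorted(session_ids)}")
    session_id = session_ids.pop()
    specimen_ids = {sp.specimen_id for sp in manifest}
    unknown = {s.specimen_id for s in submissions if s.status is Status.REPORTED} - specimen_ids
    if unknown:
        raise ConsistencyError(f"submissions reference specimens not in manifest: {sorted(unknown)}")

    # gather reported values per consensus group
    groups: dict[tuple, list[tuple[str, float]]] = {}
    for sub in submissions:
        if sub.status is not Status.REPORTED:
            continue
        for marker, kind, value in sub.quantities():
            key: tuple = (sub.specimen_id, marker, kind)
            if config.group_by_instrument:
                key = key + (sub.instrument,)
            groups.setdefault(key, []).append((sub.lab_id, value))

    aggregates: dict[tuple, AggregateStat] = {}
    unscoreable: list[Quantity] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1].value, k[2].value) + tuple(
        x.value for x in k[3:]
    )):
        values = groups[key]
        try:
            aggregates[key] = compute_trimmed_aggregate(
                values,
                config,
                session_id=session_id,
                specimen_id=key[0],
                marker=key[1],
                value_kind=key[2],
                instrument=key[3] if config.group_by_instrument else None,
            )
        except InsufficientGroupError:
            unscoreable.append((key[0], key[1], key[2]))

    # SDI for every reporting lab, including trimmed outliers
    by_lab: dict[str, list[Submission]] = {}
    for sub in submissions:
        by_lab.setdefault(sub.lab_id, []).append(sub)

    scoreable_quantities = {(k[0], k[1], k[2]) for k in aggregates}
    verdicts: list[LabVerdict] = []
    for lab_id in sorted(by_lab):
        lab_subs = by_lab[lab_id]
        scores: list[SdiScore] = []
        for sub in lab_subs:
            if sub.status is not Status.REPORTED:
                continue
            for marker, kind, value in sub.quantities():
                key = (sub.specimen_id, marker, kind)
                if config.group_by_instrument:
                    key = key + (sub.instrument,)
                agg = aggregates.get(key)
                if agg is not None:
                    scores.append(compute_sdi(value, agg, config, lab_id=lab_id))
        verdicts.append(adjudicate_lab(lab_subs, scores, scoreable=scoreable_quantities))

    return SessionResult(
        session_id=session_id,
        aggregates=[aggregates[k] for k in sorted(aggregates, key=lambda k: (
            (k[0], k[1].value, k[2].value) + tuple(x.value for x in k[3:])
        ))],
        verdicts=verdicts,
        unscoreable=sorted(unscoreable, key=quantity_sort_key),
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def format_quantity(q: Quantity) -> str:
    return f"{q[0]}:{q[1].value}:{q[2].value}"


def parse_quantity(text: str) -> Quantity:
    specimen_id, marker, kind = text.split(":")
    return (specimen_id, Marker(marker), ValueKind(kind))


def verdicts_to_frame(verdicts: Iterable[LabVerdict]) -> pd.DataFrame:
    rows = [
        {
            "session_id": v.session_id,
            "lab_id": v.lab_id,
            "instrument": v.instrument.value,
            "outcome": v.outcome.value,
            "failing_quantities": ";".join(
                format_quantity(q) for q in sorted(v.failing_quantities, key=quantity_sort_key)
            ),
        }
        for v in verdicts
    ]
    return pd.DataFrame(rows, columns=["session_id", "lab_id", "instrument", "outcome", "failing_quantities"])


def write_verdicts(verdicts: Iterable[LabVerdict], path: str | Path) -> None:
    verdicts_to_frame(verdicts).to_csv(path, index=False)


def read_verdicts(path: str | Path) -> list[LabVerdict]:
    """Load a verdicts table (scores are not round-tripped, only outcomes)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"session_id", "lab_id", "instrument", "outcome"} - set(df.columns)
    if missing:
        raise ConsistencyError(f"{path}: verdicts table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        failing = frozenset(
            parse_quantity(q) for q in getattr(row, "failing_quantities", "").split(";") if q
        )
        out.append(
            LabVerdict(
                lab_id=row.lab_id,
                session_id=row.session_id,
                instrument=Instrument(row.instrument),
                outcome=Outcome(row.outcome),
                failing_quantities=failing,
            )
        )
    return out


def aggregates_to_frame(aggregates: Iterable[AggregateStat]) -> pd.DataFrame:
    rows = [
        {
            "session_id": a.session_id,
            "specimen_id": a.specimen_id,
            "marker": a.marker.value,
            "value_kind": a.value_kind.value,
            "n_initial": a.n_initial,
            "n_outliers": a.n_outliers,
            "trimmed_mean": a.trimmed_mean,
            "trimmed_sd": a.trimmed_sd,
        }
        for a in aggregates
    ]
    return pd.DataFrame(rows, columns=[
        "session_id", "specimen_id", "marker", "value_kind",
        "n_initial", "n_outliers", "trimmed_mean", "trimmed_sd",
    ])


def write_aggregates(aggregates: Iterable[AggregateStat], path: str | Path) -> None:
    aggregates_to_frame(aggregates).to_csv(path, index=False)


def scores_to_frame(verdicts: Iterable[LabVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        for sc in v.scores:
            rows.append(
                {
                    "session_id": sc.session_id,
                    "lab_id": sc.lab_id,
                    "specimen_id": sc.specimen_id,
                    "marker": sc.marker.value,
                    "value_kind": sc.value_kind.value,
                    "reported_value": sc.reported_value,
                    "residual": sc.residual,
                    "sdi": sc.sdi,
                    "within_limit": sc.within_limit,
                }
            )
    return pd.DataFrame(rows, columns=[
        "session_id", "lab_id", "specimen_id", "marker", "value_kind",
        "reported_value", "residual", "sdi", "within_limit",
    ])
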