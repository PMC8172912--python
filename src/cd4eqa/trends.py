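"""Longitudinal program analytics: participation and outcome rates over sessions.

Summaries operate on adjudicated :class:`~cd4eqa.scoring.LabVerdict`
records.  Conventions:

* *registered* labs = reported + unable-to-report;
* pass/fail percentages are taken over labs that reported (the pass rate
  among those able to report), while the unable percentage is taken over
  all registered labs;
* display percentages are rounded half-up to the nearest integer, the
  style used in program summary tables; full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_model import Instrument
from .scoring import LabVerdict, Outcome


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), unlike builtin banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SessionSummary:
    """Participation and outcome counts/rates for one session."""

    session_id: str
    n_registered: int
    n_reported: int
    n_pass: int
    n_fail: int
    n_unable: int
    pct_pass: float  # of n_reported
    pct_fail: float  # of n_reported
    pct_unable: float  # of n_registered

    @property
    def pct_pass_display(self) -> int:
        return int(round_half_up(self.pct_pass))

    @property
    def pct_fail_display(self) -> int:
        return int(round_half_up(self.pct_fail))

    @property
    def pct_unable_display(self) -> int:
        return int(round_half_up(self.pct_unable))


@dataclass(frozen=True)
class InstrumentBreakdown:
    """Outcome counts/rates for one platform in one session.

    ``instrument`` is ``None`` for the all-instruments row; within-group
    percentages are over that group's reporters.
    """

    session_id: str
    instrument: Optional[Instrument]
    n_reported: int
    n_pass: int
    n_fail: int
    pct_pass: float
    pct_fail: float

    @property
    def pct_pass_display(self) -> int:
        return int(round_half_up(self.pct_pass))

    @property
    def pct_fail_display(self) -> int:
        return int(round_half_up(self.pct_fail))


def _session_order(verdicts: Sequence[LabVerdict], session_order: Optional[Sequence[str]]) -> list[str]:
    present = {v.session_id for v in verdicts}
    if session_order is None:
        return sorted(present)
    missing = present - set(session_order)
    if missing:
        raise ValueError(f"session_order omits sessions {sorted(missing)}")
    return [s for s in session_order if s in present]


def summarize_session(verdicts: Sequence[LabVerdict]) -> SessionSummary:
    """Counts and outcome rates for one session's verdicts."""
    if not verdicts:
        raise ValueError("summarize_session needs at least one verdict")
    sessions = {v.session_id for v in verdicts}
    if len(sessions) != 1:
        raise ValueError(f"verdicts span multiple sessions: {sorted(sessions)}")
    n_pass = sum(v.outcome is Outcome.PASS for v in verdicts)
    n_fail = sum(v.outcome is Outcome.FAIL for v in verdicts)
    n_unable = sum(v.outcome is Outcome.UNABLE for v in verdicts)
    n_reported = n_pass + n_fail
    n_registered = n_reported + n_unable
    nan = float("nan")
    return SessionSummary(
        session_id=sessions.pop(),
        n_registered=n_registered,
        n_reported=n_reported,
        n_pass=n_pass,
        n_fail=n_fail,
        n_unable=n_unable,
        pct_pass=100.0 * n_pass / n_reported if n_reported else nan,
        pct_fail=100.0 * n_fail / n_reported if n_reported else nan,
        pct_unable=100.0 * n_unable / n_registered if n_registered else nan,
    )


def summarize_sessions(
    verdicts: Sequence[LabVerdict], session_order: Optional[Sequence[str]] = None
) -> list[SessionSummary]:
    order = _session_order(verdicts, session_order)
    return [
        summarize_session([v for v in verdicts if v.session_id == sid]) for sid in order
    ]


def instrument_table(
    verdicts: Sequence[LabVerdict], session_order: Optional[Sequence[str]] = None
) -> list[InstrumentBreakdown]:
    """Per-(session, instrument) outcome rows plus an all-instruments row per session.

    Only reporting labs enter the rows (unable-to-report labs carry no
    scored result); instruments absent from a session get no row.
    """
    order = _session_order(verdicts, session_order)
    rows: list[InstrumentBreakdown] = []
    for sid in order:
        reported = [
            v for v in verdicts if v.session_id == sid and v.outcome is not Outcome.UNABLE
        ]

        def row(instrument: Optional[Instrument], group: Sequence[LabVerdict]) -> InstrumentBreakdown:
            n_pass = sum(v.outcome is Outcome.PASS for v in group)
            n_fail = len(group) - n_pass
            nan = float("nan")
            return InstrumentBreakdown(
                session_id=sid,
                instrument=instrument,
                n_reported=len(group),
                n_pass=n_pass,
                n_fail=n_fail,
                pct_pass=100.0 * n_pass / len(group) if group else nan,
                pct_fail=100.0 * n_fail / len(group) if group else nan,
            )

        rows.append(row(None, reported))
        for inst in Instrument:
            group = [v for v in reported if v.instrument is inst]
            if group:
                rows.append(row(inst, group))
    return rows


def failure_rate_series(
    verdicts: Sequence[LabVerdict], session_order: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-session failure percentages by platform, plus the all-instruments baseline.

    Returns a DataFrame indexed by session (in program order) with one
    column per platform present anywhere in the input and an ``all``
    baseline column; cells are NaN where a platform had no reporters.
    """
    rows = instrument_table(verdicts, session_order)
    order = _session_order(verdicts, session_order)
    data: dict[str, dict[str, float]] = {sid: {} for sid in order}
    columns = ["all"]
    for r in rows:
        name = "all" if r.instrument is None else r.instrument.value
        if name not in columns:
            columns.append(name)
        data[r.session_id][name] = r.pct_fail
    df = pd.DataFrame(
        [[data[sid].get(col, float("nan")) for col in columns] for sid in order],
        index=pd.Index(order, name="session_id"),
        columns=columns,
    )
    return df


def participation_series(
    verdicts: Sequence[LabVerdict], session_order: Optional[Sequence[str]] = None
) -> pd.Series:
    """Registered labs (reported + unable) per session, in program order."""
    if not verdicts:
        return pd.Series([], dtype=int, name="n_registered")
    summaries = summarize_sessions(verdicts, session_order)
    return pd.Series(
        [s.n_registered for s in summaries],
        index=pd.Index([s.session_id for s in summaries], name="session_id"),
        name="n_registered",
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def summaries_to_frame(summaries: Iterable[SessionSummary], formatted: bool = False) -> pd.DataFrame:
    """Session summaries as a DataFrame.

    With ``formatted=True`` counts carry display percentages in
    parentheses, mirroring the program's printed tables.
    """
    rows = []
    for s in summaries:
        if formatted:
            rows.append(
                {
                    "session_id": s.session_id,
                    "registered": str(s.n_registered),
                    "pass": f"{s.n_pass} ({s.pct_pass_display})" if s.n_reported else "0 (-)",
                    "fail": f"{s.n_fail} ({s.pct_fail_display})" if s.n_reported else "0 (-)",
                    "unable": f"{s.n_unable} ({s.pct_unable_display})",
                }
            )
        else:
            rows.append(
                {
                    "session_id": s.session_id,
                    "n_registered": s.n_registered,
                    "n_reported": s.n_reported,
                    "n_pass": s.n_pass,
                    "n_fail": s.n_fail,
                    "n_unable": s.n_unable,
                    "pct_pass": s.pct_pass,
                    "pct_fail": s.pct_fail,
                    "pct_unable": s.pct_unable,
                }
            )
    return pd.DataFrame(rows)


def breakdowns_to_frame(rows: Iterable[InstrumentBreakdown], formatted: bool = False) -> pd.DataFrame:
    out = []
    for r in rows:
        name = "all" if r.instrument is None else r.instrument.value
        if formatted:
            out.append(
                {
                    "session_id": r.session_id,
                    "instrument": name,
                    "reported": str(r.n_reported),
                    "pass": f"{r.n_pass} ({r.pct_pass_display})" if r.n_reported else "0 (-)",
                    "fail": f"{r.n_fail} ({r.pct_fail_display})" if r.n_reported else "0 (-)",
                }
            )
        else:
            out.append(
                {
                    "session_id": r.session_id,
                    "instrument": name,
                    "n_reported": r.n_reported,
                    "n_pass": r.n_pass,
                    "n_fail": r.n_fail,
                    "pct_pass": r.pct_pass,
                    "pct_fail": r.pct_fail,
                }
            )
    return pd.DataFrame(out)


def write_trend_tables(
    verdicts: Sequence[LabVerdict],
    out_dir: str | Path,
    session_order: Optional[Sequence[str]] = None,
) -> None:
    """Write session_summaries / instrument_breakdown / failure_rates / participation CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries_to_frame(summarize_sessions(verdicts, session_order)).to_csv(
        out / "session_summaries.csv", index=False
    )
    breakdowns_to_frame(instrument_table(verdicts, session_order)).to_csv(
        out / "instrument_breakdown.csv", index=False
    )
    failure_rate_series(verdicts, session_order).to_csv(out / "failure_rates.csv")
    participation_series(verdicts, session_order).to_csv(out / "participation.csv")
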