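"""Per-lab performance reports and the coordinator country report.

Each report exists in two deterministic renderings: a structured
dictionary (serialised as JSON, for machines) and a plain-text document
(for humans).  Rendering is pure — identical inputs give byte-identical
output; any timestamp is injected by the caller, never sampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .error_taxonomy import ErrorRecord, Phase, phase_distribution
from .io_model import Quantity, quantity_sort_key
from .scoring import (
    AggregateStat,
    ConsistencyError,
    LabVerdict,
    Outcome,
    format_quantity,
)
from .trends import (
    InstrumentBreakdown,
    SessionSummary,
    instrument_table,
    summarize_session,
)


def _fmt_sdi(sdi: float) -> str:
    """Signed, two-decimal SDI (the sign says high or low versus consensus)."""
    return f"{sdi:+.2f}"


@dataclass(frozen=True)
class LabReport:
    """Performance report for one laboratory in one session."""

    lab_id: str
    session_id: str
    instrument: str
    outcome: Outcome
    rows: tuple[dict, ...]  # one per scored quantity
    corrective_actions: tuple[str, ...] = ()
    unable_reason: Optional[str] = None
    notes: str = ""
    generated_at: str = ""

    def to_dict(self) -> dict:
        return {
            "lab_id": self.lab_id,
            "session_id": self.session_id,
            "instrument": self.instrument,
            "outcome": self.outcome.value,
            "rows": list(self.rows),
            "corrective_actions": list(self.corrective_actions),
            "unable_reason": self.unable_reason,
            "notes": self.notes,
            "generated_at": self.generated_at,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = [
            f"EQA performance report — lab {self.lab_id}, session {self.session_id}",
            f"Instrument: {self.instrument}",
            f"Outcome: {self.outcome.value.upper()}",
        ]
        if self.generated_at:
            lines.append(f"Generated: {self.generated_at}")
        if self.outcome is Outcome.UNABLE:
            lines.append(f"Unable to report; reason: {self.unable_reason or 'unspecified'}")
        else:
            lines.append("")
            header = (
                f"{'quantity':<28}{'reported':>10}{'mean':>10}{'sd':>8}{'SDI':>8}  within ±limit"
            )
            lines.append(header)
            for row in self.rows:
                lines.append(
                    f"{row['quantity']:<28}{row['reported_value']:>10.1f}"
                    f"{row['trimmed_mean']:>10.1f}{row['trimmed_sd']:>8.2f}"
                    f"{row['sdi_display']:>8}  {'yes' if row['within_limit'] else 'NO'}"
                )
            if self.notes:
                lines.append("")
                lines.append(f"Notes: {self.notes}")
            if self.corrective_actions:
                lines.append("")
                lines.append("Recommended corrective-action categories:")
                for cat in self.corrective_actions:
                    lines.append(f"  - {cat}")
        return "\n".join(lines) + "\n"


def render_lab_report(
    verdict: LabVerdict,
    aggregates: Mapping[Quantity, AggregateStat],
    errors: Sequence[ErrorRecord] = (),
    generated_at: str = "",
) -> LabReport:
    """Build the per-lab report from an adjudicated verdict.

    ``aggregates`` maps each scored quantity to its consensus statistics;
    ``errors`` are coordinator-entered records, filtered here to this lab
    and session.  A verdict with no scores that is neither unable-to-report
    nor flagged unscored is inconsistent.
    """
    if (
        not verdict.scores
        and verdict.outcome is not Outcome.UNABLE
        and "unscored" not in verdict.notes
    ):
        raise ConsistencyError(
            f"verdict for lab {verdict.lab_id} has outcome {verdict.outcome.value} but no scores"
        )
    rows = []
    for sc in verdict.scores:
        agg = aggregates.get(sc.quantity)
        if agg is None:
            raise ConsistencyError(f"no aggregate for scored quantity {format_quantity(sc.quantity)}")
        rows.append(
            {
                "quantity": format_quantity(sc.quantity),
                "specimen_id": sc.specimen_id,
                "marker": sc.marker.value,
                "value_kind": sc.value_kind.value,
                "reported_value": sc.reported_value,
                "trimmed_mean": agg.trimmed_mean,
                "trimmed_sd": agg.trimmed_sd,
                "sdi": sc.sdi,
                "sdi_display": _fmt_sdi(sc.sdi),
                "within_limit": sc.within_limit,
            }
        )
    actions = tuple(
        sorted(
            {
                rec.category.value
                for rec in errors
                if rec.lab_id == verdict.lab_id and rec.session_id == verdict.session_id
            }
        )
    )
    return LabReport(
        lab_id=verdict.lab_id,
        session_id=verdict.session_id,
        instrument=verdict.instrument.value,
        outcome=verdict.outcome,
        rows=tuple(rows),
        corrective_actions=actions,
        unable_reason=verdict.unable_reason.value if verdict.unable_reason else None,
        notes=verdict.notes,
        generated_at=generated_at,
    )


@dataclass(frozen=True)
class CoordinatorReport:
    """Country-level session report for the program coordinator."""

    session_id: str
    summary: SessionSummary
    breakdowns: tuple[InstrumentBreakdown, ...]
    failing_labs: tuple[dict, ...]
    phase_percentages: Mapping[Phase, float]
    unscored_quantities: tuple[str, ...] = ()
    generated_at: str = ""

    def to_dict(self) -> dict:
        s = self.summary
        return {
            "session_id": self.session_id,
            "summary": {
                "n_registered": s.n_registered,
                "n_reported": s.n_reported,
                "n_pass": s.n_pass,
                "n_fail": s.n_fail,
                "n_unable": s.n_unable,
                "pct_pass": s.pct_pass_display if s.n_reported else None,
                "pct_fail": s.pct_fail_display if s.n_reported else None,
                "pct_unable": s.pct_unable_display if s.n_registered else None,
            },
            "instrument_breakdown": [
                {
                    "instrument": "all" if b.instrument is None else b.instrument.value,
                    "n_reported": b.n_reported,
                    "n_pass": b.n_pass,
                    "n_fail": b.n_fail,
                    "pct_pass": b.pct_pass_display if b.n_reported else None,
                    "pct_fail": b.pct_fail_display if b.n_reported else None,
                }
                for b in self.breakdowns
            ],
            "failing_labs": list(self.failing_labs),
            "phase_distribution": {p.value: v for p, v in self.phase_percentages.items()},
            "unscored_quantities": list(self.unscored_quantities),
            "generated_at": self.generated_at,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        s = self.summary
        lines = [
            f"EQA coordinator report — session {self.session_id}",
        ]
        if self.generated_at:
            lines.append(f"Generated: {self.generated_at}")
        pct_pass = f"{s.pct_pass_display}%" if s.n_reported else "-"
        pct_fail = f"{s.pct_fail_display}%" if s.n_reported else "-"
        lines += [
            "",
            f"Registered labs: {s.n_registered}",
            f"Reporting labs:  {s.n_reported}",
            f"Pass: {s.n_pass} ({pct_pass})   Fail: {s.n_fail} ({pct_fail})   "
            f"Unable to report: {s.n_unable}",
            "",
            "By instrument:",
        ]
        for b in self.breakdowns:
            name = "all" if b.instrument is None else b.instrument.value
            lines.append(
                f"  {name:<12} reported {b.n_reported:>3}  "
                f"pass {b.n_pass:>3} ({b.pct_pass_display if b.n_reported else 0}%)  "
                f"fail {b.n_fail:>3} ({b.pct_fail_display if b.n_reported else 0}%)"
            )
        lines.append("")
        if self.failing_labs:
            lines.append("Corrective actions recommended for failing labs:")
            for entry in self.failing_labs:
                actions = ", ".join(entry["recommended_actions"]) or "to be determined"
                lines.append(
                    f"  {entry['lab_id']}: failing {', '.join(entry['failing_quantities'])}"
                    f" — {actions}"
                )
        else:
            lines.append("Corrective actions: none required (all reporting labs passed).")
        if self.phase_percentages:
            lines.append("")
            lines.append("Failure phase distribution (% of recorded errors):")
            for phase in Phase:
                if phase in self.phase_percentages:
                    lines.append(f"  {phase.value:<16} {self.phase_percentages[phase]:>5.1f}")
        if self.unscored_quantities:
            lines.append("")
            lines.append(
                "Unscored quantities (participant group below the minimum size): "
                + ", ".join(self.unscored_quantities)
            )
        return "\n".join(lines) + "\n"


def render_coordinator_report(
    session_id: str,
    verdicts: Sequence[LabVerdict],
    errors: Sequence[ErrorRecord] = (),
    unscoreable: Sequence[Quantity] = (),
    generated_at: str = "",
) -> CoordinatorReport:
    """Aggregate one session's verdicts and error records into the country report."""
    session_verdicts = [v for v in verdicts if v.session_id == session_id]
    if not session_verdicts:
        raise ConsistencyError(f"no verdicts for session {session_id}")
    session_errors = [e for e in errors if e.session_id == session_id]
    failing = []
    for v in sorted(session_verdicts, key=lambda v: v.lab_id):
        if v.outcome is not Outcome.FAIL:
            continue
        actions = sorted(
            {e.category.value for e in session_errors if e.lab_id == v.lab_id}
        )
        failing.append(
            {
                "lab_id": v.lab_id,
                "failing_quantities": [
                    format_quantity(q)
                    for q in sorted(v.failing_quantities, key=quantity_sort_key)
                ],
                "recommended_actions": actions,
            }
        )
    return CoordinatorReport(
        session_id=session_id,
        summary=summarize_session(session_verdicts),
        breakdowns=tuple(instrument_table(session_verdicts)),
        failing_labs=tuple(failing),
        phase_percentages=phase_distribution(session_errors),
        unscored_quantities=tuple(
            format_quantity(q) for q in sorted(unscoreable, key=quantity_sort_key)
        ),
        generated_at=generated_at,
    )


def write_session_reports(
    out_dir: str | Path,
    verdicts: Sequence[LabVerdict],
    aggregates: Iterable[AggregateStat],
    errors: Sequence[ErrorRecord] = (),
    unscoreable: Sequence[Quantity] = (),
    generated_at: str = "",
) -> None:
    """Write one lab report pair per verdict plus the coordinator report pair."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    agg_map = {(a.specimen_id, a.marker, a.value_kind): a for a in aggregates}
    sessions = sorted({v.session_id for v in verdicts})
    for session_id in sessions:
        for v in sorted(
            (v for v in verdicts if v.session_id == session_id), key=lambda v: v.lab_id
        ):
            report = render_lab_report(v, agg_map, errors, generated_at=generated_at)
            stem = f"lab_{v.lab_id}_{session_id}"
            (out / f"{stem}.json").write_text(report.to_json(), encoding="utf-8")
            (out / f"{stem}.txt").write_text(report.to_text(), encoding="utf-8")
        coord = render_coordinator_report(
            session_id, verdicts, errors, unscoreable, generated_at=generated_at
        )
        (out / f"coordinator_{session_id}.json").write_text(coord.to_json(), encoding="utf-8")
        (out / f"coordinator_{session_id}.txt").write_text(coord.to_text(), encoding="utf-8")
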