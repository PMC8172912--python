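"""Failure-cause taxonomy: testing-phase classification and distributions.

Every failure recorded by the program coordinator is assigned a category
from a fixed list; each category belongs to exactly one phase of the
testing process:

* **pre-analytical** — before the specimen is tested: transport delay or
  preservation problems, compromised sample integrity, identification or
  request-procedure mistakes, sample mix-ups;
* **analytical** — during testing: expired reagents, pipetting and pipette
  calibration, gating technique, instrument error codes, sample
  handling/processing;
* **post-analytical** — after testing: data entry on the paper form or the
  submission website, transcription errors, reporting omissions.

Records are coordinator-entered annotations attached to failing verdicts;
no automatic root-cause inference is performed.  Distributions count
records (a failing lab may carry several).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .io_model import EqaError, SchemaError, ValidationError, _check_header


class TaxonomyError(EqaError):
    """Unknown failure category."""


class Phase(str, Enum):
    PRE_ANALYTICAL = "pre_analytical"
    ANALYTICAL = "analytical"
    POST_ANALYTICAL = "post_analytical"


class ErrorCategory(str, Enum):
    # pre-analytical
    DELAYED_TRANSPORT_PRESERVATION = "delayed_transport_preservation"
    SAMPLE_INTEGRITY = "sample_integrity"
    INCORRECT_SAMPLE_IDENTIFICATION = "incorrect_sample_identification"
    REQUEST_PROCEDURE_ERROR = "request_procedure_error"
    SAMPLE_MIXUP = "sample_mixup"
    # analytical
    EXPIRED_REAGENTS = "expired_reagents"
    PIPETTING_ERROR = "pipetting_error"
    PIPETTE_CALIBRATION = "pipette_calibration"
    GATING_TECHNIQUE = "gating_technique"
    INSTRUMENT_ERROR_CODE = "instrument_error_code"
    SAMPLE_HANDLING_PROCESSING = "sample_handling_processing"
    # post-analytical
    DATA_ENTRY_PAPER_FORM = "data_entry_paper_form"
    DATA_ENTRY_WEBSITE = "data_entry_website"
    TRANSCRIPTION_ERROR = "transcription_error"
    REPORTING_OMISSION = "reporting_omission"


CATEGORY_PHASE: Mapping[ErrorCategory, Phase] = {
    ErrorCategory.DELAYED_TRANSPORT_PRESERVATION: Phase.PRE_ANALYTICAL,
    ErrorCategory.SAMPLE_INTEGRITY: Phase.PRE_ANALYTICAL,
    ErrorCategory.INCORRECT_SAMPLE_IDENTIFICATION: Phase.PRE_ANALYTICAL,
    ErrorCategory.REQUEST_PROCEDURE_ERROR: Phase.PRE_ANALYTICAL,
    ErrorCategory.SAMPLE_MIXUP: Phase.PRE_ANALYTICAL,
    ErrorCategory.EXPIRED_REAGENTS: Phase.ANALYTICAL,
    ErrorCategory.PIPETTING_ERROR: Phase.ANALYTICAL,
    ErrorCategory.PIPETTE_CALIBRATION: Phase.ANALYTICAL,
    ErrorCategory.GATING_TECHNIQUE: Phase.ANALYTICAL,
    ErrorCategory.INSTRUMENT_ERROR_CODE: Phase.ANALYTICAL,
    ErrorCategory.SAMPLE_HANDLING_PROCESSING: Phase.ANALYTICAL,
    ErrorCategory.DATA_ENTRY_PAPER_FORM: Phase.POST_ANALYTICAL,
    ErrorCategory.DATA_ENTRY_WEBSITE: Phase.POST_ANALYTICAL,
    ErrorCategory.TRANSCRIPTION_ERROR: Phase.POST_ANALYTICAL,
    ErrorCategory.REPORTING_OMISSION: Phase.POST_ANALYTICAL,
}

PHASE_CATEGORIES: Mapping[Phase, tuple[ErrorCategory, ...]] = {
    phase: tuple(c for c, p in CATEGORY_PHASE.items() if p is phase) for phase in Phase
}


def classify_error(category: ErrorCategory | str) -> Phase:
    """Map a failure category to its testing phase.

    Accepts the enum or its string value; unknown categories raise
    :class:`TaxonomyError`.
    """
    if isinstance(category, str) and not isinstance(category, ErrorCategory):
        try:
            category = ErrorCategory(category)
        except ValueError:
            raise TaxonomyError(f"unknown error category: {category!r}") from None
    return CATEGORY_PHASE[category]


@dataclass(frozen=True)
class ErrorRecord:
    """One classified failure cause for one lab in one session."""

    lab_id: str
    session_id: str
    category: ErrorCategory
    note: str = ""

    @property
    def phase(self) -> Phase:
        return CATEGORY_PHASE[self.category]


def _pct(count: int, total: int) -> float:
    # one-decimal percentages, half-up, so the three phases sum to 100 ± 0.1
    ratio = Decimal(100 * count) / Decimal(total)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def phase_distribution(errors: Iterable[ErrorRecord]) -> dict[Phase, float]:
    """Percentage of error records per phase, to one decimal.

    Returns an empty mapping for an empty collection (no division by
    zero); otherwise every phase appears, including zero-count phases.
    """
    errors = list(errors)
    if not errors:
        return {}
    total = len(errors)
    counts = {phase: 0 for phase in Phase}
    for rec in errors:
        counts[rec.phase] += 1
    return {phase: _pct(count, total) for phase, count in counts.items()}


def category_distribution(errors: Iterable[ErrorRecord]) -> dict[ErrorCategory, float]:
    """Percentage of error records per category (observed categories only)."""
    errors = list(errors)
    if not errors:
        return {}
    total = len(errors)
    counts: dict[ErrorCategory, int] = {}
    for rec in errors:
        counts[rec.category] = counts.get(rec.category, 0) + 1
    return {c: _pct(n, total) for c, n in sorted(counts.items(), key=lambda kv: kv[0].value)}


ERROR_COLUMNS = ["session_id", "lab_id", "category", "note"]


def parse_error_records(path: str | Path) -> list[ErrorRecord]:
    """Load coordinator-entered error records; the phase is derived, never stored."""
    path = Path(path)
    records: list[ErrorRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, ERROR_COLUMNS, path)
        for line, row in enumerate(reader, start=2):
            try:
                category = ErrorCategory(row["category"].strip())
            except ValueError:
                raise TaxonomyError(
                    f"{path}:{line}: unknown error category {row['category']!r}"
                ) from None
            records.append(
                ErrorRecord(
                    lab_id=row["lab_id"].strip(),
                    session_id=row["session_id"].strip(),
                    category=category,
                    note=row["note"],
                )
            )
    return records


def write_error_records(records: Iterable[ErrorRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ERROR_COLUMNS)
        for rec in records:
            writer.writerow([rec.session_id, rec.lab_id, rec.category.value, rec.note])
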