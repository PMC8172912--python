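"""Shared fixtures: deterministic hypothesis profile and verdict builders."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import HealthCheck, settings

from cd4eqa import Instrument, LabVerdict, Outcome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: Pass/fail counts of the 11 evaluated sessions of a national CD4 EQA
#: program, by platform: {session: {instrument: (n_pass, n_fail)}}.
#: Row sums across platforms equal the all-instruments counts.
PROGRAM_HISTORY: dict[str, dict[Instrument, tuple[int, int]]] = {
    "01": {Instrument.FACSCOUNT: (3, 5), Instrument.CYFLOW: (2, 1),
           Instrument.PIMA: (1, 1), Instrument.OTHER: (1, 0)},
    "02": {Instrument.FACSCOUNT: (9, 7), Instrument.CYFLOW: (5, 8),
           Instrument.PIMA: (11, 6), Instrument.OTHER: (4, 0)},
    "03": {Instrument.FACSCOUNT: (11, 5), Instrument.CYFLOW: (6, 5),
           Instrument.PIMA: (16, 3), Instrument.OTHER: (2, 0)},
    "04": {Instrument.FACSCOUNT: (10, 1), Instrument.CYFLOW: (12, 2),
           Instrument.PIMA: (31, 1), Instrument.OTHER: (2, 0)},
    "05": {Instrument.FACSCOUNT: (8, 1), Instrument.CYFLOW: (10, 3),
           Instrument.PIMA: (28, 5), Instrument.OTHER: (2, 0)},
    "06": {Instrument.FACSCOUNT: (11, 0), Instrument.CYFLOW: (7, 1),
           Instrument.PIMA: (30, 3), Instrument.OTHER: (2, 0)},
    "07": {Instrument.FACSCOUNT: (6, 0), Instrument.CYFLOW: (2, 0),
           Instrument.PIMA: (8, 1), Instrument.OTHER: (0, 1)},
    "08": {Instrument.FACSCOUNT: (5, 4), Instrument.CYFLOW: (4, 1),
           Instrument.PIMA: (13, 2), Instrument.OTHER: (1, 1)},
    "09": {Instrument.FACSCOUNT: (5, 0), Instrument.CYFLOW: (7, 2),
           Instrument.PIMA: (29, 3), Instrument.OTHER: (2, 0)},
    "10": {Instrument.FACSCOUNT: (4, 2), Instrument.CYFLOW: (2, 5),
           Instrument.PIMA: (29, 3), Instrument.OTHER: (1, 1)},
    "11": {Instrument.FACSCOUNT: (6, 0), Instrument.CYFLOW: (5, 3),
           Instrument.PIMA: (36, 1), Instrument.OTHER: (2, 1)},
}


def make_verdicts(
    session_id: str,
    instrument: Instrument,
    n_pass: int,
    n_fail: int,
    n_unable: int = 0,
    lab_prefix: str = "LAB",
) -> list[LabVerdict]:
    """Build bare verdicts (no scores) with the requested outcome counts."""
    counter = itertools.count(1)
    out = []
    for outcome, n in (
        (Outcome.PASS, n_pass), (Outcome.FAIL, n_fail), (Outcome.UNABLE, n_unable)
    ):
        for _ in range(n):
            out.append(
                LabVerdict(
                    lab_id=f"{lab_prefix}-{instrument.value}-{next(counter):03d}",
                    session_id=session_id,
                    instrument=instrument,
                    outcome=outcome,
                )
            )
    return out


@pytest.fixture
def history_verdicts() -> list[LabVerdict]:
    """The full 11-session program history as a verdict fixture."""
    verdicts = []
    for session_id, by_inst in PROGRAM_HISTORY.items():
        for inst, (n_pass, n_fail) in by_inst.items():
            verdicts.extend(make_verdicts(session_id, inst, n_pass, n_fail))
    return verdicts
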