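"""Independent brute-force oracle for consensus trimming.

Deliberately naive: plain lists, the stdlib ``statistics`` module, and an
explicit exclude-and-recompute loop.  Kept free of any import from the
package's scoring code so it can stand as an independent cross-check.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass


@dataclass
class OracleResult:
    retained: list[float]
    n_outliers: int
    mean: float
    sd: float


def brute_force_trim(
    values: list[float], k: float = 2.0, passes: int = 1, min_n: int = 3
) -> OracleResult | None:
    """Trim values more than ``k`` SDs from the mean, then recompute.

    Returns ``None`` where the scorer must refuse: fewer than ``min_n``
    values supplied, or trimming would leave fewer than ``min_n``.
    """
    if len(values) < min_n:
        return None
    retained = list(values)
    n_outliers = 0
    for _ in range(passes):
        mean = statistics.fmean(retained)
        sd = statistics.stdev(retained)
        if sd == 0.0:
            break
        keep = [v for v in retained if abs(v - mean) <= k * sd]
        if len(keep) == len(retained):
            break
        n_outliers += len(retained) - len(keep)
        retained = keep
        if len(retained) < min_n:
            return None
    return OracleResult(
        retained=retained,
        n_outliers=n_outliers,
        mean=statistics.fmean(retained),
        sd=statistics.stdev(retained) if len(retained) > 1 else 0.0,
    )
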