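# cd4eqa

Scoring and longitudinal analytics for national **CD4 enumeration external
quality assessment (EQA) programs**.

In an EQA scheme, a coordinating reference laboratory ships blinded panels —
two stabilized whole-blood specimens, one with a low and one with a mid CD4
count — to every registered laboratory, three times a year. Each lab returns
the percentage and absolute count of CD3, CD4 and CD8 T-cells measured on its
own platform (conventional cytometers such as FACSCount and CyFlow, or
point-of-care analyzers such as PIMA), or declares itself unable to report.
Accurate CD4 enumeration drives HIV staging and treatment monitoring, so the
coordinator must detect labs drifting out of agreement and direct corrective
action. This package implements that evaluation pipeline for program
coordinators and QA researchers.

## The scoring rule

For each scored quantity (specimen × marker × percent-or-absolute), over all
reported values $x_1, \dots, x_n$:

1. compute the group mean $\bar{x}$ and sample SD $s$ (with $n-1$ denominator);
2. values with $|x_i - \bar{x}| > 2s$ are **outliers** and are excluded;
3. recompute $\bar{x}^{*}$ and $s^{*}$ on the retained values;
4. each lab's **Standard Deviation Index** is
   $\mathrm{SDI}_i = (x_i - \bar{x}^{*}) / s^{*}$; positive means the lab read
   high, negative low.

A quantity is satisfactory when $|\mathrm{SDI}| \le 2$ (boundary inclusive); a
lab passes a session only if every quantity it reported on both specimens is
satisfactory; a registered lab returning no result is *unable to report*.
Outlier-trimmed labs are still scored against the trimmed consensus. Each
failure the coordinator records is classified into a fixed category list and
its testing phase (pre-analytical / analytical / post-analytical), and the
longitudinal module tracks participation, pass/fail/unable rates, and
per-platform failure rates across sessions.

Because real submissions are confidential, the package ships a synthetic
program generator with known ground truth (per-lab bias, injected errors by
phase, unable events) so the whole pipeline is testable end to end.

## Worked example

```python
from cd4eqa import compute_trimmed_aggregate, compute_sdi

values = [("LAB001", 500.0), ("LAB002", 510.0), ("LAB003", 490.0),
          ("LAB004", 505.0), ("LAB005", 495.0), ("LAB006", 1200.0)]
agg = compute_trimmed_aggregate(values)
print(f"n={agg.n_initial}, outliers={sorted(agg.outlier_lab_ids)}, "
      f"mean={agg.trimmed_mean:.1f}, sd={agg.trimmed_sd:.2f}")
for lab, v in values:
    s = compute_sdi(v, agg, lab_id=lab)
    print(f"{lab}: reported {v:7.1f}  SDI {s.sdi:+7.2f}  within ±2: {s.within_limit}")
```

prints

```
n=6, outliers=['LAB006'], mean=500.0, sd=7.91
LAB001: reported   500.0  SDI   +0.00  within ±2: True
LAB002: reported   510.0  SDI   +1.26  within ±2: True
LAB003: reported   490.0  SDI   -1.26  within ±2: True
LAB004: reported   505.0  SDI   +0.63  within ±2: True
LAB005: reported   495.0  SDI   -0.63  within ±2: True
LAB006: reported  1200.0  SDI  +88.54  within ±2: False
```

LAB006's gross value is excluded from the consensus (the five retained values
give mean 500, SD 7.91) but the lab is still scored against it and fails;
every retained lab sits comfortably inside ±2 SDI.

## Command line

```sh
eqa simulate --seed 42 --out sim/           # synthetic program + ground truth
eqa score --submissions sim/submissions.csv --manifest sim/manifest.csv --out scored/
eqa trends --verdicts scored/ --out trends/
eqa report --submissions sim/submissions.csv --manifest sim/manifest.csv \
    --errors sim/errors.csv --session S49 --out reports/
```

`score` writes per-lab verdicts, consensus aggregates and SDI scores;
`trends` writes session summaries, per-instrument breakdowns, failure-rate
and participation series; `report` renders per-lab performance reports and
the coordinator's country report (JSON + plain text). All commands exit
nonzero with a diagnostic on schema or consistency errors.

## Acceptance script

`scripts/acceptance.py` exercises the pipeline from scratch: it generates the
default 11-session synthetic program from the given seed, scores every
session, derives the longitudinal tables, renders the final session's
coordinator report, and writes the acceptance JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the statistical conventions, generator design and
known limitations.
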