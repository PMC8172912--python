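# Methods

## Consensus statistics and SDI scoring

The target value for every scored quantity is a *trimmed consensus*: the
group mean after excluding values more than `outlier_k` (default 2) sample
standard deviations from the initial group mean, recomputed once
(`trim_passes = 1`; iterated trimming is available but is not the program's
rule). Conventions, chosen where the scheme's published description is
silent:

- **Sample SD** (n−1 denominator) throughout: groups are small and this is
  the interlaboratory-statistics convention.
- **Strict outlier boundary**: a value at exactly 2 SD is retained ("greater
  than" two SDs is excluded); **inclusive pass boundary**: |SDI| = 2 exactly
  is satisfactory ("within" ±2).
- **Pooled consensus**: all platforms contribute to one consensus per
  quantity. Peer-group (per-instrument) scoring is available via
  `ScoringConfig(group_by_instrument=True)` but is not the default, since the
  scheme describes a single group mean.
- **Trimmed labs are still adjudicated**: exclusion from the consensus is not
  an automatic failure; the lab's SDI is computed against the trimmed
  statistics and judged by the same ±2 rule.
- **Minimum group size** `min_group_n = 3` (also enforced after trimming):
  smaller groups make a 2-lab "consensus" meaningless, so the quantity is
  flagged *unscoreable* and not held against any lab. A lab all of whose
  reported quantities are unscoreable is recorded as pass with an
  `unscored` note rather than invented into either outcome.
- **Unanimous groups** (`trimmed_sd = 0`): a matching value scores SDI 0; any
  deviation is out of limit, recorded as signed infinity.
- **Aggregation to a verdict**: a lab passes only if *every* quantity it
  reported, on both specimens, is within limit. Quantities a platform does
  not measure (e.g. percentages on PIMA) are never held against it. A
  registered lab with no reported result is *unable to report*.

Determinism: group values are summed in a fixed (sorted) order, so verdicts
are bit-identical under any permutation of the input rows.

## Error taxonomy

Failure causes are coordinator-entered annotations (no automatic root-cause
inference): 15 fixed categories mapped totally onto the pre-analytical,
analytical and post-analytical phases. Distributions count *records*, not
labs — a failing lab may carry several causes. Percentages are reported to
one decimal with half-up rounding; the three phases sum to 100 within 0.1.

## Longitudinal analytics

Pass/fail percentages are taken over labs that reported; the
unable-to-report percentage over all registered labs (reported + unable).
Display percentages round half-up to the nearest integer — the style of
program summary tables — while full precision is retained internally.
Per-instrument rows partition the all-instruments row exactly; a platform
with no reporters in a session gets no row. Session ordering is supplied by
the caller (the generator emits its schedule); the default is lexicographic.

## Synthetic program generator

The generator states a world resembling a national program observed over
eleven sessions (2014–2018, three per year):

- **Roster growth** follows the observed per-session reporter counts
  (14, 50, 48, 59, 57, 54, 18, 31, 48, 47, 54) and the platform shares of the
  same history, under which conventional cytometers decline while PIMA
  point-of-care sites grow from 2 to 37.
- **Panel targets** are declared, clinically plausible values (the scheme
  never publishes its targets): low specimen ≈ 150 CD4 cells/µL, mid ≈ 500,
  with CD3/CD8 companions satisfying CD3 ≈ CD4 + CD8; all overridable.
- **Measurement model**: `value = nominal × (1 + bias) × (1 + ε)` with
  `ε ~ N(0, cv²)`; platform CVs default to 4 % (FACSCount), 6 % (CyFlow,
  volumetric and pipetting-sensitive), 8 % (PIMA), 5 % (other). Per-lab bias
  is persistent across sessions, drawn once from `N(0, 0.02²)` unless pinned
  via `lab_bias`. Absolute counts are reported as whole cells/µL, percentages
  to one decimal; values are clamped to their legal ranges rather than drawn
  from truncated distributions (simplicity and testability over tail
  fidelity).
- **Unable to report** occurs with probability 0.08 per lab-session (reason
  drawn uniformly from the observed list); **injected errors** occur with
  probability 0.12 per reporting lab (a per-session schedule is supported for
  declining-error scenarios), with phase probabilities 0.175 / 0.770 / 0.055.
  Each phase has a concrete surrogate: pre-analytical degrades the whole
  panel by `error_magnitude` (sample-integrity drift), analytical perturbs
  one quantity by ±`error_magnitude` (pipetting/gating surrogate),
  post-analytical swaps two absolute values on one specimen or drops the last
  digit (transcription surrogate). `error_magnitude` defaults to 0.5 — large
  relative to platform CVs, as real recorded failures are gross errors, not
  noise.
- **Reproducibility**: one seed sequence, split per session, so programs are
  bit-identical for a seed and sessions are independently regenerable.

What the generator does *not* emulate: correlated failures within a site
over time, platform switching mid-program, drift in panel target values,
partial panels (a lab reporting one specimen only), and corrective-action
feedback reducing a lab's future failure hazard. A green synthetic test
therefore establishes that the pipeline recovers the effects it injects —
not that the defaults reproduce any particular program's measured history.

## Parameter-recovery harness

The recovery criterion (biased labs fail, clean labs pass, each in ≥95 % of
trials over 100 seeds) is evaluated on a single-quantity world: 30 PIMA labs
reporting only the absolute CD4 count at cv = 3 %, background biases from
`N(0, 0.02²)`, three labs pinned at the +4·cv bias boundary (+12 %) and three
pinned unbiased. Restricting to one quantity decouples the per-quantity
false-alarm rate (≈2 % per quantity at these settings) from panel size: with
twelve quantities per lab, even perfectly clean labs would fail a session
several percent of the time by chance alone, which is a property of the ±2
rule, not of the generator. Rates are aggregated over the pinned labs across
seeds.

## Known limitations

- The ±2 SDI rule has a non-trivial per-quantity false-alarm rate in
  homogeneous groups; programs with many scored quantities per lab will see
  chance failures. The package reports what the rule yields; it does not
  correct for multiplicity.
- With heavily contaminated groups (many coincident outliers), a single trim
  pass may retain gross values and inflate the consensus SD — the classic
  masking weakness of mean/SD trimming. Robust alternatives (median/MAD) are
  deliberately out of scope: they are not this scheme's rule.
- Published program tables contain occasional rounding inconsistencies;
  reconstruction tests target arithmetically consistent cells only.
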