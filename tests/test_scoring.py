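"""Trimmed consensus, SDI and adjudication against the brute-force oracle."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cd4eqa import (
    AggregateStat,
    ConsistencyError,
    InsufficientGroupError,
    Level,
    Marker,
    MarkerReading,
    Outcome,
    ScoringConfig,
    Specimen,
    Status,
    Submission,
    UnableReason,
    ValueKind,
    adjudicate_lab,
    compute_sdi,
    compute_trimmed_aggregate,
    score_session,
)

from .oracle import brute_force_trim


def make_agg(mean: float, sd: float) -> AggregateStat:
    return AggregateStat(
        session_id="S48", specimen_id="S48-LOW", marker=Marker.CD4,
        value_kind=ValueKind.ABSOLUTE, n_initial=10, n_outliers=0,
        trimmed_mean=mean, trimmed_sd=sd,
    )


class TestTrimmedAggregate:
    def test_unanimous_group_has_zero_sd_and_no_outliers(self):
        agg = compute_trimmed_aggregate([(f"L{i}", 500.0) for i in range(10)])
        assert agg.trimmed_mean == 500.0
        assert agg.trimmed_sd == 0.0
        assert agg.n_outliers == 0

    def test_single_gross_outlier_is_trimmed(self):
        # frozen from the brute-force oracle: full-group mean 616.67, SD 286.2;
        # only 1200 lies beyond 2 SD; retained values have mean 500, SD 7.906
        values = [("A", 500.0), ("B", 510.0), ("C", 490.0), ("D", 505.0),
                  ("E", 495.0), ("F", 1200.0)]
        agg = compute_trimmed_aggregate(values)
        assert agg.n_outliers == 1
        assert agg.outlier_lab_ids == {"F"}
        assert agg.trimmed_mean == pytest.approx(500.0)
        assert agg.trimmed_sd == pytest.approx(7.905694, abs=1e-6)
        oracle = brute_force_trim([v for _, v in values])
        assert agg.trimmed_mean == pytest.approx(oracle.mean)
        assert agg.trimmed_sd == pytest.approx(oracle.sd)
        assert agg.n_outliers == oracle.n_outliers

    def test_group_below_minimum_size_refused(self):
        with pytest.raises(InsufficientGroupError):
            compute_trimmed_aggregate([("A", 500.0), ("B", 510.0)])

    def test_value_exactly_at_two_sd_is_retained(self):
        # [97,97,97,97,92,120]: mean 100 and sample SD 10 exactly, so the
        # extreme sits at exactly 2 SD; the strict >2-SD rule must keep it
        values = [97.0, 97.0, 97.0, 97.0, 92.0, 120.0]
        agg = compute_trimmed_aggregate([(f"L{i}", v) for i, v in enumerate(values)])
        assert agg.trimmed_mean == 100.0
        assert agg.trimmed_sd == 10.0
        assert agg.n_outliers == 0
        # one step past the boundary is trimmed: z = 5/sqrt(6) > 2
        past = [0.0] * 5 + [1.0]
        agg2 = compute_trimmed_aggregate([(f"L{i}", v) for i, v in enumerate(past)])
        assert agg2.n_outliers == 1

    def test_trimming_strictly_decreases_sample_sd(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            vals = list(rng.normal(500, 20, size=12)) + [800.0]
            labs = [(f"L{i}", float(v)) for i, v in enumerate(vals)]
            agg = compute_trimmed_aggregate(labs)
            if agg.n_outliers >= 1:
                assert agg.trimmed_sd < float(np.std(vals, ddof=1))

    def test_iterated_trimming_matches_oracle(self):
        values = [100.0, 101.0, 99.0, 100.5, 99.5, 120.0, 160.0, 100.2]
        config = ScoringConfig(trim_passes=3)
        agg = compute_trimmed_aggregate([(f"L{i}", v) for i, v in enumerate(values)], config)
        oracle = brute_force_trim(values, passes=3)
        assert agg.n_outliers == oracle.n_outliers
        assert agg.trimmed_mean == pytest.approx(oracle.mean)
        assert agg.trimmed_sd == pytest.approx(oracle.sd)

    @given(
        st.lists(
            st.floats(min_value=50, max_value=2000, allow_nan=False),
            min_size=3, max_size=12,
        )
    )
    def test_matches_oracle_on_random_groups(self, values):
        labs = [(f"L{i}", v) for i, v in enumerate(values)]
        oracle = brute_force_trim(values)
        if oracle is None:
            with pytest.raises(InsufficientGroupError):
                compute_trimmed_aggregate(labs)
            return
        agg = compute_trimmed_aggregate(labs)
        assert agg.n_outliers == oracle.n_outliers
        assert agg.trimmed_mean == pytest.approx(oracle.mean, rel=1e-12)
        assert agg.trimmed_sd == pytest.approx(oracle.sd, rel=1e-9, abs=1e-9)


class TestSdi:
    @pytest.mark.parametrize(
        "reported, mean, sd, expected_sdi, within",
        [
            (500.0, 500.0, 8.0, 0.0, True),
            (516.0, 500.0, 8.0, 2.0, True),   # boundary inclusive
            (524.0, 500.0, 8.0, 3.0, False),
            (484.0, 500.0, 8.0, -2.0, True),
            (476.0, 500.0, 8.0, -3.0, False),
        ],
    )
    def test_examples(self, reported, mean, sd, expected_sdi, within):
        score = compute_sdi(reported, make_agg(mean, sd))
        assert score.sdi == pytest.approx(expected_sdi)
        assert score.within_limit is within
        assert math.copysign(1, score.sdi) == math.copysign(1, score.residual) or score.sdi == 0

    def test_zero_sd_unanimous_match_passes(self):
        score = compute_sdi(500.0, make_agg(500.0, 0.0))
        assert score.sdi == 0.0
        assert score.within_limit

    def test_zero_sd_deviation_fails_with_signed_infinity(self):
        high = compute_sdi(501.0, make_agg(500.0, 0.0))
        low = compute_sdi(499.0, make_agg(500.0, 0.0))
        assert high.sdi == math.inf and not high.within_limit
        assert low.sdi == -math.inf and not low.within_limit


# ---------------------------------------------------------------------------
# Session scoring
# ---------------------------------------------------------------------------

SPECIMENS = [
    Specimen("S48-LOW", "S48", Level.LOW),
    Specimen("S48-MID", "S48", Level.MID),
]


def reported_submission(lab_id: str, specimen_id: str, cd4_abs: float) -> Submission:
    return Submission(
        lab_id=lab_id, session_id="S48", specimen_id=specimen_id,
        instrument="PIMA", status=Status.REPORTED,
        readings=(MarkerReading(marker=Marker.CD4, absolute=cd4_abs),),
    )


def unable_submission(lab_id: str, specimen_id: str) -> Submission:
    return Submission(
        lab_id=lab_id, session_id="S48", specimen_id=specimen_id,
        instrument="PIMA", status=Status.UNABLE,
        unable_reason=UnableReason.NO_REAGENTS,
    )


def session_fixture(values_low: dict[str, float], values_mid: dict[str, float], unable=()):
    subs = []
    for lab, v in values_low.items():
        subs.append(reported_submission(lab, "S48-LOW", v))
    for lab, v in values_mid.items():
        subs.append(reported_submission(lab, "S48-MID", v))
    for lab in unable:
        subs.append(unable_submission(lab, "S48-LOW"))
        subs.append(unable_submission(lab, "S48-MID"))
    return subs


class TestScoreSession:
    def test_identical_values_all_pass_with_zero_sdi(self):
        low = {f"L{i}": 150.0 for i in range(8)}
        mid = {f"L{i}": 500.0 for i in range(8)}
        result = score_session(session_fixture(low, mid), SPECIMENS)
        assert all(v.outcome is Outcome.PASS for v in result.verdicts)
        assert all(sc.sdi == 0.0 for v in result.verdicts for sc in v.scores)

    def test_single_biased_lab_is_trimmed_and_fails(self):
        # ten unbiased labs spread evenly within ±1.5 SD of 500, plus one lab
        # shifted by about +8 group SDs on the mid-specimen CD4 count
        offsets = [-9, -7, -5, -3, -1, 1, 3, 5, 7, 9]
        low = {f"L{i:02d}": 150.0 for i in range(10)}
        mid = {f"L{i:02d}": 500.0 + o for i, o in enumerate(offsets)}
        mid["BIASED"] = 550.0
        low["BIASED"] = 150.0
        result = score_session(session_fixture(low, mid), SPECIMENS)
        oracle = brute_force_trim(list(mid.values()))
        agg = next(a for a in result.aggregates if a.specimen_id == "S48-MID")
        assert agg.trimmed_mean == pytest.approx(oracle.mean)
        assert agg.trimmed_sd == pytest.approx(oracle.sd)
        assert "BIASED" in agg.outlier_lab_ids
        failing = [v.lab_id for v in result.verdicts if v.outcome is Outcome.FAIL]
        assert failing == ["BIASED"]
        biased = next(v for v in result.verdicts if v.lab_id == "BIASED")
        assert biased.failing_quantities == {("S48-MID", Marker.CD4, ValueKind.ABSOLUTE)}

    def test_unable_lab_adjudicated_unable(self):
        low = {f"L{i}": 150.0 for i in range(5)}
        mid = {f"L{i}": 500.0 for i in range(5)}
        result = score_session(session_fixture(low, mid, unable=["U1"]), SPECIMENS)
        verdict = next(v for v in result.verdicts if v.lab_id == "U1")
        assert verdict.outcome is Outcome.UNABLE
        assert verdict.unable_reason is UnableReason.NO_REAGENTS
        assert verdict.scores == ()

    def test_small_group_is_unscoreable_not_scored(self):
        low = {"L1": 150.0, "L2": 155.0}  # below min_group_n
        mid = {"L1": 500.0, "L2": 505.0, "L3": 495.0}
        result = score_session(session_fixture(low, mid), SPECIMENS)
        assert ("S48-LOW", Marker.CD4, ValueKind.ABSOLUTE) in result.unscoreable
        l3 = next(v for v in result.verdicts if v.lab_id == "L3")
        assert l3.outcome is Outcome.PASS
        l1 = next(v for v in result.verdicts if v.lab_id == "L1")
        assert "unscored" in l1.notes  # its LOW quantity could not be scored

    def test_lab_with_only_unscoreable_quantities_flagged_unscored(self):
        # three reporters but min_group_n=4: the only group is unscoreable,
        # so every lab is recorded pass/unscored rather than scored
        subs = session_fixture({"L1": 150.0, "L2": 155.0}, {})
        subs.append(reported_submission("L3", "S48-LOW", 152.0))
        config = ScoringConfig(min_group_n=4)
        result = score_session(subs, SPECIMENS, config)
        assert all(v.outcome is Outcome.PASS for v in result.verdicts)
        assert all(v.notes == "unscored" for v in result.verdicts)

    def test_retained_labs_sdi_sums_to_zero(self):
        rng = np.random.default_rng(3)
        low = {f"L{i:02d}": float(rng.normal(150, 12)) for i in range(20)}
        mid = {f"L{i:02d}": float(rng.normal(500, 30)) for i in range(20)}
        result = score_session(session_fixture(low, mid), SPECIMENS)
        for agg in result.aggregates:
            total = sum(
                sc.sdi
                for v in result.verdicts
                for sc in v.scores
                if sc.quantity == (agg.specimen_id, agg.marker, agg.value_kind)
                and sc.lab_id not in agg.outlier_lab_ids
            )
            assert total == pytest.approx(0.0, abs=1e-9)

    def test_permutation_invariance_and_determinism(self):
        rng = np.random.default_rng(5)
        low = {f"L{i:02d}": float(rng.normal(150, 12)) for i in range(12)}
        mid = {f"L{i:02d}": float(rng.normal(500, 30)) for i in range(12)}
        subs = session_fixture(low, mid)
        base = score_session(subs, SPECIMENS)
        shuffled = score_session(list(reversed(subs)), SPECIMENS)
        assert base.verdicts == shuffled.verdicts
        assert base.aggregates == shuffled.aggregates
        again = score_session(subs, SPECIMENS)
        assert again.verdicts == base.verdicts

    @given(
        st.lists(st.floats(100, 1000, allow_nan=False), min_size=4, max_size=10),
        st.floats(0.5, 4.0),
        st.floats(-200, 200),
    )
    def test_sdi_scale_and_translation_invariance(self, values, c, t):
        """Rescaling or shifting every reported value leaves every SDI unchanged."""
        labs = [(f"L{i}", v) for i, v in enumerate(values)]
        oracle = brute_force_trim(values)
        if oracle is None or oracle.sd == 0.0:
            return
        agg = compute_trimmed_aggregate(labs)
        base = [compute_sdi(v, agg, lab_id=l).sdi for l, v in labs]

        scaled = [(l, v * c) for l, v in labs]
        agg_s = compute_trimmed_aggregate(scaled)
        assert agg_s.trimmed_mean == pytest.approx(agg.trimmed_mean * c, rel=1e-9)
        assert agg_s.trimmed_sd == pytest.approx(agg.trimmed_sd * c, rel=1e-9)
        for (l, v), expect in zip(scaled, base):
            assert compute_sdi(v, agg_s, lab_id=l).sdi == pytest.approx(expect, rel=1e-6, abs=1e-9)

        shifted = [(l, v + t) for l, v in labs]
        agg_t = compute_trimmed_aggregate(shifted)
        for (l, v), expect in zip(shifted, base):
            assert compute_sdi(v, agg_t, lab_id=l).sdi == pytest.approx(expect, rel=1e-6, abs=1e-6)


class TestAdjudicate:
    def test_scores_for_unreported_quantity_raise(self):
        sub = reported_submission("L1", "S48-LOW", 150.0)
        rogue = compute_sdi(500.0, AggregateStat(
            session_id="S48", specimen_id="S48-MID", marker=Marker.CD4,
            value_kind=ValueKind.ABSOLUTE, n_initial=5, n_outliers=0,
            trimmed_mean=500.0, trimmed_sd=8.0,
        ), lab_id="L1")
        with pytest.raises(ConsistencyError):
            adjudicate_lab([sub], [rogue])

    def test_config_validation(self):
        with pytest.raises(Exception):
            ScoringConfig(min_group_n=1)
        with pytest.raises(Exception):
            ScoringConfig(outlier_k=0)
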