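"""Retrieval-dependency statistic, reference models, and their oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loopdep import (
    RetrievalDependency,
    build_tables,
    dependent_model,
    independent_model,
    observed_dependency,
    score_outcomes,
    summarize_dependency,
)
from loopdep.dependency import ContingencyTable, DependencyModelConfig, paired_tests

CLOSED_DIRECTED = [
    ("L", "O"), ("O", "L"), ("O", "P"), ("P", "O"), ("P", "L"), ("L", "P")
]
CATEGORY = {"L": "location", "P": "people", "O": "object"}


def closed_event_trials(pid, event_id, successes, confidences=None):
    """Six directed retrieval trials of one closed event as outcome rows.

    ``successes`` maps (cue, target) letters to booleans.
    """
    rows = []
    for block, (cue, tgt) in enumerate(CLOSED_DIRECTED, start=1):
        rows.append(
            {
                "participant_id": pid,
                "loop_type": "closed",
                "event_id": event_id,
                "block": block,
                "cue_id": f"{event_id}_{cue}",
                "cue_category": CATEGORY[cue],
                "target_id": f"{event_id}_{tgt}",
                "target_category": CATEGORY[tgt],
                "correct": bool(successes[(cue, tgt)]),
                "confidence": (confidences or {}).get((cue, tgt), 4),
            }
        )
    return rows


def toy_outcomes(event_patterns, pid="p0"):
    """Outcome table with one closed event per per-trial success pattern."""
    rows = []
    for i, pattern in enumerate(event_patterns):
        succ = dict(zip(CLOSED_DIRECTED, pattern))
        rows.extend(closed_event_trials(pid, f"e{i}", succ))
    return pd.DataFrame(rows)


class TestScoring:
    @pytest.mark.parametrize(
        "correct,conf,mode,expected",
        [
            (True, 4, "confidence", True),
            (True, 3, "confidence", True),
            (True, 2, "confidence", False),
            (False, 4, "confidence", False),
            (False, 4, "accuracy", False),
            (True, 1, "accuracy", True),
        ],
    )
    def test_scoring_modes(self, correct, conf, mode, expected):
        df = pd.DataFrame({"correct": [correct], "confidence": [conf]})
        got = score_outcomes(df, DependencyModelConfig(scoring_mode=mode))
        assert bool(got.iloc[0]) is expected

    def test_missing_confidence_counts_as_failure(self):
        df = pd.DataFrame({"correct": [True], "confidence": [np.nan]})
        cfg = DependencyModelConfig(scoring_mode="confidence")
        assert not score_outcomes(df, cfg).iloc[0]


class TestTables:
    def test_closed_participant_has_six_tables(self):
        out = toy_outcomes([[True] * 6, [True] * 6])
        tables = build_tables(out, participant="p0", loop_type="closed")
        assert len(tables) == 6
        keys = {(t.category, t.role) for t in tables}
        assert keys == {
            (c, r) for c in ("location", "people", "object") for r in ("cue", "target")
        }

    def test_all_correct_toy_counts(self):
        out = toy_outcomes([[True] * 6, [True] * 6])
        for t in build_tables(out, participant="p0"):
            assert t.N == 2
            assert t.counts() == (2, 0, 0, 0)

    def test_open_end_elements_contribute_no_cue_pairs(self, small_cohort):
        outcomes = small_cohort["outcomes"]
        pid = outcomes["participant_id"].iloc[0]
        schedule = outcomes[
            (outcomes.participant_id == pid) & (outcomes.loop_type == "open")
        ]
        cue_counts = schedule.groupby(["event_id", "cue_id"]).size()
        end_elements = set(
            cue_counts[cue_counts == 1].index.get_level_values("cue_id")
        )
        # every paired cue anchor must be an element cued twice (a middle one)
        from loopdep.dependency import _paired_long

        scored = schedule.copy()
        scored["success"] = scored["correct"]
        pairs = _paired_long(scored)
        cue_anchors = set(pairs[pairs.role == "cue"]["anchor_id"])
        assert not cue_anchors & end_elements

    def test_one_pair_per_event_per_table(self, small_cohort):
        outcomes = small_cohort["outcomes"]
        pid = outcomes["participant_id"].iloc[0]
        for t in build_tables(outcomes, participant=pid):
            events = [ev for ev, _, _ in t.paired_outcomes]
            assert len(events) == len(set(events))


class TestObservedDependency:
    def test_hand_enumerated_counts(self):
        t = ContingencyTable("location", "cue", "closed", "p0")
        t.paired_outcomes = (
            [("e", True, True)] * 6
            + [("f", True, False)] * 2
            + [("g", False, True)] * 1
            + [("h", False, False)] * 1
        )
        assert observed_dependency(t) == pytest.approx(0.7)

    def test_extremes(self):
        both = ContingencyTable("location", "cue", "closed", "p0")
        both.paired_outcomes = [("a", True, True), ("b", False, False)]
        assert observed_dependency(both) == 1.0
        neither = ContingencyTable("location", "cue", "closed", "p0")
        neither.paired_outcomes = [("a", True, False)] * 5 + [("b", False, True)] * 5
        assert observed_dependency(neither) == 0.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            observed_dependency(ContingencyTable("location", "cue", "closed", "p0"))


class TestIndependentModel:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(0.5, 0.5, 0.5), (1.0, 0.3, 0.3), (0.9, 0.8, 0.74)],
    )
    def test_closed_form(self, p1, p2, expected):
        t = ContingencyTable("location", "cue", "closed", "p0")
        t.paired_outcomes = [("a", True, True)]
        assert independent_model(t, (p1, p2)) == pytest.approx(expected)


def brute_force_dependent(a_i, p1, p2, g, a_bar):
    """Independent re-implementation of the dependent model, per event."""
    strength = lambda a: max(0.0, (a - g) / (1 - g))
    m_bar = strength(a_bar)
    total = 0.0
    for a in a_i:
        e = strength(a) / m_bar if m_bar > 0 else 1.0
        ps = [g + (1 - g) * min(1.0, e * strength(p)) for p in (p1, p2)]
        total += ps[0] * ps[1] + (1 - ps[0]) * (1 - ps[1])
    return total / len(a_i)


class TestDependentModel:
    def _table(self, events):
        t = ContingencyTable("location", "cue", "closed", "p0")
        t.paired_outcomes = [(e, True, True) for e in events]
        return t

    def test_reduces_to_independent_when_factors_equal(self):
        t = self._table(["a", "b", "c"])
        acc = {"a": 0.8, "b": 0.8, "c": 0.8}
        marg = (0.7, 0.65)
        dep = dependent_model(t, acc, marg, g=0.25)
        ind = independent_model(t, marg)
        assert dep == pytest.approx(ind, abs=1e-15)

    def test_event_at_guessing_floor_predicts_guessing(self):
        g = 0.25
        t = self._table(["a"])
        dep = dependent_model(t, {"a": g}, (0.9, 0.8), g=g, grand_mean=0.7)
        assert dep == pytest.approx(g * g + (1 - g) * (1 - g))

    def test_matches_brute_force_oracle_on_heterogeneous_events(self):
        a_i = {"a": 1.0, "b": 0.5, "c": 0.25, "d": 0.9}
        t = self._table(list(a_i))
        marg = (0.85, 0.6)
        got = dependent_model(t, a_i, marg, g=0.25)
        want = brute_force_dependent(
            list(a_i.values()), *marg, g=0.25, a_bar=np.mean(list(a_i.values()))
        )
        assert got == pytest.approx(want, abs=1e-12)


class TestSummaries:
    def test_cohort_path_matches_per_table_functions(self, small_cohort):
        """The vectorized summary equals composing the per-table operations."""
        outcomes = small_cohort["outcomes"]
        cfg = DependencyModelConfig()
        summary = summarize_dependency(outcomes, cfg)
        pid = outcomes["participant_id"].iloc[0]
        for loop in ("closed", "open"):
            tables = build_tables(outcomes, participant=pid, loop_type=loop, config=cfg)
            scored = outcomes[outcomes.participant_id == pid].copy()
            scored["success"] = score_outcomes(scored, cfg)
            ev_acc = scored.groupby("event_id")["success"].mean().to_dict()
            loop_events = scored[scored.loop_type == loop]["event_id"].unique()
            a_bar = np.mean([ev_acc[e] for e in loop_events])
            d_obs = np.mean([observed_dependency(t) for t in tables])
            d_ind = np.mean([independent_model(t) for t in tables])
            d_dep = np.mean(
                [
                    dependent_model(t, ev_acc, g=cfg.g, grand_mean=a_bar)
                    for t in tables
                ]
            )
            row = summary[
                (summary.participant_id == pid) & (summary.loop_type == loop)
            ].iloc[0]
            assert row.D_obs == pytest.approx(d_obs, abs=1e-12)
            assert row.D_ind == pytest.approx(d_ind, abs=1e-12)
            assert row.D_dep == pytest.approx(d_dep, abs=1e-12)

    def test_all_correct_participant_is_at_ceiling(self):
        out = toy_outcomes([[True] * 6] * 4)
        summary = summarize_dependency(out)
        row = summary.iloc[0]
        assert row.D_obs == 1.0
        assert row.D_ind == 1.0
        assert row.evidence == 0.0

    def test_identical_evidence_gives_null_paired_test(self):
        frames = []
        for pid in ("p0", "p1", "p2"):
            closed = toy_outcomes(
                [[True] * 6, [False] * 6, [True] * 6, [True, False] * 3], pid=pid
            )
            open_ = closed.copy()
            open_["loop_type"] = "open"
            open_["event_id"] = open_["event_id"] + "_o"
            frames.append(pd.concat([closed, open_]))
        out = pd.concat(frames, ignore_index=True)
        tests = paired_tests(summarize_dependency(out))
        res = tests["evidence_closed_vs_open"]
        assert res["t"] == 0.0
        assert res["p"] == 1.0
        assert res["zero_variance"]

    def test_estimator_interface(self, small_cohort):
        est = RetrievalDependency(mode="confidence")
        est.fit(small_cohort["outcomes"])
        assert {"D_obs", "D_ind", "D_dep", "evidence"} <= set(est.summary_.columns)
        assert "evidence_closed_vs_open" in est.tests_
        assert est.get_params()["mode"] == "confidence"

    def test_estimator_rejects_missing_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            RetrievalDependency().fit(pd.DataFrame({"correct": [True]}))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.lists(st.booleans(), min_size=6, max_size=6), min_size=2, max_size=6))
def test_dependency_quantities_bounded(patterns):
    """All dependency quantities lie in [0,1]; evidence in [-1,1]."""
    out = toy_outcomes(patterns)
    summary = summarize_dependency(out)
    if summary.empty:
        return
    assert summary[["D_obs", "D_ind", "D_dep"]].ge(-1e-12).all().all()
    assert summary[["D_obs", "D_ind", "D_dep"]].le(1 + 1e-12).all().all()
    assert summary["evidence"].between(-1, 1).all()
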