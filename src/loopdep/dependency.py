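"""Retrieval dependency: contingency tables and independent/dependent models.

Two retrieval trials that probe different associations of the same event but
share an element (the same cue element used twice, or the same target element
reached from two different cues) form a paired outcome.  Pooling pairs across
events gives a 2x2 contingency table per (element category, shared role);
``observed dependency`` is the fraction of events where both trials succeed
or both fail.

Because the observed measure scales with accuracy it is compared against two
reference models.  The independent model predicts dependency from the two
trial types' marginal success rates alone.  The dependent model additionally
assumes a common per-event memory strength: each event's accuracy across its
retrieval trials is converted to a guessing-corrected strength, expressed as
an "episodic factor" relative to the average event, and used to scale the
marginal (guessing-corrected) success probabilities event by event.

Scoring can classify trials as correct vs incorrect (``accuracy`` mode) or
as high-confidence-correct vs everything else (``confidence`` mode), which
unmasks dependency differences when accuracy is at ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

ROLES = ("cue", "target")


@dataclass
class DependencyModelConfig:
    """Scoring mode and model constants for the dependency analysis."""

    scoring_mode: str = "accuracy"  # "accuracy" | "confidence"
    confidence_high_threshold: int = 3
    g: float = 0.25  # guessing rate of the 4AFC test
    episodic_factor_source: str = "all_trials"  # or "exclude_table_trials"

    def __post_init__(self):
        if self.scoring_mode not in ("accuracy", "confidence"):
            raise ValueError(f"unknown scoring_mode {self.scoring_mode!r}")
        if self.confidence_high_threshold not in (2, 3, 4):
            raise ValueError("confidence_high_threshold must be 2, 3 or 4")
        if not 0.0 < self.g < 1.0:
            raise ValueError("g must lie in (0, 1)")
        if self.episodic_factor_source not in ("all_trials", "exclude_table_trials"):
            raise ValueError(
                f"unknown episodic_factor_source {self.episodic_factor_source!r}"
            )


@dataclass
class ContingencyTable:
    """Paired outcomes across events for one (category, role) anchor."""

    category: str
    role: str
    loop_type: str
    participant_id: str
    paired_outcomes: list[tuple] = field(default_factory=list)
    # each entry: (event_id, outcome_1: bool, outcome_2: bool)

    @property
    def N(self) -> int:
        return len(self.paired_outcomes)

    def counts(self) -> tuple[int, int, int, int]:
        n11 = n10 = n01 = n00 = 0
        for _, o1, o2 in self.paired_outcomes:
            if o1 and o2:
                n11 += 1
            elif o1 and not o2:
                n10 += 1
            elif o2 and not o1:
                n01 += 1
            else:
                n00 += 1
        return n11, n10, n01, n00

    def marginals(self) -> tuple[float, float]:
        o1 = np.array([p[1] for p in self.paired_outcomes], dtype=float)
        o2 = np.array([p[2] for p in self.paired_outcomes], dtype=float)
        return float(o1.mean()), float(o2.mean())


def score_outcomes(
    outcomes: pd.DataFrame, config: DependencyModelConfig | None = None
) -> pd.Series:
    """Boolean success per trial under the active scoring mode.

    Accuracy mode: success = correct.  Confidence mode: success = correct
    AND confidence >= threshold; a trial without a recorded confidence (no
    response) counts as failure.
    """
    config = config or DependencyModelConfig()
    correct = outcomes["correct"].fillna(False).astype(bool)
    if config.scoring_mode == "accuracy":
        return correct
    if "confidence" not in outcomes.columns:
        raise ValueError("confidence mode requires a 'confidence' column")
    conf = pd.to_numeric(outcomes["confidence"], errors="coerce")
    high = conf >= config.confidence_high_threshold
    return correct & high.fillna(False)


def _paired_long(scored: pd.DataFrame) -> pd.DataFrame:
    """One row per (participant, loop, category, role, event) outcome pair.

    For each event and role, trials sharing an anchor element are paired;
    the two trials of a pair are ordered by the non-shared element's category
    then id, then block, so pairing is deterministic.  If several anchors of
    the same merged category qualify within one event (possible for open
    chains holding both an object and an animal in middle position), the
    anchor with the lexicographically smallest id is kept so that each event
    contributes at most one pair per table.
    """
    views = []
    for role, anchor, anchor_cat, other, other_cat in (
        ("cue", "cue_id", "cue_category", "target_id", "target_category"),
        ("target", "target_id", "target_category", "cue_id", "cue_category"),
    ):
        v = scored[
            ["participant_id", "loop_type", "event_id", "block", "success"]
        ].copy()
        v["role"] = role
        v["anchor_id"] = scored[anchor]
        v["category"] = scored[anchor_cat]
        v["other_cat"] = scored[other_cat]
        v["other_id"] = scored[other]
        views.append(v)
    long = pd.concat(views, ignore_index=True)
    long = long.sort_values(
        ["participant_id", "event_id", "role", "anchor_id", "other_cat", "other_id", "block"],
        kind="mergesort",
    )
    grp = ["participant_id", "event_id", "role", "anchor_id"]
    sizes = long.groupby(grp, sort=False)["success"].transform("size")
    long = long[sizes >= 2]
    long["pos"] = long.groupby(grp, sort=False).cumcount()
    long = long[long["pos"] < 2]
    pairs = long.pivot_table(
        index=["participant_id", "loop_type", "event_id", "role", "category", "anchor_id"],
        columns="pos",
        values="success",
        aggfunc="first",
    ).reset_index()
    pairs = pairs.rename(columns={0: "o1", 1: "o2"})
    # one pair per event per (category, role) table
    pairs = pairs.sort_values(
        ["participant_id", "loop_type", "category", "role", "event_id", "anchor_id"],
        kind="mergesort",
    )
    pairs = pairs.drop_duplicates(
        subset=["participant_id", "loop_type", "category", "role", "event_id"],
        keep="first",
    )
    pairs["o1"] = pairs["o1"].astype(bool)
    pairs["o2"] = pairs["o2"].astype(bool)
    return pairs.reset_index(drop=True)


def build_tables(
    outcomes: pd.DataFrame,
    participant: str | None = None,
    loop_type: str | None = None,
    config: DependencyModelConfig | None = None,
) -> list[ContingencyTable]:
    """Contingency tables for one participant (optionally one loop type).

    Closed-loop trials yield 6 tables (3 categories x {cue, target}); open
    chains yield pairs only where an element serves the same role twice
    (middle elements), so end elements contribute no cue-based pairs.
    Events with fewer than two qualifying trials are omitted; empty tables
    are dropped with a warning.
    """
    config = config or DependencyModelConfig()
    df = outcomes
    if participant is not None:
        df = df[df["participant_id"] == participant]
    if loop_type is not None:
        df = df[df["loop_type"] == loop_type]
    if df.empty:
        warnings.warn("no trials matched; no contingency tables built")
        return []
    scored = df.copy()
    scored["success"] = score_outcomes(scored, config)
    pairs = _paired_long(scored)
    tables = []
    for (pid, lp, cat, role), sub in pairs.groupby(
        ["participant_id", "loop_type", "category", "role"], sort=True
    ):
        tables.append(
            ContingencyTable(
                category=cat,
                role=role,
                loop_type=lp,
                participant_id=pid,
                paired_outcomes=[
                    (r.event_id, bool(r.o1), bool(r.o2)) for r in sub.itertuples()
                ],
            )
        )
    return tables


def observed_dependency(table: ContingencyTable) -> float:
    """Proportion of events where both paired trials succeed or both fail."""
    if table.N == 0:
        raise ValueError("observed dependency undefined for an empty table")
    n11, n10, n01, n00 = table.counts()
    return (n11 + n00) / table.N


def independent_model(table: ContingencyTable, marginals=None) -> float:
    """Expected dependency if the two trial types are independent.

    With marginal success rates P1, P2 this is ``P1*P2 + (1-P1)*(1-P2)``.
    """
    if table.N == 0:
        raise ValueError("independent model undefined for an empty table")
    p1, p2 = marginals if marginals is not None else table.marginals()
    return p1 * p2 + (1 - p1) * (1 - p2)


def _episodic_strength(a: np.ndarray, g: float) -> np.ndarray:
    """Guessing-corrected memory strength: max(0, (A - g) / (1 - g))."""
    return np.maximum(0.0, (np.asarray(a, dtype=float) - g) / (1.0 - g))


def dependent_model(
    table: ContingencyTable,
    per_event_accuracy: dict,
    marginals=None,
    g: float = 0.25,
    grand_mean: float | None = None,
) -> float:
    """Expected dependency under a shared per-event memory strength.

    Each event's accuracy ``A_i`` (over its retrieval trials) is converted
    to a guessing-corrected strength ``m_i``; the episodic factor ``E_i =
    m_i / m_bar`` scales the guessing-corrected marginal success rate of
    each trial type before re-adding the guessing floor:

        p_ti = g + (1 - g) * min(1, E_i * max(0, (P_t - g) / (1 - g)))

    The table's expected dependency is the mean over events of
    ``p_1i * p_2i + (1 - p_1i) * (1 - p_2i)``.  ``grand_mean`` defaults to
    the mean of ``per_event_accuracy`` over the events supplied (the events
    of the loop condition).
    """
    if table.N == 0:
        raise ValueError("dependent model undefined for an empty table")
    a_i = np.array([per_event_accuracy[ev] for ev, _, _ in table.paired_outcomes])
    a_bar = (
        grand_mean
        if grand_mean is not None
        else float(np.mean(list(per_event_accuracy.values())))
    )
    m_i = _episodic_strength(a_i, g)
    m_bar = float(_episodic_strength(a_bar, g))
    e_i = m_i / m_bar if m_bar > 0 else np.ones_like(m_i)
    p1, p2 = marginals if marginals is not None else table.marginals()
    out = 0.0
    for ei in e_i:
        p_ti = [
            g + (1 - g) * min(1.0, ei * max(0.0, (pt - g) / (1 - g)))
            for pt in (p1, p2)
        ]
        out += p_ti[0] * p_ti[1] + (1 - p_ti[0]) * (1 - p_ti[1])
    return out / len(e_i)


def _summarize_cohort(
    outcomes: pd.DataFrame, config: DependencyModelConfig
) -> pd.DataFrame:
    """Vectorized per-participant, per-loop dependency summary."""
    scored = outcomes.copy()
    scored["success"] = score_outcomes(scored, config)
    pairs = _paired_long(scored)
    if pairs.empty:
        return pd.DataFrame(
            columns=["participant_id", "loop_type", "D_obs", "D_ind", "D_dep", "evidence"]
        )

    # per-event accuracy (episodic factor source) and per-loop grand mean
    ev_acc = (
        scored.groupby(["participant_id", "event_id"], sort=False)["success"]
        .mean()
        .rename("A_i")
    )
    pairs = pairs.merge(ev_acc, left_on=["participant_id", "event_id"], right_index=True)
    if config.episodic_factor_source == "exclude_table_trials":
        n_ev = (
            scored.groupby(["participant_id", "event_id"], sort=False)["success"]
            .size()
            .rename("n_ev")
        )
        pairs = pairs.merge(
            n_ev, left_on=["participant_id", "event_id"], right_index=True
        )
        tot = pairs["A_i"] * pairs["n_ev"]
        pairs["A_i"] = (tot - pairs["o1"] - pairs["o2"]) / (pairs["n_ev"] - 2)
    loop_acc = (
        scored.groupby(["participant_id", "loop_type", "event_id"], sort=False)["success"]
        .mean()
        .groupby(["participant_id", "loop_type"])
        .mean()
        .rename("A_bar")
    )
    pairs = pairs.merge(
        loop_acc, left_on=["participant_id", "loop_type"], right_index=True
    )

    tkey = ["participant_id", "loop_type", "category", "role"]
    grp = pairs.groupby(tkey, sort=False)
    pairs["P1"] = grp["o1"].transform("mean")
    pairs["P2"] = grp["o2"].transform("mean")

    g = config.g
    m_i = _episodic_strength(pairs["A_i"].to_numpy(), g)
    m_bar = _episodic_strength(pairs["A_bar"].to_numpy(), g)
    e_i = np.where(m_bar > 0, m_i / np.where(m_bar > 0, m_bar, 1.0), 1.0)
    q1 = _episodic_strength(pairs["P1"].to_numpy(), g)
    q2 = _episodic_strength(pairs["P2"].to_numpy(), g)
    p1 = g + (1 - g) * np.minimum(1.0, e_i * q1)
    p2 = g + (1 - g) * np.minimum(1.0, e_i * q2)
    pairs["dep_term"] = p1 * p2 + (1 - p1) * (1 - p2)
    o1 = pairs["o1"].to_numpy()
    o2 = pairs["o2"].to_numpy()
    pairs["match"] = (o1 == o2).astype(float)
    pairs["ind_term"] = pairs["P1"] * pairs["P2"] + (1 - pairs["P1"]) * (1 - pairs["P2"])

    per_table = pairs.groupby(tkey, sort=True).agg(
        D_obs=("match", "mean"),
        D_ind=("ind_term", "mean"),
        D_dep=("dep_term", "mean"),
    )
    summary = (
        per_table.groupby(["participant_id", "loop_type"], sort=True)
        .mean()
        .reset_index()
    )
    summary["evidence"] = summary["D_obs"] - summary["D_ind"]
    return summary


def summarize_dependency(
    outcomes: pd.DataFrame, config: DependencyModelConfig | None = None
) -> pd.DataFrame:
    """Per-participant, per-loop dependency summary.

    Returns one row per (participant, loop_type) with columns ``D_obs``,
    ``D_ind``, ``D_dep`` (means across that participant's contingency
    tables) and ``evidence = D_obs - D_ind``.
    """
    return _summarize_cohort(outcomes, config or DependencyModelConfig())


def _paired_t(a: np.ndarray, b: np.ndarray) -> dict:
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if len(diff) < 2:
        raise ValueError("paired test requires at least 2 participants")
    if np.allclose(diff.std(ddof=1), 0.0):
        # zero-variance difference: t undefined unless the mean is also 0
        if np.allclose(diff.mean(), 0.0):
            return {"t": 0.0, "df": len(diff) - 1, "p": 1.0, "zero_variance": True}
        return {
            "t": np.nan,
            "df": len(diff) - 1,
            "p": np.nan,
            "zero_variance": True,
        }
    res = stats.ttest_rel(a, b)
    return {
        "t": float(res.statistic),
        "df": len(diff) - 1,
        "p": float(res.pvalue),
        "zero_variance": False,
    }


def paired_tests(summary: pd.DataFrame) -> dict:
    """Group-level paired t-tests on the dependency summaries.

    Compares dependency evidence (observed minus independent-model) between
    closed and open loops, and observed dependency against the dependent
    model within each loop condition.  Two-tailed p values throughout.
    """
    wide = summary.pivot(index="participant_id", columns="loop_type")
    out = {}
    if {"closed", "open"} <= set(summary["loop_type"].unique()):
        ev = wide["evidence"].dropna()
        out["evidence_closed_vs_open"] = _paired_t(
            ev["closed"].to_numpy(), ev["open"].to_numpy()
        )
    for lp in sorted(summary["loop_type"].unique()):
        sub = summary[summary["loop_type"] == lp]
        out[f"obs_vs_dep_{lp}"] = _paired_t(
            sub["D_obs"].to_numpy(), sub["D_dep"].to_numpy()
        )
        out[f"obs_vs_ind_{lp}"] = _paired_t(
            sub["D_obs"].to_numpy(), sub["D_ind"].to_numpy()
        )
    return out


class RetrievalDependency(BaseEstimator):
    """Retrieval-dependency analysis as a scikit-learn style estimator.

    Parameters
    ----------
    mode : {"accuracy", "confidence"}
        Trial scoring mode.
    confidence_high_threshold : int
        Minimum confidence rating counting as "high" in confidence mode.
    g : float
        Guessing rate of the forced-choice test (0.25 for 4AFC).
    episodic_factor_source : {"all_trials", "exclude_table_trials"}
        Which trials define the per-event accuracy entering the episodic
        factor of the dependent model.

    Attributes
    ----------
    summary_ : DataFrame
        One row per (participant, loop) with D_obs, D_ind, D_dep, evidence.
    tests_ : dict
        Paired t-tests between loop conditions and against the models.
    """

    def __init__(
        self,
        mode: str = "accuracy",
        confidence_high_threshold: int = 3,
        g: float = 0.25,
        episodic_factor_source: str = "all_trials",
    ):
        self.mode = mode
        self.confidence_high_threshold = confidence_high_threshold
        self.g = g
        self.episodic_factor_source = episodic_factor_source

    def _config(self) -> DependencyModelConfig:
        return DependencyModelConfig(
            scoring_mode=self.mode,
            confidence_high_threshold=self.confidence_high_threshold,
            g=self.g,
            episodic_factor_source=self.episodic_factor_source,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "RetrievalDependency":
        """Fit on a trial-outcome table (one row per retrieval trial)."""
        required = {"participant_id", "loop_type", "event_id", "cue_id", "target_id", "correct"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"outcome table missing columns: {sorted(missing)}")
        config = self._config()
        self.summary_ = _summarize_cohort(X, config)
        n_participants = self.summary_["participant_id"].nunique()
        if n_participants >= 2:
            self.tests_ = paired_tests(self.summary_)
        else:
            warnings.warn("fewer than 2 participants; group tests skipped")
            self.tests_ = {}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Summaries for new outcomes under the fitted configuration."""
        return _summarize_cohort(X, self._config())
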