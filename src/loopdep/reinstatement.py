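"""Cue/target/nontarget cortical reinstatement scores from ROI betas.

Each analysis category has one category-selective cortical ROI (by default
parahippocampal cortex for locations, medial parietal cortex for people,
lateral occipital cortex for objects).  Condition parameter estimates are
z-standardized within each (participant, ROI) cell and then averaged by the
function the ROI's category serves in each condition: cue (category first in
the ordered pair), target (category second), or nontarget (category absent).
Averaging the three ROIs gives one cue, target and nontarget reinstatement
score per participant; the nontarget score operationalizes holistic
recollection.  With loop-split beta tables the same scores are computed per
loop condition and the closed-minus-open differences are tested against
zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

DEFAULT_ROI_MAP = {"PHC": "location", "MPC": "people", "LOC": "object"}

FUNCTIONS = ("cue", "target", "nontarget")


def zscore_within_roi(beta_table: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize betas across conditions within each (participant, ROI).

    Uses the population (ddof=0) standard deviation, so a two-condition cell
    maps to scores of magnitude 1/sqrt(2) each.  A zero-variance cell raises
    an error naming the offending (participant, ROI).
    """
    df = beta_table.copy()
    out = np.empty(len(df))
    for (pid, roi), idx in df.groupby(["participant_id", "roi"]).groups.items():
        vals = df.loc[idx, "beta"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"({pid}, {roi}): need >= 2 conditions to z-score")
        sd = vals.std()
        if sd == 0:
            raise ValueError(f"({pid}, {roi}): zero variance across conditions")
        out[df.index.get_indexer(idx)] = (vals - vals.mean()) / sd
    df = df.reset_index(drop=True)
    df["beta"] = out
    return df


def _element_function(condition: str, category: str) -> str:
    c1, _, c2 = condition.partition("-")
    if category == c1:
        return "cue"
    if category == c2:
        return "target"
    return "nontarget"


def _scores_from(std_table: pd.DataFrame, roi_map: dict, extra_group=()) -> pd.DataFrame:
    df = std_table.copy()
    unmapped = set(df["roi"].unique()) - set(roi_map)
    if unmapped:
        raise ValueError(f"unmapped ROI(s): {sorted(unmapped)}")
    df["function"] = [
        _element_function(cond, roi_map[roi])
        for cond, roi in zip(df["condition"], df["roi"])
    ]
    group = ["participant_id", *extra_group, "function"]
    # mean per (participant, roi, function) first, then across ROIs, so each
    # ROI contributes equally even if condition counts differ
    per_roi = df.groupby([*group, "roi"], sort=True)["beta"].mean()
    scores = per_roi.groupby(group, sort=True).mean().rename("score").reset_index()
    return scores


def element_function_scores(
    std_table: pd.DataFrame, roi_map: dict | None = None
) -> pd.DataFrame:
    """Per-participant cue/target/nontarget reinstatement scores.

    Input is a z-standardized long table (participant_id, roi, condition,
    beta) whose conditions are ordered category pairs like
    ``"location-object"``.  Returns a wide DataFrame indexed by participant
    with columns cue, target, nontarget.
    """
    scores = _scores_from(std_table, roi_map or DEFAULT_ROI_MAP)
    wide = scores.pivot(index="participant_id", columns="function", values="score")
    return wide.reindex(columns=list(FUNCTIONS))


def loop_split_scores(
    std_table: pd.DataFrame, roi_map: dict | None = None
) -> dict[str, pd.DataFrame]:
    """Reinstatement scores per loop condition and closed-open differences.

    Input must carry a ``loop_type`` column with both conditions present for
    every (participant, roi, condition) cell.
    """
    if "loop_type" not in std_table.columns:
        raise ValueError("loop-split scores require a 'loop_type' column")
    cell = std_table.groupby(["participant_id", "roi", "condition"])["loop_type"]
    missing = cell.nunique() < 2
    if missing.any():
        bad = missing[missing].index[0]
        raise ValueError(f"missing loop condition for cell {bad}")
    scores = _scores_from(std_table, roi_map or DEFAULT_ROI_MAP, ("loop_type",))
    per_loop = scores.pivot_table(
        index=["participant_id", "function"], columns="loop_type", values="score"
    ).reset_index()
    per_loop["difference"] = per_loop["closed"] - per_loop["open"]
    diffs = per_loop.pivot(
        index="participant_id", columns="function", values="difference"
    ).reindex(columns=list(FUNCTIONS))
    return {"per_loop": per_loop, "differences": diffs}


def one_sample_tests(differences: pd.DataFrame) -> dict:
    """One-sample t-tests of closed-open differences against zero."""
    if len(differences) < 2:
        raise ValueError("group test requires at least 2 participants")
    out = {}
    for fn in differences.columns:
        vals = differences[fn].dropna().to_numpy(dtype=float)
        if np.allclose(vals.std(ddof=1), 0.0) and np.allclose(vals.mean(), 0.0):
            out[fn] = {"mean": 0.0, "t": 0.0, "df": len(vals) - 1, "p": 1.0}
            continue
        res = stats.ttest_1samp(vals, 0.0)
        out[fn] = {
            "mean": float(vals.mean()),
            "t": float(res.statistic),
            "df": len(vals) - 1,
            "p": float(res.pvalue),
        }
    return out


def _rm_anova_f(data: np.ndarray) -> tuple[float, int, int, float]:
    """One-way repeated-measures F for an (n_subjects, k_conditions) array."""
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1, keepdims=True)
    cond_means = data.mean(axis=0, keepdims=True)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    resid = data - subj_means - cond_means + grand
    ss_err = (resid**2).sum()
    df1, df2 = k - 1, (n - 1) * (k - 1)
    scale = max(1.0, (data**2).sum())
    if ss_cond < 1e-12 * scale:
        f = 0.0
    elif ss_err < 1e-12 * scale:
        f = np.inf
    else:
        f = (ss_cond / df1) / (ss_err / df2)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), df1, df2, p


def anova_element_function(scores: pd.DataFrame, mode: str = "repeated") -> dict:
    """ANOVA of reinstatement scores across element functions.

    ``repeated`` blocks on participant (one-way repeated measures);
    ``oneway`` treats the three functions as independent groups.  ``scores``
    is the wide per-participant table from :func:`element_function_scores`.
    """
    data = scores[list(FUNCTIONS)].dropna()
    if data.shape[0] < 3 or data.shape[1] < 3:
        raise ValueError("ANOVA requires >= 3 participants and all 3 functions")
    if mode == "repeated":
        f, df1, df2, p = _rm_anova_f(data.to_numpy(dtype=float))
    elif mode == "oneway":
        res = stats.f_oneway(*(data[fn].to_numpy() for fn in FUNCTIONS))
        f, p = float(res.statistic), float(res.pvalue)
        df1, df2 = 2, data.size - 3
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"F": f, "df1": df1, "df2": df2, "p": p, "mode": mode}


class ReinstatementScorer(BaseEstimator):
    """Reinstatement scoring as a scikit-learn style estimator.

    Parameters
    ----------
    roi_map : dict or None
        ROI name -> element category; defaults to PHC/MPC/LOC.
    split_loops : bool
        Also compute per-loop scores and closed-open differences (requires a
        ``loop_type`` column in the beta table).
    anova_mode : {"repeated", "oneway"}

    Attributes
    ----------
    scores_ : DataFrame, per-participant cue/target/nontarget scores
    anova_ : dict, element-function ANOVA
    differences_ : DataFrame, closed-open differences (if split_loops)
    tests_ : dict, one-sample t-tests on the differences (if split_loops)
    """

    def __init__(self, roi_map=None, split_loops: bool = False, anova_mode: str = "repeated"):
        self.roi_map = roi_map
        self.split_loops = split_loops
        self.anova_mode = anova_mode

    def fit(self, X: pd.DataFrame, y=None) -> "ReinstatementScorer":
        roi_map = self.roi_map or DEFAULT_ROI_MAP
        std = zscore_within_roi(X)
        self.standardized_ = std
        self.scores_ = element_function_scores(std, roi_map)
        if self.scores_["cue"].notna().sum() >= 3:
            self.anova_ = anova_element_function(self.scores_, self.anova_mode)
        else:
            self.anova_ = None
        if self.split_loops:
            split = loop_split_scores(std, roi_map)
            self.per_loop_ = split["per_loop"]
            self.differences_ = split["differences"]
            self.tests_ = (
                one_sample_tests(self.differences_)
                if len(self.differences_) >= 2
                else {}
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        roi_map = self.roi_map or DEFAULT_ROI_MAP
        return element_function_scores(zscore_within_roi(X), roi_map)
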