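"""Synthetic cohort generation: behavioral outcomes and neural scores.

The behavioral generator is a latent-trace Bernoulli mixture.  For a
closed-loop event a single event-level "holistic" trace forms with
probability ``p_trace_closed``; when present it governs all six retrieval
trials of that event, which induces dependency between different
associations of the same event.  For open-loop events traces form per
association (``p_trace_pair``), so successes on different associations are
independent.  A trial governed by a present trace is answered correctly with
probability ``p_hit_given_trace``; otherwise the response is a guess,
correct with probability ``g`` (0.25 under 4-alternative forced choice).

The neural generator couples each participant's realized holistic-trace
fraction to a latent nontarget-reinstatement score, and the score to
hippocampal-subfield (CA3, DG) closed-minus-open activity differences, with
Gaussian noise throughout.  ROI parameter estimates are constructed so that
target > cue > nontarget on average and the closed-loop nontarget condition
is elevated in proportion to the participant's score.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CATEGORIES, DesignConfig, build_event_set, build_retrieval_schedule

#: the six ordered cue-target category pairs used as GLM conditions
CONDITION_PAIRS = tuple(
    f"{a}-{b}" for a in CATEGORIES for b in CATEGORIES if a != b
)

SUBFIELDS = ("CA3_ant_R", "DG_ant_R")


@dataclass
class GenerativeConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a high-performing cohort (~87% overall accuracy) with a
    holistic component confined to closed loops, and subfield couplings that
    yield a clearly stronger CA3 than DG association with nontarget
    reinstatement.
    """

    n_participants: int = 30
    # behavior
    p_trace_closed: float = 0.87
    p_trace_pair: float = 0.83
    p_trace_pair_closed: float = 0.0  # within-closed pairwise traces, off by default
    p_hit_given_trace: float = 0.98
    g: float = 0.25
    p_highconf_trace: float = 0.92
    p_highconf_guess: float = 0.15
    independent_trials: bool = False  # fresh trace per trial: independence generator
    # neural
    alpha_reinstate: float = 2.0
    nontarget_gain: float = 0.25
    beta_ca3: float = 0.75
    beta_dg: float = 0.3
    sigma_neural: float = 0.16
    sigma_beta: float = 0.05
    mu_cue: float = 0.6
    mu_target: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        for name in (
            "p_trace_closed",
            "p_trace_pair",
            "p_trace_pair_closed",
            "p_hit_given_trace",
            "p_highconf_trace",
            "p_highconf_guess",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.g < 1.0:
            raise ValueError("g must lie in (0, 1)")
        if self.sigma_neural <= 0 or self.sigma_beta <= 0:
            raise ValueError("noise scales must be positive")

    @classmethod
    def strong_effect(cls, n_participants: int = 30) -> "GenerativeConfig":
        """Preset with a large, easily detectable holistic effect.

        Behavioral accuracy sits well below ceiling so that dependency is
        measurable, and the CA3 coupling dominates the DG coupling relative
        to the neural noise.
        """
        return cls(
            n_participants=n_participants,
            p_trace_closed=0.8,
            p_trace_pair=0.8,
            p_hit_given_trace=0.95,
            p_highconf_trace=0.95,
            p_highconf_guess=0.05,
            nontarget_gain=0.5,
            beta_ca3=1.0,
            beta_dg=0.1,
            sigma_neural=0.06,
            sigma_beta=0.08,
        )

    def replace(self, **kwargs) -> "GenerativeConfig":
        return dataclasses.replace(self, **kwargs)


def simulate_behavior(
    schedule: pd.DataFrame,
    config: GenerativeConfig,
    rng=None,
    participant_id: str = "p00",
) -> tuple[pd.DataFrame, dict]:
    """Simulate one participant's retrieval outcomes for a schedule.

    Returns the schedule with ``participant_id``, ``correct``, ``confidence``
    and ``rt`` columns appended, plus a dict of generative latents (the
    realized holistic-trace fraction among closed events, and the realized
    per-association trace fraction among open events).
    """
    rng = np.random.default_rng(rng)
    n = len(schedule)
    loop = schedule["loop_type"].to_numpy()
    closed = loop == "closed"

    ev_codes, ev_uniq = pd.factorize(schedule["event_id"], sort=True)
    ev_closed = np.zeros(len(ev_uniq), dtype=bool)
    ev_closed[ev_codes[closed]] = True

    pair_key = [
        (e, *sorted((c, t)))
        for e, c, t in zip(
            schedule["event_id"], schedule["cue_id"], schedule["target_id"]
        )
    ]
    as_codes, as_uniq = pd.factorize(pd.Series(pair_key), sort=True)
    as_closed = np.zeros(len(as_uniq), dtype=bool)
    as_closed[as_codes[closed]] = True

    if config.independent_trials:
        p_trial = np.where(closed, config.p_trace_closed, config.p_trace_pair)
        trace = rng.random(n) < p_trial
        trace_frac_closed = float(trace[closed].mean()) if closed.any() else np.nan
        trace_frac_open = float(trace[~closed].mean()) if (~closed).any() else np.nan
    else:
        event_trace = rng.random(len(ev_uniq)) < config.p_trace_closed
        p_assoc = np.where(as_closed, config.p_trace_pair_closed, config.p_trace_pair)
        assoc_trace = rng.random(len(as_uniq)) < p_assoc
        trace = np.where(
            closed,
            event_trace[ev_codes] | assoc_trace[as_codes],
            assoc_trace[as_codes],
        )
        trace_frac_closed = (
            float(event_trace[ev_closed].mean()) if ev_closed.any() else np.nan
        )
        trace_frac_open = (
            float(assoc_trace[~as_closed].mean()) if (~as_closed).any() else np.nan
        )

    p_correct = np.where(trace, config.p_hit_given_trace, config.g)
    correct = rng.random(n) < p_correct
    p_high = np.where(trace, config.p_highconf_trace, config.p_highconf_guess)
    high = rng.random(n) < p_high
    confidence = np.where(high, rng.integers(3, 5, n), rng.integers(1, 3, n))
    max_rt = float(schedule["duration"].max()) if n else 6.0
    rt = np.clip(0.3 + rng.lognormal(0.0, 0.4, n), 0.3, max_rt)

    out = schedule.copy()
    out.insert(0, "participant_id", participant_id)
    out["correct"] = correct
    out["confidence"] = confidence
    out["rt"] = np.round(rt, 3)
    latents = {
        "participant_id": participant_id,
        "trace_frac_closed": trace_frac_closed,
        "trace_frac_open": trace_frac_open,
    }
    return out, latents


def simulate_neural(
    latents: pd.DataFrame, config: GenerativeConfig, rng=None
) -> dict[str, pd.DataFrame]:
    """Simulate ROI parameter estimates and subfield activity differences.

    Each participant's latent nontarget-reinstatement score is
    ``alpha_reinstate * trace_frac_closed`` plus noise; subfield
    closed-minus-open differences are linear in the score (slopes
    ``beta_ca3`` / ``beta_dg``); category-selective ROI betas encode the
    element function (target > cue > nontarget) with the closed-loop
    nontarget condition elevated by ``nontarget_gain * score``.
    """
    rng = np.random.default_rng(rng)
    pids = list(latents["participant_id"])
    frac = latents["trace_frac_closed"].to_numpy(dtype=float)
    score = config.alpha_reinstate * frac + rng.normal(0, config.sigma_beta, len(pids))

    subfield_rows = []
    slopes = {"CA3_ant_R": config.beta_ca3, "DG_ant_R": config.beta_dg}
    for sf in SUBFIELDS:
        diff = slopes[sf] * score + rng.normal(0, config.sigma_neural, len(pids))
        for pid, d in zip(pids, diff):
            subfield_rows.append({"participant_id": pid, "subfield": sf, "diff": d})

    mu_fn = {"cue": config.mu_cue, "target": config.mu_target, "nontarget": 0.0}
    cells = []  # (roi, condition, loop, function)
    for roi, category in (("PHC", "location"), ("MPC", "people"), ("LOC", "object")):
        for cond in CONDITION_PAIRS:
            c1, c2 = cond.split("-")
            fn = "cue" if category == c1 else "target" if category == c2 else "nontarget"
            for lp in ("closed", "open"):
                cells.append((roi, cond, lp, fn))
    mu = np.array([mu_fn[fn] for _, _, _, fn in cells])
    nontarget_closed = np.array(
        [fn == "nontarget" and lp == "closed" for _, _, lp, fn in cells], dtype=float
    )
    # (n_participants, n_cells)
    beta = (
        mu[None, :]
        + config.nontarget_gain * score[:, None] * nontarget_closed[None, :]
        + rng.normal(0, config.sigma_beta, (len(pids), len(cells)))
    )
    betas = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, len(cells)),
            "roi": np.tile([c[0] for c in cells], len(pids)),
            "condition": np.tile([c[1] for c in cells], len(pids)),
            "loop_type": np.tile([c[2] for c in cells], len(pids)),
            "beta": beta.ravel(),
        }
    )
    return {
        "betas": betas,
        "subfields": pd.DataFrame(subfield_rows),
        "scores": pd.DataFrame({"participant_id": pids, "score_true": score}),
    }


def simulate_bold(
    design_matrix, true_betas, noise_sd: float, rng=None
) -> np.ndarray:
    """Gaussian-noise BOLD data: ``Y = X @ beta + N(0, noise_sd)``.

    ``true_betas`` may be a vector (one voxel) or ``(n_regressors,
    n_voxels)`` array.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(design_matrix, dtype=float)
    B = np.asarray(true_betas, dtype=float)
    if B.shape[0] != X.shape[1]:
        raise ValueError(
            f"true_betas has {B.shape[0]} rows but design matrix has "
            f"{X.shape[1]} columns"
        )
    Y = X @ B
    return Y + rng.normal(0, noise_sd, Y.shape)


def simulate_cohort(
    design_config: DesignConfig | None = None,
    gen_config: GenerativeConfig | None = None,
    seed=None,
) -> dict:
    """Simulate a full cohort: schedules, trial outcomes and neural data.

    With ``design_config.shared_event_set`` every participant receives the
    same event set and schedule; otherwise each participant's design is
    generated from an independent child stream.  All randomness derives from
    ``seed`` (falling back to ``gen_config.seed``).
    """
    design_config = design_config or DesignConfig()
    gen_config = gen_config or GenerativeConfig()
    if seed is None:
        seed = gen_config.seed
    ss = np.random.SeedSequence(seed)
    design_ss, behavior_ss, neural_ss = ss.spawn(3)

    n = gen_config.n_participants
    pids = [f"p{i:03d}" for i in range(n)]

    design_children = design_ss.spawn(n)
    schedules: dict[str, pd.DataFrame] = {}
    if design_config.shared_event_set:
        rng = np.random.default_rng(design_children[0])
        event_set = build_event_set(design_config, rng)
        sched = build_retrieval_schedule(event_set, design_config, rng)
        for pid in pids:
            schedules[pid] = sched
    else:
        for pid, child in zip(pids, design_children):
            rng = np.random.default_rng(child)
            event_set = build_event_set(design_config, rng)
            schedules[pid] = build_retrieval_schedule(event_set, design_config, rng)

    outcome_frames = []
    latent_rows = []
    for pid, child in zip(pids, behavior_ss.spawn(n)):
        out, lat = simulate_behavior(
            schedules[pid], gen_config, np.random.default_rng(child), pid
        )
        outcome_frames.append(out)
        latent_rows.append(lat)
    outcomes = pd.concat(outcome_frames, ignore_index=True)
    latents = pd.DataFrame(latent_rows)
    neural = simulate_neural(latents, gen_config, np.random.default_rng(neural_ss))
    return {
        "schedules": schedules,
        "outcomes": outcomes,
        "latents": latents,
        **neural,
    }
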