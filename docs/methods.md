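# Methods

`loopdep` implements an analysis pipeline for multi-element associative
memory experiments that contrast *closed-loop* events (three elements, all
three pairwise associations encoded: AB–BC–CA) with *open-loop* events (four
elements encoded as a chain: AB–BC–CD). Closed loops are hypothesized to be
stored as coherent event representations that are recalled holistically via
pattern completion; open loops serve as a control in which associations can
be retrieved independently. The package covers the experimental design, a
synthetic cohort generator, the behavioral retrieval-dependency analysis, a
minimal first-level BOLD GLM, cortical reinstatement scoring, and
group-level brain–behavior statistics.

## Experimental design

The default design holds 36 events: 18 closed loops (9 combining a location,
a literal object and a person; 9 combining a location, an animal and a
person) and 18 open chains containing one element from each of the four
stimulus pools (location, object, animal, person). For analysis the object
and animal pools are merged into a single *object* category; an
`animal_flag` is kept on elements because one scheduling constraint and lure
selection operate on the original pools.

Encoding presents one association of each event per block over three blocks
(108 trials). Within an event consecutive blocks share exactly one element,
and the block-3 pair always combines an object/animal element with a
location or person. Retrieval probes every association in both cue→target
directions over six blocks (216 trials, 6 per event) as four-alternative
forced choice (chance = 25%) with three lures drawn from the target's
stimulus pool in other events, followed by a 1–4 confidence rating.

Onsets lie on a regular grid (0.5 s fixation + stimulus window + 1.5 s
inter-stimulus interval) because the pipeline has no live response timing;
this keeps every schedule a deterministic function of the seed. Event sets
are generated per participant from independent child streams of a root
seed; a `shared_event_set` flag reproduces the fixed-set variant. A noted
design choice: the six directed retrieval trials of an event are placed
into the six blocks by a free random permutation (one trial per event per
block); no further pairing of directions across adjacent blocks is imposed.

## Synthetic cohort generator

Behavioral outcomes follow a latent-trace Bernoulli mixture. For each
closed-loop event a single holistic trace forms with probability
`p_trace_closed`; when present it governs all six retrieval trials of the
event, which is what induces dependency between different associations of
the same event. Open-loop associations receive independent per-association
traces (`p_trace_pair`), so within-event successes on different
associations are independent by construction. A governed trial is correct
with probability `p_hit_given_trace` (default 0.98); otherwise the response
is a guess, correct with probability 0.25. Confidence is high (3–4) with
probability `p_highconf_trace` under a trace and `p_highconf_guess` under a
guess. Defaults (`p_trace_closed = 0.87`, `p_trace_pair = 0.83`) put
overall accuracy near 87%, with closed-loop accuracy a few points above
open-loop — a high-performing cohort in which accuracy-based dependency is
close to ceiling and the confidence-based variant is the more sensitive
measure. Optional switches give degenerate regimes used for calibration:
`independent_trials` draws a fresh trace per trial (a true independence
generator), and zero trace probabilities give pure guessing. Response times
are drawn from a truncated log-normal and are not analyzed; they exist for
format fidelity.

The neural generator couples each participant's realized holistic-trace
fraction f (the fraction of closed events whose trace formed) to a latent
nontarget-reinstatement score s = `alpha_reinstate`·f + noise, and then to
hippocampal-subfield activity differences (closed − open):
CA3 = `beta_ca3`·s + noise, DG = `beta_dg`·s + noise. Category-selective
ROI betas are built per condition (six ordered category pairs × two loop
conditions) with mean levels target (1.0) > cue (0.6) > nontarget (0.0) and
the closed-loop nontarget cells elevated by `nontarget_gain`·s. Default
couplings were chosen once so that a 30-participant cohort lands near the
magnitudes typical of such studies (CA3 R² around 0.15, DG around 0.05,
a positive but modest CA3-vs-DG z). The generator compresses all fMRI
measurement noise into a single per-cell Gaussian (`sigma_beta`), so group
t statistics on reinstatement differences are far larger than anything real
data would produce; passing tests demonstrate correct recovery of the
injected structure, not realistic effect sizes. `GenerativeConfig.strong_effect()`
is a preset with deliberately large, easily detectable effects used for
power-style checks.

What the generator does **not** emulate: temporally autocorrelated fMRI
noise, scanner drift, trial-level variability in neural responses,
forgetting across retrieval blocks, response-time-dependent trial
durations, and any relation between confidence and latency.

## Retrieval dependency

For each participant and loop condition, trials probing different
associations of the same event but sharing an element are paired: cue-based
pairs share the cue element (AbAc), target-based pairs share the target
element (BaCa). Pooling pairs across events gives one 2×2 contingency table
per (category, role); closed loops yield six tables, open chains only where
an element serves the same role twice (the middle elements — chain ends
never cue twice). If an open event holds two merged-object elements in
middle position, the anchor with the smallest element id is kept so each
event contributes at most one pair per table.

Observed dependency is (n11 + n00)/N — the fraction of events where both
trials succeed or both fail. The independent model predicts
P1·P2 + (1−P1)(1−P2) from the two trial types' marginal success rates. The
dependent model converts each event's accuracy A_i (over its six retrieval
trials by default) to a guessing-corrected strength
m_i = max(0, (A_i − g)/(1 − g)), forms the episodic factor E_i = m_i/m̄
(with m̄ from the loop condition's mean event accuracy, and E_i = 1 when
m̄ = 0), scales the guessing-corrected marginals by E_i with clamping to
[0, 1], re-adds the guessing floor, and averages the per-event match
probability. When all E_i = 1 this reduces exactly to the independent
model. This algebra is a reconstruction from the verbal description of the
published procedure; the guessing-correction placement is the main point
where a published variant could differ, so the formula is stated fully and
tested against a brute-force per-event oracle.

Scoring modes: `accuracy` (correct vs incorrect) and `confidence` (correct
*and* confidence ≥ 3 vs everything else). Non-response trials count as
failures in both modes. Evidence for dependency is D_obs − D_ind; group
inference uses paired t-tests (evidence closed vs open; observed vs model
within loop). Because observed dependency scales with accuracy, only these
model-relative comparisons are interpretable.

## First-level GLM

Condition regressors are stimulus boxcars convolved with the conventional
double-gamma canonical HRF (peak 6 s, undershoot 16 s, unit dispersions,
6:1 amplitude ratio, 32 s support, peak-normalized), oversampled 16× per TR
and decimated to scan times. Nuisance terms: intercept, six motion
parameters, an ISI regressor, and one unit indicator per flagged outlier
scan (equivalent to deleting the scan, which is asserted in the tests).
Estimation is OLS via pseudo-inverse (rank-deficient designs warn and fall
back gracefully); contrasts report c'β and t = c'β / √(σ̂² c'(X'X)⁻c) with
dof = n_scans − rank(X). No prewhitening is applied; the intended inputs
are white-noise simulations.

Outlier scans are flagged when the frame-to-frame displacement — the
maximum absolute change over the six motion parameters, rotations converted
to mm at a 65 mm radius — exceeds 2 mm, or when the global-signal z-score
exceeds 9.0 in magnitude. A participant is excluded when the flagged
fraction strictly exceeds 10% (exactly 10% is kept).

## Reinstatement scoring

Condition parameter estimates are z-standardized across conditions within
each (participant, ROI) cell using the population-SD convention (visible in
two-condition cells, which map to ±1). Each ROI maps to one category
(default: parahippocampal cortex → location, medial parietal cortex →
people, lateral occipital cortex → object). For a ROI of category X, the
cue score averages conditions with X first in the ordered pair, the target
score those with X second, and the nontarget score those without X; scores
are then averaged across the three ROIs. With loop-split tables the same
scores are computed per loop condition and closed − open differences are
tested against zero with one-sample t-tests. The element-function ANOVA is
provided in two modes — one-way repeated measures (participant as blocking
factor; validated against `statsmodels.AnovaRM`) and an independent-groups
one-way mode — because the F degrees of freedom reported for this design in
the literature are consistent with the between-groups form at n = 26;
neither mode is endorsed over the other.

## Brain–behavior statistics

ROI correlations use Pearson r with the exact t-based p value (df = n − 2).
Comparisons of two correlations sharing one variable use the
Meng–Rosenthal–Rubin z (Fisher-transformed coefficients, with the f and h
correction terms and one-tailed p). This variant was chosen because both
analysis uses share exactly one variable; Steiger's alternative differs
slightly and neither can be distinguished by published summary statistics.
When the two correlations are numerically identical the statistic is defined
as z = 0 (p = 0.5). The voxelwise covariate map correlates each voxel's
contrast value with the covariate across participants, thresholds the
one-sided p map at 0.005 (uncorrected, optionally mask-restricted), and
extracts face-connected components with a configurable minimum extent —
a deliberate simplification that replaces random-field cluster inference.
Mask splitting cuts the occupied extent along the designated longitudinal
axis at half its length, assigning the boundary slice to the posterior half
for determinism.

## Numerical and degenerate-input conventions

- All randomness flows from one root seed through named `SeedSequence`
  child streams (design / behavior / neural / GLM demo), so every stage is
  independently reproducible and the full report bundle is byte-identical
  across runs.
- Zero-variance difference vectors in paired tests are flagged and their p
  omitted, except the all-zero case which reports t = 0, p = 1.
- Empty contingency tables are dropped with a warning; events with fewer
  than two qualifying trials are omitted from a table.
- Repeated-measures F uses a relative tolerance on the sums of squares so
  exactly-equal scores report F = 0 rather than 0/0 noise.
- The retrieval schedule contains 216 trials (6 per event × 36); the
  per-event rule is structurally forced by the bidirectional design.

## Problem sizes

Calibration checks use 200–500 simulated participants or 2000–5000
Monte-Carlo replicates, and recovery checks 200 replicates of
30-participant cohorts — sizes at which binomial error on the checked rates
is several times smaller than the acceptance margins. The acceptance script
analyzes a single default 30-participant cohort, matching the scale of the
studies this pipeline targets.

## Known limitations

- The dependent-model algebra is a documented reconstruction (see above),
  not a port of unpublished code.
- Univariate reinstatement only; no multivariate pattern similarity.
- No realistic fMRI noise model, no prewhitening, no random-field or
  permutation cluster inference, no spatial preprocessing.
- Open-loop dependency tables use only elements that repeat a role; no
  structure is imputed for chain ends.
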