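# loopdep

Analysis pipeline for multi-element event memory experiments that test
**holistic recollection**: when a single cue retrieves one element of an
event, are the event's other elements retrieved too?

The experimental paradigm encodes events as overlapping word-pair
associations. *Closed-loop* events bind three elements with all three
pairwise associations (AB–BC–CA); *open-loop* events chain four elements
with three associations (AB–BC–CD). If closed loops are stored as coherent
representations completed from any cue, then (1) retrieval success on
different associations of the same closed-loop event should be
statistically dependent, and (2) retrieving one association should
reinstate cortical activity for the event element that is neither cue nor
target (*nontarget reinstatement*), with the effect coupled to hippocampal
pattern-completion machinery (subfield CA3 more than dentate gyrus).

`loopdep` provides, as scikit-learn-style estimators plus plain functions:

- **experiment design** — event sets, encoding (3 × 36 trials) and
  bidirectional 4AFC retrieval schedules (6 × 36 trials) with the paradigm's
  randomization constraints, written as BIDS-style events TSV;
- **synthetic cohorts** — a latent-trace Bernoulli generator for trial
  outcomes (holistic traces in closed loops only) and linearly coupled
  neural scores, replacing the undeposited raw data of such studies;
- **retrieval dependency** (`RetrievalDependency`) — contingency tables per
  (category, cue/target role); observed dependency (n11+n00)/N versus the
  independent model P1·P2 + (1−P1)(1−P2) and a guessing-corrected dependent
  model with per-event *episodic factors* E_i = m_i/m̄,
  m_i = max(0, (A_i−g)/(1−g)); accuracy and high-confidence scoring modes;
- **first-level GLM** (`FirstLevelGLM`) — boxcar ⊛ canonical double-gamma
  HRF regressors, motion/ISI/outlier-indicator nuisance columns, OLS with t
  contrasts, and ART-style scan-outlier detection (2 mm / |z| > 9, >10%
  exclusion rule);
- **reinstatement scoring** (`ReinstatementScorer`) — z-standardized ROI
  betas mapped to cue/target/nontarget element functions, loop-split
  differences, one-sample t-tests and a repeated-measures ANOVA;
- **brain–behavior statistics** — Pearson ROI correlations, the
  Meng–Rosenthal–Rubin one-tailed z test for dependent correlations,
  voxelwise covariate maps with face-connected cluster extraction, and
  anterior/posterior mask splitting.

## Worked example

```python
import loopdep as ld

summary = ld.run_pipeline(ld.PipelineConfig(seed=1))

print(round(summary["accuracy"]["overall_pct"], 1))          # 87.3
dep = summary["dependency"]["confidence"]["means"]
print(round(dep["closed"]["evidence"], 3))                   # 0.158
print(round(dep["open"]["evidence"], 3))                     # 0.004
bb = summary["brain_behavior"]
print(round(bb["ca3"]["r2"], 2), round(bb["dg"]["r2"], 2))   # 0.13 0.12
```

A 30-participant synthetic cohort is simulated and pushed through the full
chain. Overall 4AFC accuracy lands near 87%. Dependency *evidence* is the
observed dependency minus the independent-model expectation: under
high-confidence scoring the closed-loop evidence (0.158) clearly exceeds
the open-loop evidence (0.004), the signature of holistic recollection
(accuracy-mode dependency sits closer to ceiling). `ca3`/`dg` give the
variance in the hippocampal closed−open activity difference explained by
each participant's nontarget reinstatement score; at a single cohort of
n = 30 these R² values carry substantial sampling noise, and
`bb["ca3_vs_dg"]["z"]` tests their difference directly. The pipeline is
deterministic given the seed: rerunning prints the same numbers.

The same stages are scriptable from the shell:

```sh
loopdep simulate --seed 1 --out data/
loopdep dependency data/p000_retrieval.tsv --mode confidence
loopdep run-all --seed 1 --out results/
```

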