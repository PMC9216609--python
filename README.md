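# stageflow

Analysis pipeline for comparing **creative problem solving (CPS)** with
**simple problem solving (SPS)** from two synchronized behavioral data
streams:

1. **Stage-coded protocols.** Each participant's session is segmented into
   timestamped units (verbal utterances and observed task actions), each
   coded into one of eight problem-solving stages: *Preparation, Ideation,
   Illumination, Evaluation, Refinement, Production, Block, Other*. The
   package estimates a per-participant first-order Markov chain over the
   stages — an 8×8 transition matrix **P** — and solves

   ```
   πP = π,   Σᵢ πᵢ = 1
   ```

   for the stationary (equilibrium) distribution **π**, used as a
   per-stage measure of relative cognitive effort. Group-level outputs are
   the per-stage mean (SD) table, pooled transition diagrams (row-conditional
   relative frequencies, exported as DOT graphs), per-stage Mann-Whitney U
   comparisons between groups, and Cohen's κ for intercoder reliability.

2. **Facial action-unit streams.** OpenFace-2.0-style CSVs (25 fps, AU
   intensities on a 0–5 scale) are confidence-filtered (frames with
   tracking confidence < 95% removed), stage-labeled by timestamp against
   the coded protocol, reduced to EMFACS emotion feature sets (e.g.
   Happiness = AU6+AU12, Anger = AU4+5+7+23), balanced by random
   undersampling to the minority stage, and classified with a degree-4
   polynomial-kernel SVM (one-vs-one), yielding a 7 emotions × (6 stages ×
   2 groups) accuracy matrix.

A synthetic-data module generates both data kinds from known parameters
(ground-truth transition chains; stage-dependent emotion mixtures that
raise an emotion's AU combination above baseline), so the entire pipeline
runs and is verifiable without any recordings.

## Worked example

```python
import stageflow as sf

# simulate a small creative-group cohort from the built-in chain
chain = sf.cps_like_chain()
cohort = sf.simulate_cohort(chain, n_participants=5, events_per_participant=100,
                            seed=1, group="CPS")

table = sf.cohort_stationary_table(cohort)
print(table.mean.round(3).to_dict())
```

prints

```
{'Preparation': 0.217, 'Ideation': 0.335, 'Illumination': 0.016,
 'Evaluation': 0.052, 'Refinement': 0.047, 'Production': 0.285,
 'Block': 0.022, 'Other': 0.026}
```

— the cohort spends about a third of its effort in Ideation and most of
the rest in Preparation/Production, mirroring the generating chain's
stationary vector (`chain.stationary().pi` ≈ (0.227, 0.314, …)); the gap
is sampling error at 100 events per participant. Pooling the same cohort,

```python
pooled = sf.pooled_transition_matrix(cohort)
print(round(pooled.relfreq[sf.StageCode.PRODUCTION, sf.StageCode.IDEATION], 3))
# 0.558
```

recovers the chain's strong production→ideation loop (true row value
0.57). The full pipeline is also available from the shell:

```bash
stageflow all --seed 42 --out results/demo
```

which writes the coded-segment and OpenFace-style CSVs, stationary and
pooled-matrix tables, DOT transition diagrams, the per-stage group
comparison, and the emotion × stage accuracy matrix, along with a resolved
config + seed manifest sufficient to reproduce every file byte-for-byte.

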