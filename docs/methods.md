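# Methods

## Stage model and data

A session is an ordered list of coded segments over half-open time
intervals `[start_s, end_s)`, each labeled with one of eight
problem-solving stages in a fixed canonical order (Preparation, Ideation,
Illumination, Evaluation, Refinement, Production, Block, Other). The
canonical order indexes every matrix in the package. Consecutive segments
with the same stage are **not** merged: repeats are real events and their
self-transitions populate the diagonal of the transition matrix (pooled
diagrams show large self-transition probabilities, which only exist if
repeats are kept). Gaps between segments are allowed; un-covered time is
simply unlabeled.

## Markov arm

**Estimation.** For one participant, `N[i][j]` counts adjacent stage
pairs in the segment-order sequence (total = sequence length − 1), and
`P[i][·] = N[i][·] / rowsum`. Two policies make `P` stochastic on
degenerate input:

* *Zero-exit rows* (the final stage of a sequence, or an unvisited stage)
  are set to the uniform distribution over **visited** stages. Making
  them absorbing would concentrate π spuriously; uniform-over-visited
  keeps P stochastic without inventing structure.
* *Unvisited stages* receive π mass exactly 0, reinserted at their
  canonical index.

**Stationary solve.** π is the left eigenvector of eigenvalue 1 of P
restricted to the visited stages, accepted when that eigenvalue is simple
within 1e-8; the result satisfies `max|πP − π| ≤ 1e-8` and `Σπ = 1 ±
1e-10`. If the eigenspace is degenerate (reducible or multi-recurrent
chains), the estimator returns empirical visit frequencies flagged
`visit_frequency_fallback` instead of erroring — every participant gets a
π, and the flag keeps the estimator auditable. An independent power
iteration (10,000 steps) agrees to 1e-6 max-norm on random ergodic
matrices in the test suite.

**Pooling.** Group matrices sum counts across participants, then
row-normalise: each cell is the row-conditional relative frequency of
that transition (pooled rows with no exits are NaN and listed as empty,
never fabricated). Diagram export emits DOT with one node per stage
(abbreviations Prep/Ide/Illum/Eva/Ref/Prod/Blo/Oth), one edge per cell at
or above the threshold, edge label = probability to two decimals, pen
width proportional to probability.

**Group comparison.** Per stage, the two groups' π entries are compared
with the Mann-Whitney U test: U from rank sums with midranks, z from the
tie-corrected variance with no continuity correction (the convention of
standard statistics packages at cohort sizes of ~30 per group). The
two-sided p is **exact** — enumeration of all C(n, n1) rank assignments —
when the pooled sample has at most 12 values, and the normal tail
otherwise; small-sample p-values from the normal approximation alone can
deviate from the exact test by far more than conventional reporting
precision (the approximation's discreteness error exceeds 0.1 below
pooled n ≈ 10). This is the standard hybrid policy of mainstream
implementations. No multiple-testing adjustment is applied to the
per-stage tests; a Holm-adjusted column is emitted alongside, clearly
marked as an extension. Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from
the coders' marginal frequencies summarises intercoder agreement; if both
coders are constant and identical (p_e = 1), κ is reported as 1 with a
degeneracy flag.

## Facial arm

**Ingestion.** OpenFace 2.0 CSVs are read with whitespace-tolerant
headers; exactly 12 AU intensity (`_r`, 0–5 scale) columns are required —
AUs {1, 4, 5, 6, 7, 9, 10, 12, 15, 17, 20, 23}, the union of the seven
EMFACS emotion combinations:

| Emotion | AU combination |
|---|---|
| Anger | 4+5+7+23 |
| Happiness | 6+12 |
| Fear | 1+4+5 |
| Pride | 6+7+12 |
| Sadness | 1+4+15 |
| Disgust | 4+7+9+10+17+20 |
| Stress | 1+6+12+15 |

**Filtering and labeling.** Frames with confidence strictly below 0.95
("less than 95%") or a failed fit are removed; frames at exactly 0.95 are
kept. Stage labels are joined by timestamp (not frame index, since
filtering creates index gaps) against the protocol's half-open intervals;
frames in gaps are dropped with a counted warning. Illumination- and
Other-labeled frames are discarded before classification (illumination is
too brief for retrospective coding; "other" has no task content), leaving
six stage classes.

**Classification.** Each class is randomly undersampled, without
replacement, to the minority-class count (implemented with a seeded numpy
generator). Balancing precedes the stratified 80/20 split. Per (emotion,
group), a soft-margin SVM (polynomial kernel, degree 4, C = 1.0 — the
regularization weight is exposed but the study names no value —
one-vs-one decomposition) is trained on the emotion's AU columns as raw
intensities (no standardization by default; a switch exists). Per-stage
accuracy is per-class **recall** of the single 6-class model on the
balanced test set — the reading consistent with a one-vs-one multiclass
model reported per stage; an alternative scheme of independent one-vs-rest
binary classifiers is available via `multiclass_scheme="ovr"`. The chance
floor for a 6-class balanced problem is asserted on balanced overall
accuracy (1/6): an individual class's recall is not chance-bounded, since
even a constant predictor scores recall 1.0 on its favored class.

## Synthetic-data generator

The generator defines the study conditions the pipeline is verified
under: 33 CPS and 31 SPS participants; sessions recorded at 25 frames/s
(a 30-minute session indexes exactly 45,000 frames).

**Chains.** Stage sequences are first-order chains. Two built-in chains
encode the reported group-level structure. Anchored entries (creative
group: production→ideation 0.57, production→preparation 0.12,
preparation→preparation 0.57, preparation→production 0.19,
illumination→ideation 0.65, illumination→preparation 0.05,
refinement→preparation 0.22, other→preparation 0.33; simple group:
preparation→preparation 0.40, preparation→production 0.50,
production→preparation 0.82, production→ideation 0.01,
refinement→preparation 0.50, other→preparation 0.49,
illumination→preparation 1.00) are fixed; the remaining mass in each row
is fixed plausible structure chosen once (ideation-centred loops for the
creative chain, preparation-centred for the simple chain). `iid_chain(q)`
builds a chain whose every row is `q`, whose stationary vector is `q`
itself — the natural generator for cohorts with a prescribed mean
occupancy profile; the two groups' mean occupancy vectors (creative:
0.21/0.37/0.00/0.09/0.07/0.23/0.02/0.01; simple:
0.53/0.01/0.00/0.08/0.04/0.32/0.01/0.01 in canonical order) ship as
constants. Segment durations are exponential (default mean 5 s,
per-stage means configurable, independent of stage identity by default —
no duration model is prescribed by the protocol design) and the
transition analysis ignores durations entirely.

**AU streams.** Within a stage, latent emotion episodes are drawn from
the stage's mixture with geometric episode lengths (default mean 25
frames = 1 s): facial expressions persist across video frames, and
per-frame independence would make classification unrealistically easy at
a given activation. While an emotion is active, each AU in its
combination is raised by `activation_delta` (default 2.0) above
`baseline` (default 0.5); Gaussian noise (default SD 0.35) is added and
intensities are clipped to [0, 5] after noise, matching the bounded
output scale. Confidence is ≥ 0.95 except for a configured fraction
(default 2%) drawn in [0.5, 0.95). The default stage mixtures give Block
a strongly negative profile (anger/fear/sadness/disgust) and the
productive stages ambivalent mixtures of happiness, pride, fear and
stress. Real AU data differ in ways the generator does not emulate —
inter-individual baselines, head-pose artifacts, correlated AU noise,
annotation error in stage boundaries — so passing tests demonstrate
pipeline correctness and statistical calibration, not field accuracy of
emotion recognition.

## Problem sizes and determinism

Default problem sizes are chosen so every check runs in minutes on one
CPU: parameter-recovery runs use the full cohort sizes (33/31) with 600
events per participant for stationary recovery and 1,000 for pooled
recovery; calibration studies (type-I error of the group comparison) use
1,000 replicates of 64 participants × 150 events through a vectorised
sequence-batch path; classification property checks use a few hundred
frames per class. The end-to-end CLI demo synthesises shorter facial
sessions (6 participants × ~10 minutes per group) than a full-scale
session; full-length 45,000-frame streams are exercised where the check
is about frame arithmetic. Every public generator and sampler takes an
explicit seed; one master seed fans out deterministically
(`numpy.random.SeedSequence` spawning) to per-participant and
per-operation seeds, and rerunning any command with the same config and
seed reproduces outputs byte-for-byte (float timestamps and intensities
are written with shortest round-trip representation, and files are re-read
with round-trip float parsing).

## Known limitations

* First-order chains only; no hidden-state, higher-order, or
  continuous-time models.
* The stationary vector of a short sequence is an estimate from a single
  realisation; the visit-frequency fallback for degenerate chains is a
  pragmatic policy, not an inference procedure.
* The per-stage accuracy definition (per-class recall of one multiclass
  model) is one of two defensible readings of a per-(emotion, stage)
  accuracy report; the other (independent binary classifiers) is
  implemented behind a switch and gives systematically different numbers.
* Synthetic AU streams make no attempt at facial realism; they encode
  exactly the statistical structure the classifier is meant to exploit.
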