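# Methods

## The problem being simulated

Two institutions hold speech-derived acoustic feature tables (one row per
participant, a binary CU/CI diagnosis) and want a shared cognitive-impairment
classifier without exchanging records. The package simulates this federation
end to end on synthetic data and asks how data heterogeneity — unequal cohort
sizes (quantity skew) and unequal case mixes (label skew) — changes what each
institution gets out of collaborating, relative to training alone.

## Synthetic cohort model

Features are class-conditional multivariate Gaussians with identity
covariance. Non-informative features are standard normal in both classes; the
first `m = n_informative` features have their mean shifted by
`d = effect_size` in the CI class. Labels are assigned by a deterministic
quota — exactly `round(n · cu_prevalence)` CU rows — rather than Bernoulli
draws, so partition fixtures have reproducible counts. Optional label noise
flips labels (only labels) after feature generation; an optional site shift
adds a constant to a random half of the cohort to emulate crude inter-site
covariate shift.

Under this model the Bayes-optimal classifier is the linear discriminant
`x · Δμ`, and its ROC AUC has the closed form `Φ(d√m/√2)`. This is the
package's main testing oracle: the generator is validated against it by Monte
Carlo, and experiment operating points are expressed in terms of it.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_features` | 176 | two speech tasks × 88 eGeMAPS-style descriptors |
| `cu_prevalence` | 0.099 | the memory-clinic case mix being emulated (≈221/2,239 CU) |
| `n_informative` | min(10, p) | a small informative subset; keeps most features as nuisance dimensions, as in real acoustic panels |
| `effect_size` | 0.573 | with m = 10 gives Bayes AUC ≈ 0.90 — a strong but imperfect signal, the operating point of the rescue experiment |
| `label_noise`, `site_shift` | 0 | off unless a study turns them on |

What the generator does **not** model: correlation between acoustic
descriptors (real eGeMAPS features are strongly collinear), non-Gaussian
tails, demographic confounders, and systematic inter-site instrumentation
differences beyond a mean shift. Passing tests therefore demonstrate the
correctness and qualitative behavior of the pipeline, not expected
performance on clinical recordings.

## Partitioning conventions

`node_fractions` allocate `floor(f_k · N)` cases to every node except the
last, which takes the remainder; this is the unique convention consistent
with the canonical two-institution tables (1,119/1,120 and 223/2,016 at
N = 2,239). Within a node the CI quota is `round(ci_fraction · size)`, drawn
without replacement from the class pools — again with the **last node taking
the remainder of both pools**. The remainder rule for classes is needed
because rounding every node's quota independently can demand one or two more
minority cases than the cohort holds (at 9.9% prevalence the 90%-CI presets
demand 224 CU from a 222-CU cohort); the last-node mix deviates from its
preset by under 0.3 percentage points at these sizes. Exhausting a pool for
any non-last node raises an error naming the node and class.

The 70/30 split takes `floor(0.7 · N)` training rows, allocated across
classes by floors plus largest remainder, so totals are exact and the split
is stratified. Stratification matters for label-skewed nodes: a 3%-CU node
must keep CU cases in its test set for specificity to be estimable.

The label-skew preset (`scenario3`) carries a documented inconsistency in its
source material (printed node percentages summing to 104%, node totals
summing to 2,226 ≠ 2,239). The preset keeps the printed 1,395:831 node-size
ratio, so a 2,226-row cohort reproduces those totals exactly and any other N
partitions cleanly; no headline count is tied to this scenario.

## Classifier and training

A feed-forward MLP: input width = number of features, hidden layers 20 and
20 with ReLU, one sigmoid output; Glorot-uniform initialization
(±√(6/(fan_in+fan_out))), zero biases. Training is plain minibatch SGD,
batch 32, initial lr 0.01 with exponential decay 0.95 **per epoch**
(interpreting a per-"step" decay as per-epoch: 150 steps of 0.95 leaves
lr ≈ 4.6 × 10⁻⁶, whereas per-batch decay would extinguish the rate inside
the first epoch at realistic node sizes; the decay unit is configurable).
The loss is binary cross-entropy with per-sample weights `w_c = N/(2N_c)`
computed **once per node from its training labels** and applied in every
batch — not recomputed per batch, which would be undefined for single-class
batches. No dropout, batch norm, or weight decay; the small architecture is
the capacity control. An optional validation hold-out exists but is off by
default since the study design only uses train/test.

Features are z-standardized per node with that node's training statistics
(applied unchanged to its test data). In the federated condition each client
keeps its own scaler; under covariate shift this is a known source of
client-model disagreement, and it is the realistic choice since pooling
statistics would leak data.

Probabilities are thresholded at 0.5 for the confusion matrix (threshold
configurable); AUC uses midrank ties.

## Federated orchestration

Defaults: 150 rounds × 1 local epoch, conserving the 150-epoch budget of the
local condition while maximizing communication (the classical FedAvg
regime). The lr schedule is indexed by cumulative epoch count across rounds,
so local and federated conditions traverse identical lr trajectories. The
single final global model is evaluated on every node's test set; local models
are cross-evaluated on every node's test set as well.

Seeding: per-client shuffle generators are seeded identically and advance
independently. Consequence (used as an exact test): with identical client
data and the mean aggregator, federated training for R rounds equals
single-client training for R epochs bit-for-bit, and aggregation of identical
clients is a fixed point. A master seed derives all stage seeds via
`SeedSequence(master).generate_state(4)` in the fixed order (generator,
partition, split, training), making whole experiments byte-reproducible.

Aggregation: FedAvg weights by training-set size; IDA weights inversely to
the ℓ1 distance from the round's unweighted average model, over the fully
flattened parameter tree, biases included, with ε = 10⁻⁸ guarding the
division. A structural caveat the package surfaces deliberately: **for K = 2
clients IDA always yields α = (½, ½)** (each model is equidistant from the
midpoint), so in two-institution studies IDA is arithmetically identical to
the plain mean and differs from FedAvg only through the sample-size weights
FedAvg applies. The plain-mean baseline makes this observable in round logs.

## Experiment sizes used in the shipped analyses

The rescue and null-signal simulations use the full cohort size (n = 2,239)
but a 50-round × 1-epoch budget (and 50-epoch local baselines) over 10 and 5
master seeds respectively; medians over seeds are reported because the
data-poor node's test set (67 cases, ~7 CU) makes single-seed panels noisy.
These sizes give stable directional results while keeping the whole analysis
re-runnable in about a minute.

## Known limitations

* Single-process simulation: no transport, stragglers, dropout, asynchrony,
  or privacy mechanisms (no secure aggregation / differential privacy).
* The independence of acoustic features in the generator overstates the
  effective signal dimension relative to collinear real panels.
* With 166 pure-noise dimensions and ~1,500 training rows, trained models sit
  well below the Bayes AUC ceiling; this estimation gap is expected and is
  why acceptance checks are directional (federated vs local) rather than
  absolute.
* Per-node standardization is the only harmonization implemented; no
  ComBat-style adjustment or domain adaptation.
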