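# Methods

## Model and assumptions

The package treats side-effect prediction as multi-label classification on
binary descriptors. MLKNN assumes that the label of a drug is exchangeable
with those of its nearest neighbors in feature space: for each label it
estimates, from the training set, (i) the prior probability that a drug
carries the label and (ii) the distribution of the number of label-positive
drugs among a drug's k nearest neighbors, separately for label-positive and
label-negative drugs. Prediction multiplies prior and likelihood and
normalizes. All estimators use additive smoothing with factor s, which
keeps every probability strictly inside (0,1) and forces each posterior row
to sum to 1 — the package asserts this numerically to 1e-12.

Neighbor search ranks training drugs by squared Euclidean distance on the
binary vectors (identical ordering to Euclidean and to Hamming distance for
binary data; squared integer arithmetic avoids floating-point ties that
plain `sqrt` distances could introduce). Jaccard and cosine distances are
available through `MLKNNConfig(distance=...)`. Equidistant neighbors are
ordered by training-row index, making every fit deterministic; note this
means score invariance under training-row permutation is only guaranteed
when no tie straddles the k-th neighbor boundary. During fitting a drug is
never its own neighbor, which prevents self-leakage into the likelihood
counts.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 5 | neighbor count; larger k smooths the likelihood but dilutes locality |
| s | 1.0 | additive smoothing (Laplace) for priors and posteriors |
| σ | 0.001 | mutual-information threshold (bits) of the stage-1 filter |
| GA population | 100 | chromosomes per generation |
| GA max generations | 60 | hard cap on the search |
| GA tolerance | 1e-6 | stop when best fitness changes less between generations |
| elitism | 2 | best chromosomes copied unchanged |
| crossover fraction | 0.8 | fraction of offspring produced by crossover |
| mutation rate | 0.01 | per-gene flip probability (binary encoding) |
| mutation σ | 0.1 | Gaussian mutation scale (simplex encoding) |

k and s have no canonical values for this problem; 5 and 1.0 are the common
MLKNN defaults and both are exposed in the config and CLI. Mutual
information is computed in bits (log base 2); only the ranking against σ
matters, and the base is configurable.

## Feature selection

Stage 1 computes, for every feature dimension, the plug-in mutual
information against each label over the empirical 2×2 joint (zero-count
cells contribute zero) and aggregates by the maximum over labels; the
notation-consistent reading of the aggregate is max_j I(v_i ; d_j).
Dimensions with score strictly above σ survive. Two practical notes:

- The plug-in MI of truly independent binary pairs is biased upward by
  roughly 1/(2 n ln 2) nats — about 0.0036 bits at n = 200 — and the
  max-over-labels aggregation raises it further, so at desk-scale sample
  sizes σ = 0.001 rejects almost nothing. The filter is effective at large
  n (at n = 10000 the bias falls well below σ and most noise dimensions are
  rejected, which the tests verify); at small n the GA wrapper does the
  real work.
- If nothing passes σ the filter falls back to the top ⌈p/10⌉ dimensions by
  score, logged, so downstream stages always have candidates.

Stage 2 encodes dimension subsets as binary chromosomes. Fitness is the
merged AUPR of MLKNN restricted to the chromosome's dimensions under an
internal 5-fold cross-validation of the training drugs; the fold partition
is fixed per run, so fitness is deterministic and cached by chromosome.
The all-zero chromosome is assigned fitness 0. The same internal folds then
furnish the five final submodels: each is fitted on one fold's complement
restricted to the chosen dimensions, and FS-MLKNN predictions are the mean
of the five submodel score matrices. Feature selection is re-run
independently inside every outer cross-validation training set.

## Genetic algorithm

One seeded engine serves both searches. Selection uses rank scaling
(weight 1/√rank) with stochastic universal sampling; the parent pool is
shuffled before pairing. Binary chromosomes use uniform (scattered)
crossover and per-gene flip mutation. Simplex chromosomes (ensemble
weights) use an extrapolating blend crossover (BLX-0.5) and Gaussian
mutation, followed by repair: negative genes are clipped to zero and the
vector renormalized to sum 1 (an all-zero vector becomes uniform), so every
evaluated chromosome is a valid weight vector. Interpolating crossover was
rejected because, under the stop rule below, it stalls far from simplex
vertices on even trivial objectives; extrapolation plus repair reaches
vertices reliably.

Termination follows the stated rule literally: stop when the
best-so-far fitness changes by less than the tolerance between consecutive
generations, or at the generation cap. A constant-fitness objective
therefore stops at generation 2. The rule makes runs short whenever a
generation fails to improve, which suits the expensive wrapper fitness;
elitism guarantees the best-so-far trace is non-decreasing.

Non-finite fitness values are logged and treated as −∞ so a defective
chromosome can never win.

## Ensemble

One FS-MLKNN base predictor is fitted per feature type on the full training
set. For weight tuning, the training drugs are partitioned into five
internal folds; per feature type, an MLKNN restricted to that feature's
already-chosen dimensions is fitted on each fold complement and scores the
held-out fold, giving out-of-fold base score matrices. The GA (simplex
encoding) maximizes the merged AUPR of the weighted sum of these
out-of-fold scores. Re-running the entire GA dimension search inside every
internal fold would nest two GA searches for marginal benefit; reusing the
chosen dimensions keeps the out-of-fold property that overfit base
predictors are not rewarded, at a fraction of the cost. With a single
feature type the weight is 1 and no GA runs.

## Evaluation metrics

- **Merged (micro) AUPR / AUC** pool all drug–label pairs into one ranking.
  AUPR is the non-interpolated step area (average-precision form); tied
  scores enter the curve as one block. AUC uses the rank-sum estimator with
  average ranks for ties. Zero-positive (or single-class) truth raises an
  explicit error rather than returning a default.
- **Ranking metrics** follow the classic multi-label definitions: one-error
  (top-ranked label irrelevant), coverage (rank of the deepest relevant
  label minus 1, unnormalized, so values scale with q), ranking loss
  (misordered relevant/irrelevant pairs, ties counting half) and average
  precision. Drugs with no relevant labels are skipped for
  one-error/ranking-loss/AP and contribute 0 to coverage.
- **Hamming loss** applies the MAP threshold (score > 0.5; posterior tie →
  0) before counting disagreements.
- **Per-label AUPR** is undefined (NaN) for labels with no positive drug;
  the three-way method comparison counts strictly-greater / equal /
  strictly-smaller per defined label.
- **Top-N recall** takes each drug's N highest-scored labels (ties at the
  cutoff broken by label index) and reports the per-drug recall of its
  known side effects.

Every metric is verified against an independent brute-force implementation
(and, where one exists, against scikit-learn) to 1e-12 in the test suite.

## Synthetic data

The generator emulates the structure the method assumes — several sparse
binary feature matrices with a planted informative subset — at desk scale:
200 drugs, three feature types of 50 dimensions (density 0.25, 5 planted
each), 30 labels, base label rate 0.05, association strength 0.6, label
noise 0.02, three associated labels per planted dimension. Those defaults
keep the full FS-MLKNN + ensemble pipeline in minutes while preserving the
qualitative regime: severe label imbalance and a minority of predictive
dimensions. A label fires with probability 0.6 when any of its planted
dimensions is present and 0.05 otherwise, then every cell flips with
probability 0.02; the realized association map is returned as ground truth
so selection precision/recall is computable exactly.

What the generator does **not** emulate: the correlation structure of real
chemical fingerprints (substructure keys are strongly co-occurring),
thousands-of-labels cardinality, and label–label dependence beyond shared
planted dimensions. Passing recovery and improvement tests on this data
therefore shows the pipeline is implemented correctly and can exploit
planted marginal signal; it does not certify performance on real benchmark
matrices.

## Protocols and reproducibility

Outer cross-validation splits drugs into five near-equal folds (the n mod 5
leftover drugs distributed one per fold), trains on four and scores the
fifth, and evaluates the metric suite once per repeat on the merged
out-of-fold score matrix; means and standard deviations are reported across
repeats, with across-fold standard deviations recorded as well since either
aggregation is defensible. A leakage guard aborts if a test drug appears in
any training structure, and the tests verify that permuting a held-out
fold's labels leaves that fold's selected dimensions unchanged. The
independent protocol fits the ensemble on one drug set and reports merged
AUPR/AUC plus top-N recalls on a disjoint set.

All randomness — data generation, fold splits, GA initialization and
operators — flows from a single integer seed through `numpy`'s PCG64
generator, so every manifest is reproducible bit for bit; the acceptance
script's problem sizes are the synthetic defaults above (plus a 150/50
independent split), chosen so the whole run completes in a couple of
minutes on one CPU.

## Known limitations

- Real benchmark matrices (hundreds of dimensions × thousands of labels)
  are supported by the I/O layer but the GA wrapper is O(population ×
  generations × internal-CV MLKNN) and will take hours at that scale, as
  wrapper selection inherently does.
- The MI filter is per-dimension (marginal); redundant or interacting
  dimensions are left to the GA stage.
- The consecutive-generation stop rule can halt the GA early on plateaus;
  raising `fitness_tolerance` to 0 disables it (the generation cap then
  governs).
- Binary features only; continuous descriptors would need prior
  discretization.
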