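# fsmlknn

Multi-label learning for drug side-effect prediction: a Bayesian multi-label
k-nearest-neighbor learner (MLKNN) wrapped by two-stage feature selection
(FS-MLKNN), combined across drug feature types by a weighted-scoring
ensemble, with the full multi-label evaluation suite and reproducible
cross-validation protocols.

## The problem

A marketed drug typically induces many adverse reactions at once, so
predicting its side-effect profile is a multi-label classification task:
given a binary feature vector **x** ∈ {0,1}^p describing a drug (presence of
chemical substructures, protein targets, enzymes, pathways, transporters or
indications) predict a binary label vector **y** ∈ {0,1}^q over hundreds to
thousands of side-effect terms. The label matrix is severely imbalanced —
far more negative than positive drug–label pairs — so the area under the
precision-recall curve (AUPR) over all merged pairs is the headline metric,
not AUC. Only a minority of feature dimensions is actually linked to
toxicity; identifying them both improves accuracy and points at candidate
mechanisms.

## The method

**MLKNN.** For each label *l*, combine a smoothed prior with a neighborhood
likelihood and decide by maximum a posteriori:

    y_t(l) = argmax_{b∈{0,1}} P(H_b^l) · P(E_{C_t(l)}^l | H_b^l)

where C_t(l) counts label-positive drugs among the k nearest training
neighbors of drug *t*, and with smoothing factor *s*:

    P(H_1^l)       = (s + Σ_i y_i(l)) / (2s + n)
    P(E_j^l|H_1^l) = (s + c_l[j]) / (s(k+1) + Σ_i c_l[i])
    P(E_j^l|H_0^l) = (s + c'_l[j]) / (s(k+1) + Σ_i c'_l[i])

c_l[j] counts label-positive training drugs with exactly *j* label-positive
neighbors (self excluded), c'_l[j] the same among label-negative drugs. The
ranking score is the normalized posterior, which exceeds 0.5 exactly when
the MAP rule outputs 1.

**FS-MLKNN.** Stage 1 keeps dimensions whose maximum mutual information
I(v_i; d_j) against any label exceeds σ = 0.001. Stage 2 runs a genetic
algorithm over binary chromosomes of the surviving dimensions; a
chromosome's fitness is the internal 5-fold-CV merged AUPR of MLKNN
restricted to its dimensions (population 100, at most 60 generations,
stopping when best fitness changes by less than 1e-6). The final model is
the average of five MLKNN submodels, one per internal fold.

**Ensemble.** One FS-MLKNN base predictor per feature type; the ensemble
score is Σ_i w_i S_i with nonnegative weights summing to 1, tuned by a GA
over the probability simplex to maximize out-of-fold merged AUPR on the
training drugs.

## Worked example

```python
from fsmlknn import CVPlan, generate, run_cv
from fsmlknn.synthetic import default_spec

bundle = generate(default_spec(seed=2))          # 200 drugs, 3 feature types, 30 labels
plan = CVPlan(n_folds=5, seed=2)
plain    = run_cv(bundle, "mlknn",    plan, feature_name="target")
selected = run_cv(bundle, "fs_mlknn", plan, feature_name="target")
print(f"MLKNN    AUPR {plain.mean['aupr']:.4f}")
print(f"FS-MLKNN AUPR {selected.mean['aupr']:.4f}")
```

prints

```
MLKNN    AUPR 0.3683
FS-MLKNN AUPR 0.3739
```

i.e. on a synthetic bundle whose labels are driven by 5 planted dimensions
per feature type, feature selection improves the merged out-of-fold AUPR of
the 5-fold cross-validation by discarding noise dimensions (a random ranker
would score ≈ the positive prevalence, here ≈ 0.23). The
`examples/` directory holds one short narrative script per capability:
dataset generation, MLKNN, feature selection, ensemble weighting,
cross-validation, and the independent train/test protocol. A thin CLI
(`fsmlknn simulate / data stats / mlknn predict / select / evaluate / cv /
independent`) wraps the same functions for shell use.

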