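"""Seeded generator of synthetic drug-feature / side-effect datasets.

The generator emulates the structure the method assumes: several sparse
binary feature matrices (one per feature type), thousands-of-labels-style
imbalance scaled down to desk size, and a planted subset of feature
dimensions statistically associated with the labels.  Noise dimensions are
independent Bernoulli draws; each planted dimension is wired to a few
labels, and an associated label fires with probability
``association_strength`` for drugs where any of its planted dimensions is
present (``label_base_rate`` otherwise), then every label cell is flipped
with probability ``noise_rate``.

The ground-truth record (planted dimensions per feature, dimension-to-label
association map) makes selection precision/recall computable, so the
mutual-information filter and the GA wrapper can be tested for parameter
recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import DatasetBundle, FeatureTable, LabelTable
from .errors import ValidationError

__all__ = ["FeatureSpec", "SyntheticSpec", "generate", "default_spec", "expected_label_prevalence"]


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic feature type: p binary dims at the given density, n_informative planted."""

    name: str
    p: int = 50
    density: float = 0.25
    n_informative: int = 5

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValidationError(f"{self.name}: p must be >= 1")
        if not 0 <= self.density <= 1:
            raise ValidationError(f"{self.name}: density must be in [0, 1]")
        if not 0 <= self.n_informative <= self.p:
            raise ValidationError(f"{self.name}: n_informative must be in [0, p]")


@dataclass(frozen=True)
class SyntheticSpec:
    n_drugs: int = 200
    feature_specs: tuple[FeatureSpec, ...] = (
        FeatureSpec("substructure"),
        FeatureSpec("target"),
        FeatureSpec("indication"),
    )
    q_labels: int = 30
    label_base_rate: float = 0.05
    association_strength: float = 0.6
    noise_rate: float = 0.02
    labels_per_planted_dim: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.q_labels < 1:
            raise ValidationError("need at least one drug and one label")
        for r, name in (
            (self.label_base_rate, "label_base_rate"),
            (self.association_strength, "association_strength"),
            (self.noise_rate, "noise_rate"),
        ):
            if not 0 <= r <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 1 <= self.labels_per_planted_dim <= self.q_labels:
            raise ValidationError("labels_per_planted_dim must be in [1, q_labels]")
        if not self.feature_specs:
            raise ValidationError("need at least one feature type")
        names = [fs.name for fs in self.feature_specs]
        if len(set(names)) != len(names):
            raise ValidationError("feature type names must be unique")


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The desk-scale default: 200 drugs, 3 feature types (p=50, 5 planted each), 30 labels."""
    return SyntheticSpec(seed=seed, **overrides)


def generate(spec: SyntheticSpec) -> DatasetBundle:
    """Generate a bundle; ``bundle.ground_truth`` records planted dims and associations."""
    rng = np.random.default_rng(spec.seed)
    n, q = spec.n_drugs, spec.q_labels
    drug_ids = [f"drug{i:04d}" for i in range(n)]
    label_ids = [f"se{l:03d}" for l in range(q)]

    features: dict[str, FeatureTable] = {}
    planted: dict[str, list[str]] = {}
    associations: dict[str, list[str]] = {}  # "<feature>:<dim>" -> label ids
    # per-label indicator: does any associated planted dim fire for each drug
    label_active = np.zeros((n, q), dtype=bool)

    for fs in spec.feature_specs:
        X = (rng.random((n, fs.p)) < fs.density).astype(np.int8)
        dim_ids = [f"{fs.name}_d{j:03d}" for j in range(fs.p)]
        planted_idx = rng.choice(fs.p, size=fs.n_informative, replace=False)
        planted[fs.name] = [dim_ids[j] for j in sorted(planted_idx)]
        for j in sorted(planted_idx):
            assoc = rng.choice(q, size=spec.labels_per_planted_dim, replace=False)
            associations[f"{fs.name}:{dim_ids[j]}"] = [label_ids[l] for l in sorted(assoc)]
            label_active[:, assoc] |= X[:, j].astype(bool)[:, None]
        features[fs.name] = FeatureTable(drug_ids, dim_ids, X, fs.name)

    p_fire = np.where(label_active, spec.association_strength, spec.label_base_rate)
    Y = (rng.random((n, q)) < p_fire).astype(np.int8)
    flips = rng.random((n, q)) < spec.noise_rate
    Y = np.where(flips, 1 - Y, Y).astype(np.int8)

    labels = LabelTable(drug_ids, label_ids, Y)
    ground_truth = {
        "planted_dims": planted,
        "associations": associations,
        "spec": spec,
    }
    return DatasetBundle(features, labels, ground_truth=ground_truth)


def expected_label_prevalence(spec: SyntheticSpec, bundle: DatasetBundle) -> np.ndarray:
    """Analytic expected prevalence per label, given the realized association map.

    For label l with associated planted dims having densities rho_1..rho_r:
    P(active) = 1 - prod(1 - rho_i); pre-noise rate = P(active)*strength +
    (1-P(active))*base; the noise flip then mixes toward 1/2.
    """
    density_by_dim = {}
    for fs in spec.feature_specs:
        for d in bundle.ground_truth["planted_dims"][fs.name]:
            density_by_dim[f"{fs.name}:{d}"] = fs.density
    p_inactive = np.ones(spec.q_labels)
    label_pos = {l: i for i, l in enumerate(bundle.labels.label_ids)}
    for key, lbls in bundle.ground_truth["associations"].items():
        for l in lbls:
            p_inactive[label_pos[l]] *= 1.0 - density_by_dim[key]
    p_active = 1.0 - p_inactive
    pre = p_active * spec.association_strength + p_inactive * spec.label_base_rate
    return pre * (1.0 - spec.noise_rate) + (1.0 - pre) * spec.noise_rate
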