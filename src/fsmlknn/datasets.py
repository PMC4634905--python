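"""Binary drug-representation matrices and the drug x side-effect label matrix.

Drugs are represented by one binary matrix per feature type (chemical
substructures, targets, enzymes, pathways, transporters, indications, ...):
cell (i, j) is 1 iff drug i carries component j.  Side effects form an
analogous binary drug x label matrix.  The on-disk dialect is tab-separated
text: one header row of dimension/label identifiers, first column of drug
identifiers, cells strictly "0"/"1".
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "LabelTable",
    "DatasetBundle",
    "read_feature_table",
    "read_label_table",
    "write_table",
    "align_bundle",
    "dataset_stats",
]


def _validate_binary_matrix(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 2 or values.size == 0:
        raise ValidationError(f"{what}: expected a nonempty 2-D matrix, got shape {values.shape}")
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(f"{what}: non-binary cell at row {i}, column {j}: {values[i, j]!r}")
    return values.astype(np.int8)


def _validate_unique(ids: list[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"{what}: duplicate identifier {x!r}")
        seen.add(x)
    return ids


@dataclass
class FeatureTable:
    """One feature type's binary drugs x dimensions matrix.

    Rows are drugs, columns are feature dimensions (e.g. the 881 PubChem
    substructure keys); ``values[i, j] == 1`` means drug i carries dimension j.
    """

    drug_ids: list[str]
    dim_ids: list[str]
    values: np.ndarray
    feature_name: str = "feature"

    def __post_init__(self) -> None:
        self.drug_ids = _validate_unique(self.drug_ids, f"{self.feature_name} drug_ids")
        self.dim_ids = _validate_unique(self.dim_ids, f"{self.feature_name} dim_ids")
        self.values = _validate_binary_matrix(self.values, self.feature_name)
        if self.values.shape != (len(self.drug_ids), len(self.dim_ids)):
            raise ValidationError(
                f"{self.feature_name}: matrix shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.dim_ids)} dims"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_dims(self) -> int:
        return len(self.dim_ids)

    def restrict_drugs(self, drug_ids: list[str]) -> "FeatureTable":
        pos = {d: i for i, d in enumerate(self.drug_ids)}
        idx = [pos[d] for d in drug_ids]
        return FeatureTable(list(drug_ids), list(self.dim_ids), self.values[idx], self.feature_name)

    def restrict_dims(self, dim_ids: list[str]) -> "FeatureTable":
        pos = {d: i for i, d in enumerate(self.dim_ids)}
        missing = [d for d in dim_ids if d not in pos]
        if missing:
            raise ValidationError(f"{self.feature_name}: missing dimensions {missing[:5]}")
        idx = [pos[d] for d in dim_ids]
        return FeatureTable(list(self.drug_ids), list(dim_ids), self.values[:, idx], self.feature_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids, columns=self.dim_ids)


@dataclass
class LabelTable:
    """Binary drugs x side-effect matrix: ``values[i, l] == 1`` iff drug i induces side effect l."""

    drug_ids: list[str]
    label_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _validate_unique(self.drug_ids, "label drug_ids")
        self.label_ids = _validate_unique(self.label_ids, "label_ids")
        self.values = _validate_binary_matrix(self.values, "labels")
        if self.values.shape != (len(self.drug_ids), len(self.label_ids)):
            raise ValidationError(
                f"labels: matrix shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.label_ids)} labels"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_labels(self) -> int:
        return len(self.label_ids)

    def restrict_drugs(self, drug_ids: list[str]) -> "LabelTable":
        pos = {d: i for i, d in enumerate(self.drug_ids)}
        idx = [pos[d] for d in drug_ids]
        return LabelTable(list(drug_ids), list(self.label_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids, columns=self.label_ids)


@dataclass
class DatasetBundle:
    """Aligned feature tables (one per feature type) plus the label table.

    Every feature table shares the label table's drug order.
    """

    features: dict[str, FeatureTable]
    labels: LabelTable
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name, ft in self.features.items():
            if ft.drug_ids != self.labels.drug_ids:
                raise ValidationError(f"feature table {name!r} drug order differs from labels")

    @property
    def drug_ids(self) -> list[str]:
        return self.labels.drug_ids

    def digest(self) -> str:
        """SHA-256 over matrices and identifiers, for run manifests."""
        h = hashlib.sha256()
        for name in sorted(self.features):
            ft = self.features[name]
            h.update(name.encode())
            h.update("\x00".join(ft.drug_ids + ft.dim_ids).encode())
            h.update(np.ascontiguousarray(ft.values).tobytes())
        h.update("\x00".join(self.labels.drug_ids + self.labels.label_ids).encode())
        h.update(np.ascontiguousarray(self.labels.values).tobytes())
        return h.hexdigest()


def _read_matrix(path, what: str) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValidationError(f"{what}: file {path} has a header but no data rows")
    drug_ids = _validate_unique([str(x) for x in df.index], f"{what} drug_ids")
    col_ids = _validate_unique([str(x) for x in df.columns], f"{what} column ids")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=np.int8)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        ok = np.isin(col, ("0", "1"))
        if not ok.all():
            i = int(np.argmin(ok))
            raise ValidationError(
                f"{what}: non-binary cell at drug {drug_ids[i]!r}, column {col_ids[j]!r}: {col[i]!r}"
            )
        values[:, j] = col == "1"
    return drug_ids, col_ids, values


def read_feature_table(path, feature_name: str = "feature") -> FeatureTable:
    """Read one feature type's binary matrix from tab-separated text."""
    drug_ids, dim_ids, values = _read_matrix(path, feature_name)
    return FeatureTable(drug_ids, dim_ids, values, feature_name)


def read_label_table(path) -> LabelTable:
    """Read the drug x side-effect binary matrix from tab-separated text."""
    drug_ids, label_ids, values = _read_matrix(path, "labels")
    return LabelTable(drug_ids, label_ids, values)


def write_table(table: FeatureTable | LabelTable, path) -> None:
    """Write a table in the TSV dialect (lossless round-trip with the readers)."""
    table.to_frame().to_csv(path, sep="\t")


def align_bundle(features: list[FeatureTable], labels: LabelTable) -> DatasetBundle:
    """Restrict all tables to the common drugs, in the label table's order.

    Drugs present in a feature table but absent from the labels (or vice versa)
    are dropped with a log message, not an error: benchmark files differ in
    coverage.  An empty intersection raises :class:`AlignmentError`.
    """
    if not features:
        raise ValidationError("align_bundle: need at least one feature table")
    common = set(labels.drug_ids)
    for ft in features:
        common &= set(ft.drug_ids)
    if not common:
        raise AlignmentError("no drug identifiers shared by all tables")
    order = [d for d in labels.drug_ids if d in common]
    dropped = sorted(set(labels.drug_ids) - common)
    for ft in features:
        dropped += sorted(set(ft.drug_ids) - common)
    if dropped:
        logger.warning("align_bundle: dropped %d drug rows absent from some table", len(dropped))
    aligned = {ft.feature_name: ft.restrict_drugs(order) for ft in features}
    if len(aligned) != len(features):
        raise ValidationError("feature tables must have distinct feature_name values")
    return DatasetBundle(aligned, labels.restrict_drugs(order))


def dataset_stats(bundle: DatasetBundle) -> dict:
    """Descriptive statistics of a dataset bundle.

    Reports drug/label counts, per-feature dimensionality, how many side-effect
    columns have no positive drug at all (such labels have undefined per-label
    AUPR), and the mean number of side effects per drug (as float and rounded
    to the nearest integer, the form in which such counts are usually quoted).
    """
    Y = bundle.labels.values
    col_pos = Y.sum(axis=0)
    mean_labels = float(Y.sum(axis=1).mean())
    return {
        "n_drugs": bundle.labels.n_drugs,
        "n_labels": bundle.labels.n_labels,
        "n_dims": {name: ft.n_dims for name, ft in bundle.features.items()},
        "n_all_zero_label_columns": int((col_pos == 0).sum()),
        "n_labels_with_positive": int((col_pos > 0).sum()),
        "mean_labels_per_drug": mean_labels,
        "mean_labels_per_drug_rounded": int(round(mean_labels)),
    }
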