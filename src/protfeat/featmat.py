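"""Labeled feature matrix: assembly, standardization, statistics, persistence.

The matrix is a pandas DataFrame with protein ids as the row index and
feature names as columns; a :class:`~protfeat.seqdata.Labeling` can be
attached for class-aware operations.  All statistics here are exploratory:
Welch t per feature, per-class histograms/scatter data, and independent
average-linkage hierarchical clustering of rows and columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .seqdata import Labeling


@dataclass
class FeatureMatrix:
    data: pd.DataFrame
    labeling: Labeling | None = None
    #: provenance of each feature column (category name or "user")
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate protein ids in feature matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature names in feature matrix")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in features: {bad}")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def add_block(self, block: pd.DataFrame, provenance: str) -> None:
        """Append feature columns computed for the same proteins."""
        if not block.index.equals(self.data.index) and len(self.data.columns):
            raise ValueError("block row index does not match the matrix")
        clash = set(block.columns) & set(self.data.columns)
        if clash:
            raise ValueError(f"duplicate feature names: {sorted(clash)}")
        self.data = block.copy() if self.data.empty else pd.concat(
            [self.data, block], axis=1)
        for c in block.columns:
            self.provenance[c] = provenance
        self.__post_init__()


def standardize(fm: FeatureMatrix) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Standardize each column to mean 0, population sd 1.

    Returns the standardized matrix and a (mean, sd) table, so test data
    can later be transformed with identical parameters.  Constant columns
    are dropped with a warning naming them.
    """
    X = fm.data
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    constant = sds[sds == 0.0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant feature columns: {constant}")
        X = X.drop(columns=constant)
        means = means.drop(constant)
        sds = sds.drop(constant)
    Z = (X - means) / sds
    params = pd.DataFrame({"mean": means, "sd": sds})
    out = FeatureMatrix(Z, labeling=fm.labeling,
                        provenance={c: fm.provenance.get(c, "?") for c in Z.columns})
    return out, params


def apply_standardization(data: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Transform ``data`` with previously estimated (mean, sd) parameters."""
    missing = [c for c in params.index if c not in data.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = data[params.index]
    return (X - params["mean"]) / params["sd"]


def t_statistics(fm: FeatureMatrix, labeling: Labeling | None = None) -> pd.DataFrame:
    """Welch two-sample t per feature for a 2-class labeling.

    Sign convention: t > 0 means a larger mean in the first class name.
    The returned table is sorted ascending by t and carries per-class
    means and standard deviations (sample sd, ddof=1).
    """
    labeling = labeling or fm.labeling
    if labeling is None:
        raise ValueError("no labeling attached or given")
    if len(labeling.class_names) != 2:
        raise ValueError(
            f"t-statistics need exactly 2 classes, got {len(labeling.class_names)}"
        )
    c1, c2 = labeling.class_names
    ids1 = [i for i in fm.ids if labeling.assignments.get(i) == c1]
    ids2 = [i for i in fm.ids if labeling.assignments.get(i) == c2]
    if len(ids1) < 2 or len(ids2) < 2:
        raise ValueError("each class needs at least 2 labeled proteins")
    X1 = fm.data.loc[ids1].to_numpy(float)
    X2 = fm.data.loc[ids2].to_numpy(float)
    n1, n2 = len(ids1), len(ids2)
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    v1, v2 = X1.var(axis=0, ddof=1), X2.var(axis=0, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    table = pd.DataFrame(
        {
            "t": t,
            f"mean_{c1}": m1, f"mean_{c2}": m2,
            f"sd_{c1}": np.sqrt(v1), f"sd_{c2}": np.sqrt(v2),
        },
        index=pd.Index(fm.feature_names, name="feature"),
    )
    return table.sort_values("t", kind="mergesort")


def cluster_order(fm: FeatureMatrix) -> tuple[list[str], list[str]]:
    """Leaf orders of average-linkage/Euclidean clustering of rows and columns.

    Rows and columns are clustered independently on the standardized
    matrix; class labels never enter the distance computation.
    """
    if len(fm.ids) < 2:
        raise ValueError("clustering needs at least 2 rows")
    z, _ = standardize(fm)
    X = z.data.to_numpy(float)
    row_order = [z.ids[i] for i in leaves_list(linkage(X, method="average"))]
    if X.shape[1] >= 2:
        col_order = [z.feature_names[i]
                     for i in leaves_list(linkage(X.T, method="average"))]
    else:
        col_order = list(z.feature_names)
    return row_order, col_order


def histogram_data(fm: FeatureMatrix, labeling: Labeling, feature: str,
                   bins: int = 10, standardized: bool = False):
    """Per-class histogram counts with bin edges shared across classes."""
    if feature not in fm.data.columns:
        raise KeyError(f"unknown feature {feature!r}")
    data = fm.data
    if standardized:
        data = standardize(fm)[0].data
        if feature not in data.columns:
            raise KeyError(f"feature {feature!r} was constant and dropped")
    values = data[feature]
    labeled = [i for i in fm.ids if i in labeling.assignments]
    edges = np.histogram_bin_edges(values.loc[labeled], bins=bins)
    counts = {}
    for cls in labeling.class_names:
        ids = [i for i in labeled if labeling.assignments[i] == cls]
        counts[cls], _ = np.histogram(values.loc[ids], bins=edges)
    return edges, counts


def scatter_data(fm: FeatureMatrix, labeling: Labeling, f1: str,
                 f2: str) -> pd.DataFrame:
    """Labeled (f1, f2) point pairs for all labeled proteins."""
    for f in (f1, f2):
        if f not in fm.data.columns:
            raise KeyError(f"unknown feature {f!r}")
    ids = [i for i in fm.ids if i in labeling.assignments]
    return pd.DataFrame(
        {
            "x": fm.data.loc[ids, f1].to_numpy(),
            "y": fm.data.loc[ids, f2].to_numpy(),
            "label": [labeling.assignments[i] for i in ids],
        },
        index=pd.Index(ids, name="id"),
    )


def merge(fm: FeatureMatrix, user_tsv: str | Path) -> FeatureMatrix:
    """Append user-computed feature columns from a TSV file.

    The TSV must have an id column first; every id must exist in the
    matrix, and feature names must not collide with existing ones.
    """
    table = pd.read_csv(user_tsv, sep="\t", index_col=0,
                        float_precision="round_trip")
    missing = [i for i in table.index if i not in set(fm.ids)]
    if missing:
        raise ValueError(f"user features reference unknown proteins: {missing}")
    absent = [i for i in fm.ids if i not in set(table.index)]
    if absent:
        raise ValueError(f"user features missing for proteins: {absent}")
    block = table.loc[fm.ids].astype(float)
    out = FeatureMatrix(fm.data.copy(), labeling=fm.labeling,
                        provenance=dict(fm.provenance))
    out.add_block(block, provenance="user")
    return out


# ---------------------------------------------------------------------------
# persistence (TSV + JSON sidecar, text only, full float precision)


def save(fm: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    fm.data.to_csv(path, sep="\t", float_format="%.17g")
    sidecar = {
        "provenance": fm.provenance,
        "standardization": "population-sd",
        "n_proteins": len(fm.ids),
        "n_features": len(fm.feature_names),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2) + "\n")


def load(path: str | Path, labeling: Labeling | None = None) -> FeatureMatrix:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    provenance = {}
    meta = path.with_suffix(path.suffix + ".meta.json")
    if meta.exists():
        provenance = json.loads(meta.read_text()).get("provenance", {})
    return FeatureMatrix(data, labeling=labeling, provenance=provenance)


def empty(ids: list[str]) -> FeatureMatrix:
    return FeatureMatrix(pd.DataFrame(index=pd.Index(ids, name="id")))
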