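"""Case x feature tables: the tabular hand-off between extraction and modelling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "prepare_table"]


@dataclass
class FeatureTable:
    """A numeric case x feature matrix with binary outcome labels (1 = pCR).

    ``values`` is (n_cases, n_features); ``feature_ids`` are the string forms
    of the structured feature identifiers (or plain names for synthetic
    fast-mode tables). Modelling stages require a table with no missing
    values (see :func:`prepare_table`) and both label classes present.
    """

    values: np.ndarray
    feature_ids: list[str]
    labels: np.ndarray
    case_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D case x feature matrix")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids must match the number of columns")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels must align with rows")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        if not self.case_ids:
            self.case_ids = [f"case_{i:04d}" for i in range(self.values.shape[0])]
        elif len(self.case_ids) != self.values.shape[0]:
            raise ValueError("case_ids must align with rows")

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids, index=self.case_ids)
        df.insert(0, "label", self.labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "label") -> "FeatureTable":
        labels = df[label_col].to_numpy()
        feats = df.drop(columns=[label_col])
        return cls(
            feats.to_numpy(dtype=float),
            [str(c) for c in feats.columns],
            labels,
            [str(i) for i in df.index],
        )

    def subset(self, feature_ids: list[str]) -> "FeatureTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return FeatureTable(
            self.values[:, idx], list(feature_ids), self.labels.copy(), list(self.case_ids)
        )

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        """Merge two cohorts sharing the same feature roster (row-wise)."""
        if self.feature_ids != other.feature_ids:
            raise ValueError("feature rosters differ; cannot merge cohorts")
        return FeatureTable(
            np.vstack([self.values, other.values]),
            list(self.feature_ids),
            np.concatenate([self.labels, other.labels]),
            list(self.case_ids) + list(other.case_ids),
        )


def prepare_table(
    table: FeatureTable, max_missing_frac: float = 0.2
) -> tuple[FeatureTable, dict]:
    """Drop mostly-missing features and median-impute the rest.

    Features missing (NaN sentinel) in more than ``max_missing_frac`` of the
    cases are dropped; remaining missing entries are imputed with the
    feature's median over the observed cases. Constant features are dropped
    too (they carry no signal and break normality tests). Returns the clean
    table and a small provenance dict for the run report.
    """
    X = table.values
    miss = np.isnan(X).mean(axis=0)
    keep = miss <= max_missing_frac
    X = X[:, keep]
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    med = np.nanmedian(X, axis=0)
    rows, cols = np.nonzero(np.isnan(X))
    X = X.copy()
    X[rows, cols] = med[cols]
    nonconst = np.nanstd(X, axis=0) > 0
    dropped_const = int((~nonconst).sum())
    X = X[:, nonconst]
    kept_ids = [f for f, k in zip(kept_ids, nonconst) if k]
    info = {
        "n_features_in": table.n_features,
        "n_dropped_missing": int((~keep).sum()),
        "n_dropped_constant": dropped_const,
        "n_imputed_values": int(len(rows)),
        "max_missing_frac": max_missing_frac,
    }
    return FeatureTable(X, kept_ids, table.labels.copy(), list(table.case_ids)), info
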