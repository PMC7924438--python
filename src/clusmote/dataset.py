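"""Labeled feature datasets: the common currency between modules.

A :class:`LabeledDataset` holds a numeric feature matrix, binary labels
(1 = positive / minority / epitope class, 0 = negative / majority), an
optional group identifier per row (standing in for antigen–antibody
complexes in grouped cross-validation), and a per-row provenance tag
distinguishing original rows from synthetic (interpolated) ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORIGINAL = "original"
SYNTHETIC = "synthetic"


@dataclass
class LabeledDataset:
    X: np.ndarray
    y: np.ndarray
    group: np.ndarray | None = None
    provenance: np.ndarray | None = None
    feature_names: list[str] | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        self.y = np.asarray(self.y)
        if len(self.y) != self.X.shape[0]:
            raise ValueError(
                f"label count {len(self.y)} != row count {self.X.shape[0]}"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite entries")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        self.y = self.y.astype(int)
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != len(self.y):
                raise ValueError("group length mismatch")
        if self.provenance is None:
            self.provenance = np.full(len(self.y), ORIGINAL, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if len(self.provenance) != len(self.y):
                raise ValueError("provenance length mismatch")
        if self.feature_names is None:
            self.feature_names = [f"f{i + 1}" for i in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_positive(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == 0).sum())

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        """Row subset (copy); attrs are dropped, they describe the full set."""
        idx = np.asarray(idx)
        return LabeledDataset(
            X=self.X[idx].copy(),
            y=self.y[idx].copy(),
            group=None if self.group is None else self.group[idx].copy(),
            provenance=self.provenance[idx].copy(),
            feature_names=list(self.feature_names),
        )

    # -- CSV round-trip --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.y
        if self.group is not None:
            df["group"] = self.group
        df["provenance"] = self.provenance
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        if "label" not in df.columns:
            raise ValueError("missing required 'label' column")
        feat_cols = [c for c in df.columns if c not in ("label", "group", "provenance")]
        return cls(
            X=df[feat_cols].to_numpy(dtype=float),
            y=df["label"].to_numpy(),
            group=df["group"].to_numpy() if "group" in df.columns else None,
            provenance=(
                df["provenance"].to_numpy() if "provenance" in df.columns else None
            ),
            feature_names=feat_cols,
        )

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        return cls.from_frame(pd.read_csv(path))
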