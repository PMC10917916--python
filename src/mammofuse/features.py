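"""Labeled feature-matrix container with TSV round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """N x p real matrix with per-row sample IDs and per-column feature IDs."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        n, p = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"f{j:05d}" for j in range(p)]
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("ID lengths must match matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset_columns(self, mask_or_idx) -> "FeatureMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[j] for j in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(dtype=np.float64),
                   sample_ids=[str(i) for i in df.index],
                   feature_ids=[str(c) for c in df.columns])
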