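"""Named feature matrices and train-fitted [0,1] scaling."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "MinMaxScaler"]


@dataclass
class FeatureMatrix:
    """Trials x named-features table."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise ValueError("feature count does not match name count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @staticmethod
    def hstack(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        n = {p.n_trials for p in parts}
        if len(n) != 1:
            raise ValueError(f"trial-count mismatch across feature blocks: {sorted(n)}")
        return FeatureMatrix(
            np.hstack([p.values for p in parts]),
            [name for p in parts for name in p.names],
        )

    def subset(self, idx: np.ndarray | list[int]) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(self.values[:, idx], [self.names[i] for i in idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @staticmethod
    def from_tsv(path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        return FeatureMatrix(df.to_numpy(dtype=float), list(df.columns))


@dataclass
class MinMaxScaler:
    """Column-wise min-max map to [0,1], fitted on training trials only.

    Constant columns map to 0. Test values outside the training range scale
    past [0,1] without clipping, so the transform stays affine.
    """

    mins: np.ndarray = field(default=None)  # type: ignore[assignment]
    ranges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def fit(self, fm: FeatureMatrix) -> "MinMaxScaler":
        self.mins = fm.values.min(axis=0)
        span = fm.values.max(axis=0) - self.mins
        self.ranges = np.where(span > 0, span, np.inf)  # constant column -> 0
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if self.mins is None:
            raise RuntimeError("scaler not fitted")
        return FeatureMatrix((fm.values - self.mins) / self.ranges, list(fm.names))

    def fit_transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        return self.fit(fm).transform(fm)
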