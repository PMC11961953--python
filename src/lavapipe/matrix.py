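"""The feature-by-sample count container shared by all counting and testing
stages, with TSV round-trip helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Integer feature x sample counts plus per-sample library sizes.

    ``counts``: DataFrame with feature ids as index and sample ids as columns.
    ``library_sizes``: reads per sample used as normalisation denominators
    (for RPM this is total genome-mapped reads, which may exceed column sums
    when counting is restricted to a feature subset).  ``feature_lengths``:
    optional per-feature lengths in bases, required for TPM.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes, dtype=float).reindex(
                self.counts.columns
            )
            if self.library_sizes.isna().any():
                missing = self.library_sizes.index[self.library_sizes.isna()].tolist()
                raise ValueError(f"library_sizes missing for samples {missing}")
        if self.feature_lengths is not None:
            self.feature_lengths = pd.Series(self.feature_lengths, dtype=float).reindex(
                self.counts.index
            )

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_features(self, features) -> "CountMatrix":
        features = [f for f in features if f in self.counts.index]
        lengths = (
            self.feature_lengths.loc[features] if self.feature_lengths is not None else None
        )
        return CountMatrix(
            self.counts.loc[features], self.library_sizes.copy(), lengths
        )

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(samples)],
            self.library_sizes.loc[list(samples)],
            None if self.feature_lengths is None else self.feature_lengths.copy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write counts with library sizes as a trailing '#library_size' row."""
        out = self.counts.copy()
        out.loc["#library_size"] = self.library_sizes.values
        out.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path, lengths: pd.Series | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        lib = None
        if "#library_size" in df.index:
            lib = df.loc["#library_size"].astype(float)
            df = df.drop(index="#library_size")
        counts = df.astype(np.int64) if np.allclose(df.values, np.round(df.values)) else df
        return cls(counts, lib, lengths)
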