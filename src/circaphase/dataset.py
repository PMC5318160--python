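"""Expression dataset container and plain-text I/O.

An :class:`ExpressionDataset` holds a features x samples matrix of log2
abundance values, per-sample metadata (participant, sleep condition, batch,
clock time and — once melatonin has been processed — the assigned circadian
phase), and an optional parallel flag matrix marking unreliable measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("in_phase", "out_of_phase", "tsd_no_debt", "tsd_debt")

METADATA_COLUMNS = [
    "participant_id",
    "condition",
    "batch",
    "clock_time_h",
    "phase_deg",
]


@dataclass
class ExpressionDataset:
    """Log2 expression matrix with sample metadata and optional flags.

    values: DataFrame indexed by feature_id, one column per sample_id.
    samples: DataFrame indexed by sample_id with columns participant_id,
        condition, batch, clock_time_h and phase_deg (NaN when unassigned).
    flags: optional {0,1} DataFrame with the same shape/labels as values.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample_ids in expression matrix")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature_ids in expression matrix")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples missing metadata: {list(missing)[:5]}")
        # align metadata rows to matrix column order
        self.samples = self.samples.loc[self.values.columns]
        for col in METADATA_COLUMNS:
            if col not in self.samples.columns:
                self.samples[col] = np.nan
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise ValueError("flags shape differs from values shape")
            self.flags = self.flags.loc[self.values.index, self.values.columns]

    # -- basic views ------------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def participants(self) -> list:
        return sorted(self.samples["participant_id"].unique())

    def phases(self) -> pd.Series:
        """Assigned circadian phases (degrees); NaN where unassigned."""
        return self.samples["phase_deg"]

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        sample_ids = list(sample_ids)
        return ExpressionDataset(
            values=self.values[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
            flags=None if self.flags is None else self.flags[sample_ids].copy(),
        )

    def subset_features(self, feature_ids) -> "ExpressionDataset":
        feature_ids = list(feature_ids)
        return ExpressionDataset(
            values=self.values.loc[feature_ids].copy(),
            samples=self.samples.copy(),
            flags=None if self.flags is None else self.flags.loc[feature_ids].copy(),
        )

    def matrix(self) -> np.ndarray:
        """Samples x features array (the regression orientation)."""
        return self.values.to_numpy().T

    # -- I/O ---------------------------------------------------------------

    def write(self, expression_tsv, metadata_tsv, flags_tsv=None) -> None:
        self.values.to_csv(expression_tsv, sep="\t", index_label="feature_id")
        self.samples.to_csv(metadata_tsv, sep="\t", index_label="sample_id")
        if flags_tsv is not None and self.flags is not None:
            self.flags.astype(int).to_csv(flags_tsv, sep="\t", index_label="feature_id")


def read_expression_dataset(
    expression_tsv, metadata_tsv, flags_tsv=None
) -> ExpressionDataset:
    """Load an expression TSV (+ metadata, + optional flags) from disk."""
    values = pd.read_csv(expression_tsv, sep="\t", index_col="feature_id")
    samples = pd.read_csv(metadata_tsv, sep="\t", index_col="sample_id")
    flags = None
    if flags_tsv is not None and Path(flags_tsv).exists():
        flags = pd.read_csv(flags_tsv, sep="\t", index_col="feature_id")
    return ExpressionDataset(values=values, samples=samples, flags=flags)
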