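"""Preprocessing: quantile normalization to a frozen reference, replicate
averaging, flag-based filtering, and train-set z-scoring.

The pipeline is deliberately asymmetric between training and
validation/deployment data: the reference quantiles and the per-feature
z-score statistics are computed on the training set only, then applied
unchanged to any later sample — including a single clinical sample — so that
new data never influence the normalization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quantile normalization to a stored reference


@dataclass
class ReferenceQuantiles:
    """Reference array of empirical quantiles (non-decreasing)."""

    quantiles: np.ndarray

    def __post_init__(self) -> None:
        self.quantiles = np.asarray(self.quantiles, dtype=float)
        if np.any(np.diff(self.quantiles) < 0):
            raise ValueError("reference quantiles must be non-decreasing")

    def __len__(self) -> int:
        return self.quantiles.size

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"quantiles": self.quantiles.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "ReferenceQuantiles":
        with open(path) as fh:
            return cls(np.asarray(json.load(fh)["quantiles"]))


def build_reference_quantiles(training: ExpressionDataset) -> ReferenceQuantiles:
    """Mean of the sorted per-sample value vectors of the training set."""
    if training.n_samples == 0:
        raise ValueError("cannot build reference quantiles from an empty dataset")
    sorted_cols = np.sort(training.values.to_numpy(), axis=0)
    return ReferenceQuantiles(sorted_cols.mean(axis=1))


def _quantile_map_column(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace the value of rank k by ref[k]; ties get the mean of the tied
    reference values."""
    order = np.argsort(col, kind="mergesort")
    out = np.empty_like(ref)
    out[order] = ref
    sorted_vals = col[order]
    # average the reference over runs of tied input values
    i = 0
    n = col.size
    while i < n:
        j = i + 1
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        if j - i > 1:
            out[order[i:j]] = ref[i:j].mean()
        i = j
    return out


def quantile_normalize_to_reference(
    data: ExpressionDataset, ref: ReferenceQuantiles
) -> ExpressionDataset:
    """Quantile-normalize each sample independently against the reference.

    Within each sample the k-th smallest value is replaced by the k-th
    reference quantile, so validation samples never influence the reference.
    """
    if data.n_features != len(ref):
        raise ValueError(
            f"feature count {data.n_features} != reference length {len(ref)}"
        )
    arr = data.values.to_numpy()
    out = np.column_stack(
        [_quantile_map_column(arr[:, j], ref.quantiles) for j in range(arr.shape[1])]
    )
    values = pd.DataFrame(out, index=data.values.index, columns=data.values.columns)
    return ExpressionDataset(values=values, samples=data.samples.copy(), flags=data.flags)


# ---------------------------------------------------------------------------
# technical replicates and flag filters


def average_technical_replicates(
    data: ExpressionDataset, probe_groups: dict
) -> ExpressionDataset:
    """Collapse technically replicated probes to one row per group.

    Values are averaged; flags are averaged then binarized at >= 0.5.
    `probe_groups` maps every feature_id to a group id (typically the gene
    or consolidated probe name).
    """
    missing = [f for f in data.feature_ids if f not in probe_groups]
    if missing:
        raise ValueError(f"features without a group assignment: {missing[:5]}")
    groups = pd.Series({f: probe_groups[f] for f in data.feature_ids}, name="group")
    # preserve first-appearance order of groups
    seen = groups[~groups.duplicated()].tolist()
    values = data.values.groupby(groups, sort=False).mean().loc[seen]
    values.index.name = None
    flags = None
    if data.flags is not None:
        flags = (
            data.flags.groupby(groups, sort=False).mean().loc[seen] >= 0.5
        ).astype(int)
        flags.index.name = None
    return ExpressionDataset(values=values, samples=data.samples.copy(), flags=flags)


def filter_flagged(
    data: ExpressionDataset,
    sample_max_flagged: float = 0.30,
    feature_max_flagged: float = 0.10,
) -> ExpressionDataset:
    """Drop flagged-heavy samples, then flagged-heavy features.

    Samples with strictly more than `sample_max_flagged` of their features
    flagged are removed first; then features flagged in strictly more than
    `feature_max_flagged` of the remaining samples are removed.
    """
    if data.flags is None:
        raise ValueError("dataset has no flag matrix")
    flags = data.flags.astype(float)
    sample_frac = flags.mean(axis=0)
    keep_samples = sample_frac.index[sample_frac <= sample_max_flagged]
    if len(keep_samples) == 0:
        raise ValueError("all samples exceeded the flagged-feature threshold")
    n_samples_dropped = data.n_samples - len(keep_samples)
    feature_frac = flags[keep_samples].mean(axis=1)
    keep_features = feature_frac.index[feature_frac <= feature_max_flagged]
    n_features_dropped = data.n_features - len(keep_features)
    logger.info(
        "filter_flagged: dropped %d samples (>%.0f%% flagged) and %d features "
        "(flagged in >%.0f%% of samples)",
        n_samples_dropped,
        100 * sample_max_flagged,
        n_features_dropped,
        100 * feature_max_flagged,
    )
    return ExpressionDataset(
        values=data.values.loc[keep_features, keep_samples].copy(),
        samples=data.samples.loc[keep_samples].copy(),
        flags=data.flags.loc[keep_features, keep_samples].copy(),
    )


# ---------------------------------------------------------------------------
# z-scoring with stored training statistics


@dataclass
class FeatureScaler:
    """Per-feature mean/SD computed on a training set, applied to any data."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            raise ValueError("scaler SD must be positive for every feature")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.mean.index)

    def transform_frame(self, values: pd.DataFrame) -> pd.DataFrame:
        """Z-score a features x samples frame using the stored statistics."""
        missing = self.mean.index.difference(values.index)
        if len(missing):
            raise KeyError(f"scaler features absent from data: {list(missing)[:5]}")
        sub = values.loc[self.mean.index]
        return sub.sub(self.mean, axis=0).div(self.sd, axis=0)

    def transform_vector(self, sample: pd.Series) -> pd.Series:
        """Z-score a single sample (indexed by feature_id)."""
        missing = self.mean.index.difference(sample.index)
        if len(missing):
            raise KeyError(f"scaler features absent from sample: {list(missing)[:5]}")
        return (sample.loc[self.mean.index] - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {
            "features": list(self.mean.index),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        idx = pd.Index(d["features"])
        return cls(
            mean=pd.Series(d["mean"], index=idx), sd=pd.Series(d["sd"], index=idx)
        )


def fit_feature_scaler(training: ExpressionDataset | pd.DataFrame) -> FeatureScaler:
    """Per-feature mean and sample SD on the training set.

    Constant features (SD = 0) cannot be z-scored and are excluded with a
    warning; downstream models simply never see them.
    """
    values = training.values if isinstance(training, ExpressionDataset) else training
    if values.shape[1] < 2:
        raise ValueError("need at least two training samples to fit a scaler")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        warnings.warn(
            f"excluding {len(constant)} constant feature(s) from scaler",
            UserWarning,
            stacklevel=2,
        )
        mean = mean.drop(constant)
        sd = sd.drop(constant)
    return FeatureScaler(mean=mean, sd=sd)


def apply_scaler(scaler: FeatureScaler, data: ExpressionDataset) -> ExpressionDataset:
    """Z-score a dataset with stored training statistics (features the scaler
    never saw are dropped implicitly by selection)."""
    return ExpressionDataset(
        values=scaler.transform_frame(data.values),
        samples=data.samples.copy(),
        flags=None if data.flags is None else data.flags.loc[scaler.feature_ids],
    )


def apply_batch_correction_hook(
    data: ExpressionDataset, corrected_values: pd.DataFrame | None = None
) -> ExpressionDataset:
    """Pass-through hook for externally batch-corrected matrices.

    Batch correction itself (e.g. an empirical-Bayes method run elsewhere)
    is out of scope; this hook accepts a corrected matrix with identical
    labels and swaps it in, or returns the data unchanged.
    """
    if corrected_values is None:
        return data
    if not corrected_values.index.equals(data.values.index) or not (
        corrected_values.columns.equals(data.values.columns)
    ):
        raise ValueError("corrected matrix labels differ from the dataset")
    return ExpressionDataset(
        values=corrected_values.copy(), samples=data.samples.copy(), flags=data.flags
    )
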