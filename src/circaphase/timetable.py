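"""Molecular timetable: cosinor screening and look-up-table phase prediction.

Time-indicating features are screened by correlating each feature's
abundance, across samples ordered by assigned circadian phase, with the
best-fitting 24-h cosine.  Features exceeding the correlation cutoff in every
sleep condition and in the pooled series form a look-up table of expected
(unit-cosine) values over a dense phase grid; a new sample's phase is the
grid phase whose template correlates best with its z-scored, mean-centred
abundance vector.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import UndefinedPhaseError, from_cartesian, to_cartesian
from .dataset import CONDITIONS, ExpressionDataset
from .preprocess import FeatureScaler, fit_feature_scaler

logger = logging.getLogger(__name__)


class EmptyModelError(ValueError):
    """No feature survived the rhythmicity screen."""


class UndefinedCorrelationError(ValueError):
    """Sample vector constant across the model features; correlation undefined."""


# ---------------------------------------------------------------------------
# cosinor fitting


@dataclass
class CosinorFit:
    """Least-squares fit of a fixed 24-h-period cosine to abundance vs phase.

    peak_phase_deg is the acrophase (phase of maximum) of the fitted cosine;
    r is the Pearson correlation between abundance and cos(theta - peak).
    Constant abundance has no defined peak; by convention r = 0 and
    peak_phase_deg is NaN.
    """

    peak_phase_deg: float
    r: float
    amplitude: float
    mesor: float


def fit_cosinor(phases_deg, abundance) -> CosinorFit:
    """Closed-form cosinor: regress abundance on cos(theta) and sin(theta).

    The fitted a*cos + b*sin equals A*cos(theta - phi) with A = hypot(a, b)
    and phi = atan2-style angle of (a, b), so the acrophase comes straight
    from the coefficients.
    """
    theta = np.asarray(phases_deg, dtype=float)
    y = np.asarray(abundance, dtype=float)
    if theta.size < 4:
        raise ValueError("cosinor needs at least 4 points")
    if np.allclose(y, y[0]):
        return CosinorFit(peak_phase_deg=float("nan"), r=0.0, amplitude=0.0, mesor=float(y[0]))
    c, s = to_cartesian(theta)
    X = np.column_stack([np.ones_like(c), c, s])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, a, b = (float(v) for v in coef)
    amplitude = float(np.hypot(a, b))
    if amplitude == 0.0:
        return CosinorFit(peak_phase_deg=float("nan"), r=0.0, amplitude=0.0, mesor=mesor)
    peak = from_cartesian(a, b)
    template = np.cos(np.deg2rad(theta - peak))
    if np.std(template) == 0.0:
        return CosinorFit(peak_phase_deg=peak, r=0.0, amplitude=amplitude, mesor=mesor)
    r = float(np.corrcoef(y, template)[0, 1])
    return CosinorFit(peak_phase_deg=peak, r=r, amplitude=amplitude, mesor=mesor)


def _cosinor_stats_matrix(values: pd.DataFrame, phases: np.ndarray):
    """Vectorized cosinor over all features at once.

    Returns (peak_deg, r) arrays aligned with values.index.  values is
    features x samples; phases aligns with its columns.
    """
    c, s = to_cartesian(phases)
    X = np.column_stack([np.ones_like(c), c, s])  # m x 3
    Y = values.to_numpy().T  # m x N
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)  # 3 x N
    a, b = coef[1], coef[2]
    amp = np.hypot(a, b)
    peak = np.degrees(np.arctan2(b, a)) % 360.0
    # Pearson r between each feature and cos(theta - peak_feature)
    templates = np.cos(np.deg2rad(phases[:, None] - peak[None, :]))  # m x N
    Yc = Y - Y.mean(axis=0)
    Tc = templates - templates.mean(axis=0)
    denom = np.sqrt((Yc**2).sum(axis=0) * (Tc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Yc * Tc).sum(axis=0) / denom, 0.0)
    r = np.where(amp > 0, r, 0.0)
    peak = np.where(amp > 0, peak, np.nan)
    return peak, r


def rhythmicity_ranking(
    data: ExpressionDataset, condition: str = "all"
) -> pd.DataFrame:
    """Rank every feature by squared cosine correlation (r^2), descending.

    `condition` selects one sleep condition's samples or "all" for the
    pooled series.  Rows: feature_id, peak_phase_deg, r, r2, rank.
    """
    if condition == "all":
        sub = data
    else:
        keep = data.samples.index[data.samples["condition"] == condition]
        sub = data.subset_samples(keep)
    phases = sub.phases().to_numpy(dtype=float)
    if np.isnan(phases).any():
        raise ValueError("all selected samples need an assigned phase")
    peak, r = _cosinor_stats_matrix(sub.values, phases)
    out = pd.DataFrame(
        {
            "feature_id": sub.feature_ids,
            "peak_phase_deg": peak,
            "r": r,
            "r2": r**2,
        }
    ).sort_values(["r2", "feature_id"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# timetable model


@dataclass
class TimetableModel:
    """Look-up table of time-indicating features with fitted peak phases."""

    features: list
    peak_phases_deg: np.ndarray
    scaler: FeatureScaler
    threshold_used: float
    phase_grid_step_deg: float = 1.0

    def __post_init__(self) -> None:
        self.peak_phases_deg = np.asarray(self.peak_phases_deg, dtype=float)
        if len(self.features) != self.peak_phases_deg.size:
            raise ValueError("features and peak phases differ in length")

    def phase_grid(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.phase_grid_step_deg)

    def templates(self) -> np.ndarray:
        """Grid x features matrix of expected (unit-cosine) values."""
        grid = self.phase_grid()
        return np.cos(np.deg2rad(grid[:, None] - self.peak_phases_deg[None, :]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model": "timetable",
                    "schema_version": 1,
                    "features": list(self.features),
                    "peak_phases_deg": [round(p, 4) for p in self.peak_phases_deg],
                    "scaler": self.scaler.to_dict(),
                    "threshold_used": self.threshold_used,
                    "phase_grid_step_deg": self.phase_grid_step_deg,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "TimetableModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            features=d["features"],
            peak_phases_deg=np.asarray(d["peak_phases_deg"]),
            scaler=FeatureScaler.from_dict(d["scaler"]),
            threshold_used=d["threshold_used"],
            phase_grid_step_deg=d["phase_grid_step_deg"],
        )


def select_timetable_features(
    training: ExpressionDataset,
    threshold: float = 0.3,
    gene_map: dict | None = None,
    phase_grid_step_deg: float = 1.0,
    conditions: tuple = CONDITIONS,
) -> TimetableModel:
    """Screen time-indicating features and build the look-up model.

    Each feature gets five cosinor fits — one per sleep condition plus the
    pooled "all conditions" series — and survives only if r >= threshold in
    all five.  Where several surviving features target the same gene
    (via `gene_map`), the one with the highest pooled r represents it.
    Peak phases stored in the model come from the pooled fit; the z-score
    scaler is fit on the full training set.
    """
    phases = training.phases().to_numpy(dtype=float)
    if np.isnan(phases).any():
        raise ValueError("training samples must all have assigned phases")
    present = set(training.samples["condition"])
    missing = [c for c in conditions if c not in present]
    if missing:
        raise ValueError(f"training set lacks conditions: {missing}")

    r_by_series = {}
    pooled_peak, pooled_r = _cosinor_stats_matrix(training.values, phases)
    r_by_series["all"] = pooled_r
    for cond in conditions:
        keep = training.samples["condition"].to_numpy() == cond
        _, r_cond = _cosinor_stats_matrix(
            training.values.loc[:, keep], phases[keep]
        )
        r_by_series[cond] = r_cond

    ok = np.ones(training.n_features, dtype=bool)
    for r in r_by_series.values():
        ok &= r >= threshold
    if not ok.any():
        raise EmptyModelError(f"no feature passes r >= {threshold} in all series")

    surv = pd.DataFrame(
        {
            "feature_id": np.asarray(training.feature_ids)[ok],
            "pooled_r": pooled_r[ok],
            "peak": pooled_peak[ok],
        }
    )
    gene_map = gene_map or {}
    surv["gene"] = [gene_map.get(f, f) for f in surv["feature_id"]]
    surv = surv.sort_values(
        ["gene", "pooled_r", "feature_id"], ascending=[True, False, True],
        kind="mergesort",
    ).drop_duplicates("gene", keep="first")
    surv = surv.sort_values("feature_id", kind="mergesort")

    scaler = fit_feature_scaler(training.values.loc[surv["feature_id"]])
    kept = [f for f in surv["feature_id"] if f in set(scaler.feature_ids)]
    surv = surv.set_index("feature_id").loc[kept]
    logger.info(
        "timetable screen at r >= %.2f kept %d features", threshold, len(surv)
    )
    if len(kept) < 3:
        import warnings

        warnings.warn(
            f"timetable model has only {len(kept)} feature(s); the correlation "
            "comparator is degenerate below 3 features",
            UserWarning,
            stacklevel=2,
        )
    return TimetableModel(
        features=kept,
        peak_phases_deg=surv["peak"].to_numpy(),
        scaler=scaler,
        threshold_used=threshold,
        phase_grid_step_deg=phase_grid_step_deg,
    )


def _grid_argmax_correlation(model: TimetableModel, vec: np.ndarray) -> float:
    """Phase on the grid whose template best correlates with `vec`.

    Ties break to the smallest phase (argmax on the ascending grid).
    """
    v = vec - vec.mean()
    if np.allclose(v, 0.0):
        raise UndefinedCorrelationError(
            "sample is constant across model features; correlation undefined"
        )
    T = model.templates()
    Tc = T - T.mean(axis=1, keepdims=True)
    denom = np.sqrt((Tc**2).sum(axis=1) * (v**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, Tc @ v / denom, -np.inf)
    grid = model.phase_grid()
    return float(grid[int(np.argmax(corr))])


def timetable_predict(model: TimetableModel, sample: pd.Series) -> float:
    """Predict one sample's circadian phase (degrees) from the look-up table.

    The sample is z-scored with the stored training scaler, mean-centred
    across the model's features, and correlated against the unit-cosine
    template at every grid phase; the best-correlating phase wins.
    """
    z = model.scaler.transform_vector(sample).loc[model.features].to_numpy()
    return _grid_argmax_correlation(model, z)


def timetable_predict_differential(
    model: TimetableModel, sample1: pd.Series, sample2: pd.Series
) -> float:
    """Predict the phase of sample1 from a 12-h-apart pair.

    The z-scored difference sample1 - sample2 is compared with differential
    templates cos(phi - peak) - cos(phi + 180 - peak) over the grid;
    participant-constant offsets cancel in the difference.
    """
    z1 = model.scaler.transform_vector(sample1).loc[model.features].to_numpy()
    z2 = model.scaler.transform_vector(sample2).loc[model.features].to_numpy()
    d = z1 - z2
    if np.allclose(d - d.mean(), 0.0):
        raise UndefinedCorrelationError("identical samples give a constant difference")
    grid = model.phase_grid()
    T1 = model.templates()
    T2 = np.cos(np.deg2rad((grid[:, None] + 180.0) - model.peak_phases_deg[None, :]))
    D = T1 - T2
    Dc = D - D.mean(axis=1, keepdims=True)
    v = d - d.mean()
    denom = np.sqrt((Dc**2).sum(axis=1) * (v**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, Dc @ v / denom, -np.inf)
    return float(grid[int(np.argmax(corr))])
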