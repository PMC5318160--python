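"""Partial-least-squares regression of circadian phase on the transcriptome.

The circular response y (degrees) is embedded as (cos y, sin y) and regressed
on z-scored abundance with a two-call PLS2 protocol: a first fit on all
features ranks them by summed absolute predictor loadings over the latent
factors; a second fit on the top-n features yields the deployed model, which
reduces to two linear forms

    yhat_c = sum_i wc_i z_i + wc0,    yhat_s = sum_i ws_i z_i + ws0,

and the predicted phase is the angle of (yhat_c, yhat_s) with the quadrant
rule.  The differential mode applies the same machinery to within-participant
differences of samples taken 12 h apart, which cancels stable trait-like
expression offsets before any scaling.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .circular import angle_difference, directional_mean, from_cartesian, to_cartesian
from .dataset import ExpressionDataset
from .preprocess import FeatureScaler, fit_feature_scaler

logger = logging.getLogger(__name__)


@dataclass
class DifferentialObservation:
    """One 12-h within-participant difference vector (sample1 - sample2).

    The response phase is that of sample 1, the earlier draw.
    """

    participant_id: str
    condition: str
    sample1_id: str
    sample2_id: str
    delta_values: pd.Series
    response_phase_deg: float


def build_differential_dataset(
    data: ExpressionDataset,
    separation_h: float = 12.0,
    tolerance_h: float = 0.5,
) -> list[DifferentialObservation]:
    """Enumerate 12-h-apart sample pairs within participant x condition.

    Every ordered pair (s1, s2) with s2 drawn `separation_h` (+- tolerance)
    after s1 yields one observation with delta = values(s1) - values(s2)
    and response = phase(s1); overlapping pairs are allowed.  Ordering is
    deterministic (by s1 clock time, then sample id).
    """
    obs: list[DifferentialObservation] = []
    meta = data.samples
    for (pid, cond), grp in meta.groupby(["participant_id", "condition"], sort=True):
        grp = grp.sort_values(["clock_time_h"], kind="mergesort")
        sids = list(grp.index)
        times = grp["clock_time_h"].to_numpy(dtype=float)
        for i, s1 in enumerate(sids):
            for j, s2 in enumerate(sids):
                dt = times[j] - times[i]
                if abs(dt - separation_h) <= tolerance_h:
                    obs.append(
                        DifferentialObservation(
                            participant_id=pid,
                            condition=cond,
                            sample1_id=s1,
                            sample2_id=s2,
                            delta_values=data.values[s1] - data.values[s2],
                            response_phase_deg=float(meta.loc[s1, "phase_deg"]),
                        )
                    )
    if not obs:
        warnings.warn("no 12-h sample pairs found; differential set is empty",
                      UserWarning, stacklevel=2)
    return obs


def differential_to_frames(obs: list[DifferentialObservation]):
    """Stack differential observations into (values features x obs, metadata)."""
    if not obs:
        raise ValueError("empty differential observation list")
    ids = [f"{o.sample1_id}-minus-{o.sample2_id}" for o in obs]
    values = pd.concat([o.delta_values for o in obs], axis=1)
    values.columns = ids
    meta = pd.DataFrame(
        {
            "participant_id": [o.participant_id for o in obs],
            "condition": [o.condition for o in obs],
            "batch": np.nan,
            "clock_time_h": np.nan,
            "phase_deg": [o.response_phase_deg for o in obs],
        },
        index=ids,
    )
    return ExpressionDataset(values=values, samples=meta)


@dataclass
class PLSRPhaseModel:
    """Deployed circular-response PLSR model (linear-coefficient form)."""

    mode: str  # "one_sample" | "differential"
    features: list
    scaler: FeatureScaler
    latent_factors: int
    coef_cos: np.ndarray
    intercept_cos: float
    coef_sin: np.ndarray
    intercept_sin: float
    loadings: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coef_cos = np.asarray(self.coef_cos, dtype=float)
        self.coef_sin = np.asarray(self.coef_sin, dtype=float)
        n = len(self.features)
        if self.coef_cos.size != n or self.coef_sin.size != n:
            raise ValueError("coefficient length differs from feature count")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model": "plsr_phase",
                    "schema_version": 1,
                    "mode": self.mode,
                    "features": list(self.features),
                    "scaler": self.scaler.to_dict(),
                    "latent_factors": self.latent_factors,
                    "coef_cos": self.coef_cos.tolist(),
                    "intercept_cos": self.intercept_cos,
                    "coef_sin": self.coef_sin.tolist(),
                    "intercept_sin": self.intercept_sin,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "PLSRPhaseModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mode=d["mode"],
            features=d["features"],
            scaler=FeatureScaler.from_dict(d["scaler"]),
            latent_factors=d["latent_factors"],
            coef_cos=np.asarray(d["coef_cos"]),
            intercept_cos=d["intercept_cos"],
            coef_sin=np.asarray(d["coef_sin"]),
            intercept_sin=d["intercept_sin"],
        )


def _pls_linear_coefficients(Z: np.ndarray, Y: np.ndarray, T: int):
    """Fit a T-factor PLS2 and return (coef 2xN, intercept 2, loadings NxT).

    Z is samples x features (already z-scored), Y is samples x 2 (cos, sin).
    The fitted model is linear: Yhat = Z @ coef.T + intercept.
    """
    # tight inner-loop tolerance: keeps the fit deterministic and preserves
    # the rotation symmetry of the objective to numerical precision
    pls = PLSRegression(n_components=T, scale=False, tol=1e-12, max_iter=5000)
    pls.fit(Z, Y)
    coef = np.asarray(pls.coef_)  # (n_targets, n_features) in recent sklearn
    if coef.shape[0] != Y.shape[1]:
        coef = coef.T
    intercept = np.asarray(pls.intercept_, dtype=float)
    return coef, intercept, np.asarray(pls.x_loadings_)


def fit_plsr_phase(
    training: ExpressionDataset | list[DifferentialObservation],
    latent_factors: int,
    n_features: int,
    mode: str | None = None,
    ranking: str = "sum_abs_loadings",
) -> PLSRPhaseModel:
    """Two-call PLS2 fit of (cos y, sin y) on z-scored abundance.

    First call on all features; features are then ranked by the aggregated
    absolute predictor loadings over the retained factors (default: sum) and
    the top `n_features` kept; the second call on that subset gives the
    deployed coefficients.  For differential input the z-score statistics
    are fit on the delta vectors themselves.
    """
    if isinstance(training, list):
        data = differential_to_frames(training)
        mode = mode or "differential"
    else:
        data = training
        mode = mode or "one_sample"
    T = int(latent_factors)
    if T < 1:
        raise ValueError("latent_factors must be >= 1")
    phases = data.phases().to_numpy(dtype=float)
    if np.isnan(phases).any():
        raise ValueError("all training observations need a response phase")
    m = data.n_samples
    if m < T + 1:
        raise ValueError(f"need more than {T} observations to fit {T} factors")

    scaler = fit_feature_scaler(data.values)
    feats_all = scaler.feature_ids
    if not (1 <= n_features <= len(feats_all)):
        raise ValueError(
            f"n_features must be in [1, {len(feats_all)}], got {n_features}"
        )
    if T > min(len(feats_all), m - 1):
        raise ValueError("latent_factors exceeds the available rank")

    Z = scaler.transform_frame(data.values).to_numpy().T  # m x N
    cy, sy = to_cartesian(phases)
    Y = np.column_stack([cy, sy])

    # call 1: rank features on the full matrix
    if n_features < len(feats_all):
        _, _, loadings = _pls_linear_coefficients(Z, Y, T)
        if ranking == "sum_abs_loadings":
            score = np.abs(loadings).sum(axis=1)
        elif ranking == "max_abs_loadings":
            score = np.abs(loadings).max(axis=1)
        else:
            raise ValueError(f"unknown ranking rule: {ranking!r}")
        order = np.argsort(-score, kind="mergesort")[:n_features]
        top = sorted(order)  # keep original feature order for determinism
        feats = [feats_all[i] for i in top]
    else:
        feats = list(feats_all)

    sub_scaler = FeatureScaler(
        mean=scaler.mean.loc[feats], sd=scaler.sd.loc[feats]
    )
    Zsub = sub_scaler.transform_frame(data.values.loc[feats]).to_numpy().T
    Teff = min(T, len(feats), m - 1)
    if Teff != T:
        logger.info("reducing latent factors from %d to %d (rank limit)", T, Teff)
    coef, intercept, loadings2 = _pls_linear_coefficients(Zsub, Y, Teff)
    return PLSRPhaseModel(
        mode=mode,
        features=feats,
        scaler=sub_scaler,
        latent_factors=Teff,
        coef_cos=coef[0],
        intercept_cos=float(intercept[0]),
        coef_sin=coef[1],
        intercept_sin=float(intercept[1]),
        loadings=loadings2,
    )


def predict_phase(model: PLSRPhaseModel, sample: pd.Series) -> float:
    """Deploy the linear form on one (raw, unscaled) sample vector."""
    z = model.scaler.transform_vector(sample).loc[model.features].to_numpy()
    return predict_phase_from_z(model, z)


def predict_phase_from_z(model: PLSRPhaseModel, z: np.ndarray) -> float:
    """Deploy the linear form on an already z-scored vector over model.features."""
    yc = float(model.coef_cos @ z + model.intercept_cos)
    ys = float(model.coef_sin @ z + model.intercept_sin)
    return from_cartesian(yc, ys)


def predict_phases(model: PLSRPhaseModel, data: ExpressionDataset) -> pd.Series:
    """Vectorized prediction for every sample of a dataset (raw values)."""
    Z = model.scaler.transform_frame(data.values).loc[model.features].to_numpy().T
    yc = Z @ model.coef_cos + model.intercept_cos
    ys = Z @ model.coef_sin + model.intercept_sin
    out = [from_cartesian(c, s) for c, s in zip(yc, ys)]
    return pd.Series(out, index=data.sample_ids, name="predicted_phase_deg")


def predict_phase_differential(
    model: PLSRPhaseModel, sample1: pd.Series, sample2: pd.Series
) -> float:
    """Predict the phase of sample1 from a 12-h pair with a differential model."""
    if model.mode != "differential":
        raise ValueError("model was not trained in differential mode")
    delta = sample1 - sample2
    return predict_phase(model, delta)


def aggregate_consecutive(
    model: PLSRPhaseModel,
    samples: pd.DataFrame,
    observed_phases_deg,
) -> dict:
    """Repeated one-sample use: average predictions over 2-3 consecutive draws.

    `samples` is features x k (k = 2 or 3 consecutive samples of one
    participant/condition).  Returns the directional means of predictions
    and observations and their circular difference.
    """
    k = samples.shape[1]
    if not 2 <= k <= 3:
        raise ValueError("consecutive aggregation takes 2 or 3 samples")
    preds = [predict_phase(model, samples.iloc[:, i]) for i in range(k)]
    pred_mean = directional_mean(preds)
    obs_mean = directional_mean(np.asarray(observed_phases_deg, dtype=float))
    return {
        "predicted_phases_deg": preds,
        "predicted_mean_deg": pred_mean,
        "observed_mean_deg": obs_mean,
        "error_deg": angle_difference(pred_mean, obs_mean),
    }
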