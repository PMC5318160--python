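"""Leave-one-participant-out cross-validation, the (latent factors, feature
count) grid search, and the minimal-complexity parameter-selection rule.

Every fold re-runs the entire pipeline — z-scoring, feature
screening/ranking, model fitting — on the fold's training observations only,
so feature sets may differ between folds and no information leaks from the
held-out participant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circular_r2
from .dataset import ExpressionDataset
from .plsr import (
    DifferentialObservation,
    differential_to_frames,
    fit_plsr_phase,
    predict_phases,
)
from . import timetable as tt

logger = logging.getLogger(__name__)

# Default grid axes.  One-sample: 8 latent-factor values x 17 feature counts
# = 136 combinations; differential: 5 x 20 = 100 combinations.
DEFAULT_T_AXIS_ONE_SAMPLE = tuple(range(5, 41, 5))
DEFAULT_N_AXIS_ONE_SAMPLE = (
    100, 200, 300, 400, 500, 750, 1000, 1250, 1500, 1750,
    2000, 2500, 3000, 3500, 4000, 4500, 5000,
)
DEFAULT_T_AXIS_DIFFERENTIAL = (4, 5, 6, 7, 8)
DEFAULT_N_AXIS_DIFFERENTIAL = tuple(range(50, 1001, 50))


def _as_dataset(data) -> ExpressionDataset:
    if isinstance(data, list):
        return differential_to_frames(data)
    return data


def lopo_splits(data: ExpressionDataset | list[DifferentialObservation]):
    """One (train_ids, test_ids) split per participant.

    Test = every observation of that participant; train = everything else.
    The union of test sets covers each observation exactly once.
    """
    ds = _as_dataset(data)
    participants = ds.participants
    if len(participants) < 2:
        raise ValueError("leave-one-participant-out needs >= 2 participants")
    pid = ds.samples["participant_id"]
    splits = []
    for p in participants:
        test = list(pid.index[pid == p])
        train = list(pid.index[pid != p])
        splits.append((train, test))
    return splits


def cv_evaluate(
    model_family: str,
    params: dict,
    data: ExpressionDataset | list[DifferentialObservation],
) -> dict:
    """Pooled LOPO predictions and circular R^2 for one parameter setting.

    model_family "plsr" takes params {latent_factors, n_features}; family
    "timetable" takes {threshold} (plus optional gene_map / grid step).
    Fold failures are recorded, not raised; their observations are dropped
    from the pooled score.
    """
    ds = _as_dataset(data)
    splits = lopo_splits(ds)
    observed, predicted, index = [], [], []
    failures = []
    for train_ids, test_ids in splits:
        train = ds.subset_samples(train_ids)
        test = ds.subset_samples(test_ids)
        try:
            if model_family == "plsr":
                model = fit_plsr_phase(
                    train,
                    latent_factors=params["latent_factors"],
                    n_features=params["n_features"],
                    mode=params.get("mode"),
                    ranking=params.get("ranking", "sum_abs_loadings"),
                )
                preds = predict_phases(model, test)
            elif model_family == "timetable":
                model = tt.select_timetable_features(
                    train,
                    threshold=params.get("threshold", 0.3),
                    gene_map=params.get("gene_map"),
                    phase_grid_step_deg=params.get("phase_grid_step_deg", 1.0),
                    conditions=params.get(
                        "conditions",
                        tuple(sorted(set(train.samples["condition"]))),
                    ),
                )
                preds = pd.Series(
                    [tt.timetable_predict(model, test.values[sid]) for sid in test_ids],
                    index=test_ids,
                )
            else:
                raise ValueError(f"unknown model family: {model_family!r}")
        except Exception as exc:  # noqa: BLE001 - fold failures are data
            failures.append((test.samples["participant_id"].iloc[0], str(exc)))
            continue
        observed.extend(test.phases().tolist())
        predicted.extend(preds.tolist())
        index.extend(test_ids)
    if not observed:
        raise RuntimeError(f"every fold failed: {failures[:3]}")
    r2 = circular_r2(np.asarray(observed), np.asarray(predicted))
    return {
        "r2": r2,
        "observed": pd.Series(observed, index=index, name="observed_phase_deg"),
        "predicted": pd.Series(predicted, index=index, name="predicted_phase_deg"),
        "failures": failures,
    }


@dataclass
class CVGrid:
    """Cross-validated R^2 over the (latent factors, feature count) grid."""

    axis_T: list
    axis_n: list
    r2: pd.DataFrame  # index = T, columns = n; NaN where invalid/failed
    status: pd.DataFrame = field(default=None)  # "ok" | "invalid" | "failed"

    def to_tsv(self, path) -> None:
        rows = []
        for T in self.axis_T:
            for n in self.axis_n:
                rows.append(
                    (T, n, self.r2.loc[T, n], self.status.loc[T, n])
                )
        pd.DataFrame(rows, columns=["latent_factors", "n_features", "r2", "status"]).to_csv(
            path, sep="\t", index=False
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "axis_T": list(self.axis_T),
                    "axis_n": list(self.axis_n),
                    "r2": self.r2.where(self.r2.notna(), None).values.tolist(),
                    "status": self.status.values.tolist(),
                },
                fh,
            )


def grid_search(
    data: ExpressionDataset | list[DifferentialObservation],
    axis_T,
    axis_n,
    model_family: str = "plsr",
) -> CVGrid:
    """cv_evaluate at every (T, n) cell; cells with n < T are marked invalid."""
    axis_T = list(axis_T)
    axis_n = list(axis_n)
    if not axis_T or not axis_n:
        raise ValueError("grid axes must be non-empty")
    ds = _as_dataset(data)
    max_n = ds.n_features
    r2 = pd.DataFrame(np.nan, index=axis_T, columns=axis_n)
    status = pd.DataFrame("ok", index=axis_T, columns=axis_n)
    for T in axis_T:
        for n in axis_n:
            if n < T or n > max_n:
                status.loc[T, n] = "invalid"
                continue
            try:
                res = cv_evaluate(
                    model_family, {"latent_factors": T, "n_features": n}, data
                )
                r2.loc[T, n] = res["r2"]
            except Exception as exc:  # noqa: BLE001
                status.loc[T, n] = "failed"
                logger.warning("grid cell (T=%s, n=%s) failed: %s", T, n, exc)
    return CVGrid(axis_T=axis_T, axis_n=axis_n, r2=r2, status=status)


def select_parameters(grid: CVGrid, r2_min: float = 0.70) -> tuple:
    """Least-complexity rule: among cells with R^2 >= r2_min pick the
    smallest feature count, breaking ties by the smallest latent-factor
    count.  If no cell qualifies, fall back to the argmax-R^2 cell with a
    warning."""
    cells = [
        (T, n, grid.r2.loc[T, n])
        for T in grid.axis_T
        for n in grid.axis_n
        if pd.notna(grid.r2.loc[T, n])
    ]
    if not cells:
        raise ValueError("no evaluable cells in the grid")
    qualifying = [c for c in cells if c[2] >= r2_min]
    if qualifying:
        T, n, r2 = min(qualifying, key=lambda c: (c[1], c[0]))
        logger.info(
            "selected (T=%d, n=%d) with R^2=%.3f under the >= %.2f floor",
            T, n, r2, r2_min,
        )
        return T, n
    T, n, r2 = max(cells, key=lambda c: c[2])
    logger.warning(
        "no cell reached R^2 >= %.2f; falling back to argmax (T=%d, n=%d, R^2=%.3f)",
        r2_min, T, n, r2,
    )
    return T, n


def scan_threshold(
    training: ExpressionDataset, thresholds, **timetable_params
) -> pd.DataFrame:
    """LOPO R^2 of the timetable model at each screening threshold.

    Returns a table (threshold, r2, status); the best row is the argmax of
    r2 among cells that evaluated.  A threshold under which some fold has no
    surviving feature is marked failed, not fatal.
    """
    rows = []
    for thr in thresholds:
        try:
            res = cv_evaluate(
                "timetable", {"threshold": thr, **timetable_params}, training
            )
            rows.append((thr, res["r2"], "ok" if not res["failures"] else "partial"))
        except Exception as exc:  # noqa: BLE001
            logger.warning("threshold %.3g failed: %s", thr, exc)
            rows.append((thr, np.nan, "failed"))
    out = pd.DataFrame(rows, columns=["threshold", "r2", "status"])
    return out


def best_threshold(scan: pd.DataFrame) -> float:
    ok = scan.dropna(subset=["r2"])
    if ok.empty:
        raise ValueError("no threshold produced an evaluable model")
    return float(ok.loc[ok["r2"].idxmax(), "threshold"])
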