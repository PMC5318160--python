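"""Validation-set performance reporting: the full error-metric battery,
per-phase-bin ANOVA, and across-condition ANOVA with Tukey HSD post-hoc.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import (
    MetricsSummary,
    angle_difference,
    circular_r2,
    phase_error_minutes,
    summarize_errors,
)

logger = logging.getLogger(__name__)


@dataclass
class PredictionReport:
    """Per-sample predictions with the summary metric battery.

    rows: sample_id-indexed frame with participant, condition, observed and
    predicted phase (degrees), signed error (degrees and minutes).
    """

    rows: pd.DataFrame
    summary: MetricsSummary
    bin_anova_p: float | None = None
    condition_anova_p: float | None = None
    pairwise_conditions: pd.DataFrame | None = None

    def write(self, tsv_path=None, json_path=None) -> None:
        if tsv_path is not None:
            self.rows.to_csv(tsv_path, sep="\t", index_label="sample_id")
        if json_path is not None:
            payload = {
                "summary": self.summary.to_dict(),
                "bin_anova_p": self.bin_anova_p,
                "condition_anova_p": self.condition_anova_p,
            }
            if self.pairwise_conditions is not None:
                payload["pairwise_conditions"] = self.pairwise_conditions.to_dict(
                    orient="records"
                )
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=1, default=float)


def plot_report(report: "PredictionReport", path_prefix) -> list:
    """Write the standard three panels as PNGs (requires matplotlib):
    predicted vs observed phase, mean error per observed-phase bin, and the
    cumulative absolute-error curve.  Returns the paths written."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    rows = report.rows
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(rows["observed_deg"], rows["predicted_deg"], s=10, alpha=0.6)
    ax.plot([0, 360], [0, 360], lw=0.8, color="grey")
    ax.set_xlabel("observed phase (deg)")
    ax.set_ylabel("predicted phase (deg)")
    ax.set_xlim(0, 360)
    ax.set_ylim(0, 360)
    paths.append(f"{path_prefix}_pred_vs_obs.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    bt = report.summary.bin_table
    if bt is not None:
        fig, ax = plt.subplots(figsize=(5, 3))
        centers = bt["bin_lo_deg"] + (bt["bin_hi_deg"] - bt["bin_lo_deg"]) / 2
        ax.errorbar(
            centers,
            bt["mean_error_min"],
            yerr=1.96 * bt["se"],
            fmt="o-",
            capsize=3,
        )
        ax.axhline(0, lw=0.8, color="grey")
        ax.set_xlabel("observed phase bin (deg)")
        ax.set_ylabel("mean error (min, 95% CI)")
        paths.append(f"{path_prefix}_binned_error.png")
        fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3))
    curve = report.summary.cum_curve
    ax.step(curve["abs_error_min"], curve["proportion"], where="post")
    ax.set_xlabel("absolute error (min)")
    ax.set_ylabel("cumulative proportion")
    ax.set_ylim(0, 1.02)
    paths.append(f"{path_prefix}_cumulative_error.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return paths


def _observed_phase_bins(observed_deg: np.ndarray, bin_width: float) -> np.ndarray:
    """Half-open observed-phase bins [lo, hi) over [0, 360)."""
    return (np.floor(np.asarray(observed_deg) / bin_width) * bin_width).astype(float)


def phase_bin_table(
    observed_deg, errors_deg, bin_width: float = 30.0
) -> pd.DataFrame:
    """Mean signed error (minutes) per observed-phase bin with a normal-
    approximation 95% CI (mean +- 1.96 SE)."""
    df = pd.DataFrame(
        {
            "bin_lo_deg": _observed_phase_bins(observed_deg, bin_width),
            "error_min": phase_error_minutes(errors_deg),
        }
    )
    g = df.groupby("bin_lo_deg")["error_min"]
    out = pd.DataFrame(
        {
            "n": g.size(),
            "mean_error_min": g.mean(),
            "se": g.std(ddof=1).fillna(0.0) / np.sqrt(g.size()),
        }
    ).reset_index()
    out["ci95_lo"] = out["mean_error_min"] - 1.96 * out["se"]
    out["ci95_hi"] = out["mean_error_min"] + 1.96 * out["se"]
    out["bin_hi_deg"] = out["bin_lo_deg"] + bin_width
    return out


def binwise_error_anova(
    errors_deg, observed_deg, bin_width: float = 30.0
) -> float:
    """One-way fixed-effects ANOVA of signed error on observed-phase bin.

    A small p-value indicates the model's accuracy depends on the circadian
    phase at which the sample was drawn.  Degenerate input (zero within-bin
    variance everywhere, non-equal means) reports p = 0 with a warning.
    """
    errors = phase_error_minutes(errors_deg)
    bins = _observed_phase_bins(np.asarray(observed_deg, dtype=float), bin_width)
    groups = [errors[bins == b] for b in np.unique(bins)]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError("binwise ANOVA needs >= 2 bins with >= 2 observations")
    if all(np.allclose(g, g[0]) for g in groups):
        means = [g.mean() for g in groups]
        if np.allclose(means, means[0]):
            return 1.0
        warnings.warn("zero within-bin variance; reporting p = 0", UserWarning,
                      stacklevel=2)
        return 0.0
    _, p = stats.f_oneway(*groups)
    return float(p)


def condition_error_comparison(
    rows: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA of signed error on sleep condition + Tukey HSD pairs.

    `rows` needs columns condition and error_min.  Returns (anova p-value,
    pairwise table with mean differences and adjusted p-values).
    """
    conditions = rows["condition"].unique()
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions for a comparison")
    groups = [rows.loc[rows["condition"] == c, "error_min"].to_numpy() for c in conditions]
    if all(np.allclose(g, g[0]) for g in groups if g.size):
        warnings.warn("zero within-condition variance", UserWarning, stacklevel=2)
        anova_p = 0.0 if not np.allclose(
            [g.mean() for g in groups], groups[0].mean()
        ) else 1.0
        pairs = pd.DataFrame(
            columns=["group1", "group2", "meandiff_min", "p_adj", "reject"]
        )
        return anova_p, pairs
    _, anova_p = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(
        rows["error_min"].to_numpy(), rows["condition"].to_numpy(), alpha=alpha
    )
    pairs = pd.DataFrame(
        tk.summary().data[1:], columns=[c for c in tk.summary().data[0]]
    ).rename(
        columns={
            "group1": "group1",
            "group2": "group2",
            "meandiff": "meandiff_min",
            "p-adj": "p_adj",
            "reject": "reject",
        }
    )[["group1", "group2", "meandiff_min", "p_adj", "reject"]]
    return float(anova_p), pairs


def evaluate_predictions(
    observed_deg,
    predicted_deg,
    metadata: pd.DataFrame | None = None,
    bin_width_deg: float = 30.0,
    within_threshold_min: float = 120.0,
) -> PredictionReport:
    """Assemble the full report for a set of phase predictions.

    metadata (optional) is indexed like the prediction vectors and may carry
    participant_id and condition columns; with >= 2 conditions present the
    across-condition ANOVA + Tukey HSD table is filled in.
    """
    observed = np.atleast_1d(np.asarray(observed_deg, dtype=float))
    predicted = np.atleast_1d(np.asarray(predicted_deg, dtype=float))
    if observed.size == 0 or observed.shape != predicted.shape:
        raise ValueError("observed/predicted must be equal-length and non-empty")
    errors = np.atleast_1d(angle_difference(predicted, observed))
    try:
        r2 = circular_r2(observed, predicted)
    except Exception:
        # degenerate observed spread (no directional mean / zero TSS):
        # perfect predictions still score 1, otherwise R^2 is undefined
        r2 = 1.0 if np.all(errors == 0.0) else None
    summary = summarize_errors(
        errors,
        bin_width=15.0,
        within_threshold_min=within_threshold_min,
        r2=r2,
    )
    summary.bin_table = phase_bin_table(observed, errors, bin_width=bin_width_deg)

    if isinstance(observed_deg, pd.Series):
        index = observed_deg.index
    elif metadata is not None:
        index = metadata.index
    else:
        index = pd.RangeIndex(observed.size)
    rows = pd.DataFrame(
        {
            "observed_deg": observed,
            "predicted_deg": predicted,
            "error_deg": errors,
            "error_min": phase_error_minutes(errors),
        },
        index=index,
    )
    if metadata is not None:
        for col in ("participant_id", "condition"):
            if col in metadata.columns:
                rows[col] = metadata.loc[index, col]

    report = PredictionReport(rows=rows, summary=summary)
    try:
        report.bin_anova_p = binwise_error_anova(
            errors, observed, bin_width=bin_width_deg
        )
    except ValueError:
        report.bin_anova_p = None
    if "condition" in rows.columns and rows["condition"].nunique() >= 2:
        try:
            p, pairs = condition_error_comparison(rows)
            report.condition_anova_p = p
            report.pairwise_conditions = pairs
        except ValueError:
            pass
    return report
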