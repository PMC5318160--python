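"""Circular-phase arithmetic and circular performance statistics.

Circadian phase is expressed in degrees on [0, 360), with 0 degrees anchored
at dim-light melatonin onset (DLMO) and 360 degrees = 24 h, i.e. 1 degree =
4 minutes.  Signed phase errors live on the half-open interval (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEGREES_PER_HOUR = 15.0
MINUTES_PER_DEGREE = 4.0


class UndefinedPhaseError(ValueError):
    """Raised when a phase cannot be defined (zero resultant vector)."""


class DegenerateVarianceError(ValueError):
    """Raised when the observed phases carry no circular variance."""


def normalize_phase(value):
    """Wrap an angle (degrees) onto [0, 360). Accepts scalars or arrays."""
    return np.asarray(value, dtype=float) % 360.0


def to_cartesian(phase_deg):
    """Map phase(s) in degrees to unit-circle coordinates (x=cos, y=sin)."""
    rad = np.deg2rad(np.asarray(phase_deg, dtype=float))
    return np.cos(rad), np.sin(rad)


def from_cartesian(x, y) -> float:
    """Recover a phase in [0, 360) from Cartesian coordinates.

    Uses the arctangent with an explicit quadrant offset: 0 in quadrant I,
    +180 in quadrants II and III, +360 in quadrant IV.  The vector need not
    be unit length; only its direction matters.

    Raises
    ------
    UndefinedPhaseError
        If (x, y) is the zero vector.
    """
    x = float(x)
    y = float(y)
    if x == 0.0 and y == 0.0:
        raise UndefinedPhaseError("phase undefined for the zero vector")
    if x == 0.0:
        # On the y-axis the arctan form is singular; take the limit.
        return 90.0 if y > 0 else 270.0
    theta = np.rad2deg(np.arctan(y / x))
    if x > 0 and y >= 0:  # quadrant I (incl. positive x-axis)
        offset = 0.0
    elif x < 0:  # quadrants II and III
        offset = 180.0
    else:  # quadrant IV: x > 0, y < 0
        offset = 360.0
    return float((theta + offset) % 360.0)


def directional_mean(phases_deg, tol: float = 1e-9) -> float:
    """Directional (circular) mean of a set of phases, in degrees.

    Each phase is mapped to the unit circle; the mean of the Cartesian
    coordinates is mapped back to an angle with the quadrant rule.

    Raises
    ------
    UndefinedPhaseError
        If the list is empty or the resultant vector length is below `tol`
        (e.g. two antipodal phases), in which case no mean direction exists.
    """
    phases = np.atleast_1d(np.asarray(phases_deg, dtype=float))
    if phases.size == 0:
        raise UndefinedPhaseError("directional mean of an empty set")
    x, y = to_cartesian(phases)
    xbar, ybar = float(np.mean(x)), float(np.mean(y))
    if np.hypot(xbar, ybar) <= tol:
        raise UndefinedPhaseError(
            "resultant vector has (near-)zero length; mean direction undefined"
        )
    return from_cartesian(xbar, ybar)


def angle_difference(theta_deg, beta_deg):
    """Signed circular difference delta = theta - beta on (-180, 180].

    Three cases: the raw difference is kept if it already lies in
    (-180, 180); 360 is subtracted if it exceeds 180 and added if it falls
    below -180.  A raw difference of exactly +-180 maps to +180 so the
    operation is total.  Vectorized over array inputs.
    """
    d = np.asarray(theta_deg, dtype=float) - np.asarray(beta_deg, dtype=float)
    out = (d + 180.0) % 360.0 - 180.0  # lands on [-180, 180)
    out = np.where(out == -180.0, 180.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def phase_error_minutes(delta_deg):
    """Convert a signed phase error in degrees to minutes (1 deg = 4 min)."""
    return np.asarray(delta_deg, dtype=float) * MINUTES_PER_DEGREE


def circular_r2(observed_deg, predicted_deg, residuals: str = "degrees") -> float:
    """Circular coefficient of determination, R^2 = 1 - RSS/TSS.

    Residuals y_i - yhat_i and deviations y_i - ybar (ybar the directional
    mean of the observed phases) are signed circular differences.  R^2 is at
    most 1 and may be negative: a model predicting worse than the constant
    directional mean has RSS > TSS.

    Parameters
    ----------
    residuals:
        "degrees" (default) computes squared circular differences in
        degrees; "cartesian" computes squared Euclidean distances between
        the unit-circle embeddings instead.  The two agree closely for
        small errors.

    Raises
    ------
    DegenerateVarianceError
        If all observed phases coincide (TSS = 0).
    """
    obs = np.atleast_1d(np.asarray(observed_deg, dtype=float))
    pred = np.atleast_1d(np.asarray(predicted_deg, dtype=float))
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    ybar = directional_mean(obs)
    if residuals == "degrees":
        rss = float(np.sum(angle_difference(obs, pred) ** 2))
        tss = float(np.sum(angle_difference(obs, ybar) ** 2))
    elif residuals == "cartesian":
        ox, oy = to_cartesian(obs)
        px, py = to_cartesian(pred)
        mx, my = to_cartesian(ybar)
        rss = float(np.sum((ox - px) ** 2 + (oy - py) ** 2))
        tss = float(np.sum((ox - mx) ** 2 + (oy - my) ** 2))
    else:
        raise ValueError(f"unknown residual scheme: {residuals!r}")
    if tss == 0.0:
        raise DegenerateVarianceError("observed phases identical; TSS is zero")
    return 1.0 - rss / tss


@dataclass
class MetricsSummary:
    """Summary statistics of a set of signed circular prediction errors.

    mean_error_min / sd_error_min are the mean and sample (n-1) SD of the
    signed errors in minutes.  prop_within is the fraction of samples with
    absolute error at or below the threshold (inclusive).  hist counts
    signed errors in half-open bins of `bin_width` degrees centred on 0.
    cum_curve gives (abs error in minutes, cumulative proportion) pairs; its
    last proportion is exactly 1.
    """

    mean_error_min: float
    sd_error_min: float
    prop_within: float
    within_threshold_min: float
    r2: float | None = None
    hist: pd.DataFrame = field(default_factory=pd.DataFrame)
    cum_curve: pd.DataFrame = field(default_factory=pd.DataFrame)
    bin_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "mean_error_min": self.mean_error_min,
            "sd_error_min": self.sd_error_min,
            "prop_within": self.prop_within,
            "within_threshold_min": self.within_threshold_min,
            "r2": self.r2,
            "hist": self.hist.to_dict(orient="list"),
            "cum_curve": self.cum_curve.to_dict(orient="list"),
        }
        if self.bin_table is not None:
            d["bin_table"] = self.bin_table.to_dict(orient="list")
        return d


def error_histogram(errors_deg, bin_width: float = 15.0) -> pd.DataFrame:
    """Frequency distribution of signed errors in half-open degree bins.

    Bins are aligned so 0 degrees sits at a bin centre, covering
    [-180 - w/2, 180 + w/2) as needed.
    """
    errors = np.asarray(errors_deg, dtype=float)
    half = bin_width / 2.0
    lo = -(np.ceil((180.0 - half) / bin_width) * bin_width + half)
    edges = np.arange(lo, -lo + bin_width / 2, bin_width)
    counts, edges = np.histogram(errors, bins=edges)
    return pd.DataFrame(
        {
            "bin_lo_deg": edges[:-1],
            "bin_hi_deg": edges[1:],
            "bin_center_deg": (edges[:-1] + edges[1:]) / 2.0,
            "count": counts,
        }
    )


def cumulative_error_curve(errors_deg) -> pd.DataFrame:
    """Cumulative frequency of absolute error, in minutes.

    Returns one row per distinct absolute error with the proportion of
    samples at or below it; non-decreasing, terminal proportion exactly 1.
    """
    abs_min = np.sort(np.abs(phase_error_minutes(errors_deg)))
    n = abs_min.size
    uniq, counts = np.unique(abs_min, return_counts=True)
    cum = np.cumsum(counts) / n
    cum[-1] = 1.0  # guard against float round-off
    return pd.DataFrame({"abs_error_min": uniq, "proportion": cum})


def summarize_errors(
    errors_deg,
    bin_width: float = 30.0,
    within_threshold_min: float = 120.0,
    r2: float | None = None,
) -> MetricsSummary:
    """Compute the standard error-metric battery from signed errors (degrees)."""
    errors = np.atleast_1d(np.asarray(errors_deg, dtype=float))
    if errors.size == 0:
        raise ValueError("no errors to summarize")
    err_min = phase_error_minutes(errors)
    sd = float(np.std(err_min, ddof=1)) if errors.size > 1 else 0.0
    return MetricsSummary(
        mean_error_min=float(np.mean(err_min)),
        sd_error_min=sd,
        prop_within=float(np.mean(np.abs(err_min) <= within_threshold_min)),
        within_threshold_min=within_threshold_min,
        r2=r2,
        hist=error_histogram(errors, bin_width=bin_width),
        cum_curve=cumulative_error_curve(errors),
    )
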