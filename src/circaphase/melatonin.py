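"""Dim-light melatonin onset (DLMO) and circadian phase assignment.

DLMO is the clock time at which plasma melatonin first rises to 25% of its
range above baseline; it anchors 0 degrees of circadian phase.  A sample
drawn h hours after DLMO sits at (h mod 24) * 15 degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import DEGREES_PER_HOUR
from .dataset import ExpressionDataset


class NoOnsetError(ValueError):
    """Raised when the melatonin profile never crosses the onset threshold."""


@dataclass
class MelatoninSeries:
    """A participant/condition melatonin concentration time course (pg/ml)."""

    participant_id: str
    condition: str
    times_h: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times_h.size < 4:
            raise ValueError("melatonin series needs at least 4 points")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("melatonin sampling times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("melatonin concentrations must be non-negative")


@dataclass
class DlmoResult:
    """Onset time plus the threshold decomposition that produced it."""

    dlmo_time_h: float
    threshold: float
    baseline: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.baseline <= self.threshold <= self.amplitude):
            raise ValueError("expected baseline <= threshold <= amplitude")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _baseline(conc: np.ndarray, method: str, window: tuple | None, times: np.ndarray):
    if method == "lowest_quartile":
        k = max(1, math.ceil(conc.size / 4))
        return float(np.sort(conc)[:k].mean())
    if method == "minimum":
        return float(conc.min())
    if method == "window":
        if window is None:
            raise ValueError("baseline window required for method='window'")
        mask = (times >= window[0]) & (times <= window[1])
        if not mask.any():
            raise ValueError("no samples inside the baseline window")
        return float(conc[mask].mean())
    raise ValueError(f"unknown baseline method: {method!r}")


def compute_dlmo(
    series: MelatoninSeries,
    baseline_method: str = "lowest_quartile",
    baseline_window: tuple | None = None,
) -> DlmoResult:
    """Locate the onset: first ascending crossing of the 25%-of-range threshold.

    threshold = baseline + 0.25 * (amplitude - baseline), with amplitude the
    maximum observed concentration and baseline (by default) the mean of the
    lowest quartile of concentrations.  The crossing time is linearly
    interpolated between the bracketing hourly samples; a sample lying
    exactly on the threshold during an ascent is returned as-is.
    """
    t = series.times_h
    c = series.concentrations
    amplitude = float(c.max())
    baseline = _baseline(c, baseline_method, baseline_window, t)
    threshold = baseline + 0.25 * (amplitude - baseline)
    for i in range(1, t.size):
        if c[i - 1] < threshold <= c[i]:
            frac = (threshold - c[i - 1]) / (c[i] - c[i - 1])
            return DlmoResult(
                dlmo_time_h=float(t[i - 1] + frac * (t[i] - t[i - 1])),
                threshold=threshold,
                baseline=baseline,
                amplitude=amplitude,
            )
    raise NoOnsetError(
        f"no ascending crossing of threshold {threshold:.3g} pg/ml for "
        f"{series.participant_id}/{series.condition}"
    )


def assign_phase(sample_clock_time_h: float, dlmo: DlmoResult | float) -> float:
    """Circadian phase (degrees) of a sample drawn at the given clock time.

    phase = ((t - DLMO) mod 24) * 15; periodic in 24 h.
    """
    dlmo_time = dlmo.dlmo_time_h if isinstance(dlmo, DlmoResult) else float(dlmo)
    return float(((sample_clock_time_h - dlmo_time) % 24.0) * DEGREES_PER_HOUR)


def assign_phases_to_dataset(
    data: ExpressionDataset, dlmo_by_key: dict
) -> ExpressionDataset:
    """Assign phase_deg to every sample from per-(participant, condition) DLMOs.

    `dlmo_by_key` maps (participant_id, condition) -> DlmoResult (or clock
    hours).  Samples without an entry keep phase_deg = NaN.
    """
    out = data.samples.copy()
    for sid, row in out.iterrows():
        key = (row["participant_id"], row["condition"])
        if key in dlmo_by_key:
            out.loc[sid, "phase_deg"] = assign_phase(row["clock_time_h"], dlmo_by_key[key])
    return ExpressionDataset(values=data.values.copy(), samples=out, flags=data.flags)


def read_melatonin_csv(path) -> list[MelatoninSeries]:
    """Read a melatonin CSV (participant_id, condition, time_h, concentration)
    into one series per participant/condition, times sorted ascending."""
    df = pd.read_csv(path)
    required = {"participant_id", "condition", "time_h", "concentration"}
    if not required.issubset(df.columns):
        raise ValueError(f"melatonin CSV must have columns {sorted(required)}")
    out = []
    for (pid, cond), grp in df.groupby(["participant_id", "condition"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            MelatoninSeries(
                participant_id=str(pid),
                condition=str(cond),
                times_h=grp["time_h"].to_numpy(),
                concentrations=grp["concentration"].to_numpy(),
            )
        )
    return out


def write_melatonin_csv(series_list: list[MelatoninSeries], path) -> None:
    rows = []
    for s in series_list:
        for t, c in zip(s.times_h, s.concentrations):
            rows.append((s.participant_id, s.condition, t, c))
    pd.DataFrame(
        rows, columns=["participant_id", "condition", "time_h", "concentration"]
    ).to_csv(path, index=False)


def compute_dlmo_table(series_list: list[MelatoninSeries], **kwargs) -> dict:
    """Map (participant_id, condition) -> DlmoResult for a list of series."""
    return {
        (s.participant_id, s.condition): compute_dlmo(s, **kwargs)
        for s in series_list
    }
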