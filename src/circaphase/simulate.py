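"""Synthetic cohort generator emulating a two-protocol circadian study.

Each participant undergoes one protocol — mistimed sleep (conditions
in_phase / out_of_phase, transcriptome sampled every 3 h) or sleep
deprivation (tsd_no_debt / tsd_debt, every 4 h) — with samples spanning a
circadian cycle, an hourly melatonin profile per condition whose
25%-of-range crossing defines the participant's DLMO, participant-specific
trait offsets on every feature, batch effects, and condition-dependent
fractions of rhythmic features.  Rhythmic feature sets are nested
(out_of_phase subset of tsd subset of in_phase) so that a core of features
stays rhythmic under every condition, as observed in blood.

All randomness flows through one seeded generator; a config's seed fully
determines the output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import DEGREES_PER_HOUR
from .dataset import CONDITIONS, ExpressionDataset
from .melatonin import MelatoninSeries

PROTOCOLS = {
    "mistimed_sleep": ("in_phase", "out_of_phase"),
    "sleep_deprivation": ("tsd_no_debt", "tsd_debt"),
}


@dataclass
class SyntheticConfig:
    """Study-scale knobs for the generator (defaults = desk-scale cohort)."""

    n_participants: int = 20
    n_features: int = 1000
    rhythmic_fraction: dict = field(
        default_factory=lambda: {
            "in_phase": 0.08,
            "out_of_phase": 0.01,
            "tsd_no_debt": 0.06,
            "tsd_debt": 0.06,
        }
    )
    amplitude_range_log2: tuple = (0.5, 1.5)
    mesor_mean_log2: float = 8.0
    mesor_sd_log2: float = 1.5
    trait_sd: float = 1.5
    noise_sd: float = 1.0
    n_batches: int = 2
    batch_effect_sd: float = 0.1
    samples_per_condition: dict = field(
        default_factory=lambda: {
            "in_phase": 8,
            "out_of_phase": 8,
            "tsd_no_debt": 7,
            "tsd_debt": 7,
        }
    )
    sampling_interval_h: dict = field(
        default_factory=lambda: {
            "in_phase": 3.0,
            "out_of_phase": 3.0,
            "tsd_no_debt": 4.0,
            "tsd_debt": 4.0,
        }
    )
    dlmo_mean_h: float = 21.5
    dlmo_sd_h: float = 1.0
    melatonin_baseline_pg_ml: float = 3.0
    melatonin_amplitude_pg_ml: float = 50.0
    melatonin_rise_steepness_h: float = 0.75
    flag_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for c, f in self.rhythmic_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"rhythmic fraction for {c} outside [0, 1]: {f}")
        if self.n_participants < 2 or self.n_features < 1:
            raise ValueError("need >= 2 participants and >= 1 feature")
        if not 0.0 <= self.flag_rate <= 1.0:
            raise ValueError("flag_rate outside [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    rhythmic: pd.DataFrame  # features x conditions, amplitude (0 = arrhythmic)
    acrophase_deg: pd.Series  # per-feature peak phase
    trait: pd.DataFrame  # features x participants
    dlmo_h: pd.Series  # per participant, clock hours
    true_phase_deg: pd.Series  # per sample
    protocol: pd.Series  # per participant

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "rhythmic_amplitude": self.rhythmic.to_dict(orient="index"),
                    "acrophase_deg": self.acrophase_deg.to_dict(),
                    "dlmo_h": self.dlmo_h.to_dict(),
                    "true_phase_deg": self.true_phase_deg.to_dict(),
                    "protocol": self.protocol.to_dict(),
                },
                fh,
            )


def _melatonin_profile(cfg: SyntheticConfig, dlmo_h: float):
    """Hourly (times, concentrations) profile: flat baseline then a logistic
    nocturnal rise whose 25%-of-range crossing sits at the configured DLMO."""
    s = cfg.melatonin_rise_steepness_h
    # logistic reaches 25% of its asymptote at t_mid - s*ln(3)
    t_mid = dlmo_h + s * math.log(3.0)
    times = dlmo_h + np.arange(-6.0, 7.0)  # 13 hourly samples around onset
    conc = cfg.melatonin_baseline_pg_ml + cfg.melatonin_amplitude_pg_ml / (
        1.0 + np.exp(-(times - t_mid) / s)
    )
    return times, conc


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[ExpressionDataset, list[MelatoninSeries], SyntheticTruth]:
    """Generate (expression dataset, melatonin series, ground truth).

    value(feature g, sample s of participant p, condition c) =
        mesor_g + trait_{p,g} + batch_{b(s),g}
        + A_{g,c} * cos(theta_s - phi_g) + Normal(0, noise_sd),
    with theta_s the sample's true phase from the participant's DLMO.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_features
    features = [f"FEAT{j:05d}" for j in range(N)]
    participants = [f"P{i:03d}" for i in range(cfg.n_participants)]

    # nested rhythmic sets: every condition's rhythmic features are a prefix
    # of one permutation, so low-fraction conditions are subsets of high ones
    perm = rng.permutation(N)
    amp = rng.uniform(*cfg.amplitude_range_log2, size=N)
    acro = rng.uniform(0.0, 360.0, size=N)
    mesor = rng.normal(cfg.mesor_mean_log2, cfg.mesor_sd_log2, size=N)
    rhythmic = pd.DataFrame(0.0, index=features, columns=list(CONDITIONS))
    for cond in CONDITIONS:
        k = round(cfg.rhythmic_fraction[cond] * N)
        idx = perm[:k]
        rhythmic.iloc[idx, rhythmic.columns.get_loc(cond)] = amp[idx]

    trait = pd.DataFrame(
        rng.normal(0.0, cfg.trait_sd, size=(N, cfg.n_participants)),
        index=features,
        columns=participants,
    )
    batch_effects = rng.normal(0.0, cfg.batch_effect_sd, size=(N, cfg.n_batches))
    dlmo = pd.Series(
        rng.normal(cfg.dlmo_mean_h, cfg.dlmo_sd_h, size=cfg.n_participants) % 24.0,
        index=participants,
        name="dlmo_h",
    )
    protocol = pd.Series(
        [list(PROTOCOLS)[i % 2] for i in range(cfg.n_participants)],
        index=participants,
        name="protocol",
    )

    cols, meta_rows, values_cols, true_phase = [], [], [], {}
    melatonin: list[MelatoninSeries] = []
    acro_arr = acro
    for i, pid in enumerate(participants):
        batch = int(rng.integers(cfg.n_batches))
        for cond in PROTOCOLS[protocol[pid]]:
            times, conc = _melatonin_profile(cfg, dlmo[pid])
            melatonin.append(
                MelatoninSeries(
                    participant_id=pid,
                    condition=cond,
                    times_h=times,
                    concentrations=conc,
                )
            )
            step = cfg.sampling_interval_h[cond]
            k = cfg.samples_per_condition[cond]
            start = dlmo[pid] + float(rng.uniform(0.0, step))
            amp_c = rhythmic[cond].to_numpy()
            for j in range(k):
                t = start + j * step
                theta = ((t - dlmo[pid]) % 24.0) * DEGREES_PER_HOUR
                sid = f"{pid}_{cond}_s{j:02d}"
                signal = amp_c * np.cos(np.deg2rad(theta - acro_arr))
                noise = rng.normal(0.0, cfg.noise_sd, size=N)
                vec = (
                    mesor
                    + trait[pid].to_numpy()
                    + batch_effects[:, batch]
                    + signal
                    + noise
                )
                cols.append(sid)
                values_cols.append(vec)
                true_phase[sid] = theta
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "participant_id": pid,
                        "condition": cond,
                        "batch": f"B{batch}",
                        "clock_time_h": round(t % 24.0, 4),
                        "phase_deg": theta,
                    }
                )

    values = pd.DataFrame(
        np.column_stack(values_cols), index=features, columns=cols
    )
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    flags = None
    if cfg.flag_rate > 0:
        flags = pd.DataFrame(
            (rng.random(values.shape) < cfg.flag_rate).astype(int),
            index=values.index,
            columns=values.columns,
        )
    data = ExpressionDataset(values=values, samples=samples, flags=flags)
    truth = SyntheticTruth(
        rhythmic=rhythmic,
        acrophase_deg=pd.Series(acro, index=features, name="acrophase_deg"),
        trait=trait,
        dlmo_h=dlmo,
        true_phase_deg=pd.Series(true_phase, name="true_phase_deg"),
        protocol=protocol,
    )
    return data, melatonin, truth


def split_cohort(
    data: ExpressionDataset,
    truth: SyntheticTruth,
    train_fraction: float = 0.5,
    balance_on: str = "protocol",
    seed: int = 0,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Participant-level train/validation split, stratified within label.

    All samples of a participant land in one set; per-stratum training
    counts match round(train_fraction * stratum size) so strata differ from
    the requested fraction by at most one participant.
    """
    participants = data.participants
    if len(participants) < 2:
        raise ValueError("cannot split a single-participant cohort")
    rng = np.random.default_rng(seed)
    if balance_on == "protocol":
        labels = truth.protocol
    elif balance_on == "condition":
        labels = data.samples.groupby("participant_id")["condition"].first()
    elif balance_on is None:
        labels = pd.Series("all", index=participants)
    else:
        raise ValueError(f"unknown balance label: {balance_on!r}")
    # per-stratum floor counts, then hand remainders to the strata with the
    # largest fractional parts so the global count hits round(frac * total)
    strata = {
        lab: sorted([p for p in participants if labels[p] == lab])
        for lab in sorted(labels.unique())
    }
    target_total = int(round(train_fraction * len(participants)))
    target_total = min(max(target_total, 1), len(participants) - 1)
    base = {lab: int(np.floor(train_fraction * len(m))) for lab, m in strata.items()}
    leftover = target_total - sum(base.values())
    frac_order = sorted(
        strata,
        key=lambda lab: (train_fraction * len(strata[lab])) % 1.0,
        reverse=True,
    )
    for lab in frac_order[:max(leftover, 0)]:
        base[lab] += 1
    train_pids: set = set()
    for lab, members in strata.items():
        k = min(base[lab], len(members))
        train_pids.update(rng.permutation(members)[:k])
    if not train_pids or train_pids == set(participants):
        raise ValueError("split left one side empty; adjust train_fraction")
    mask = data.samples["participant_id"].isin(train_pids)
    train = data.subset_samples(data.samples.index[mask])
    valid = data.subset_samples(data.samples.index[~mask])
    return train, valid
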