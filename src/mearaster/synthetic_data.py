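"""Ground-truth-labeled synthetic multiwell MEA recordings.

The study's recordings are not public, so this generator emulates them:
24-well/16-electrode plates, 10-minute epochs per concentration under
cumulative administration, rhythmic network bursts riding on sparse
background firing, and mechanism-specific concentration-dependent
changes in the five burst parameters (TS/NoB/IBI/DoB/SiB).

Burst onsets follow a Gamma-jittered quasi-periodic point process;
within-burst spike times are drawn from a peaked (Beta) envelope so a
well-defined pooled-rate maximum exists for IMFI estimation.  A drug
mechanism is a set of saturating monotone multiplier curves (Hill form)
acting on the generator parameters; multipliers are 1 at concentration
zero.  Every draw is seeded and fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mearaster.mea_io import (
    N_ELECTRODES,
    ConditionLabel,
    DoseSeriesRecording,
    SpikeTrain,
    WellRecording,
    write_spike_table,
)

# times are quantized to the spike-table precision so write/read round-trips
_TIME_QUANTUM = 1e-5

NEGATIVE_CLASS = "negative"

__all__ = [
    "NEGATIVE_CLASS",
    "SynthWellConfig",
    "DrugEffectModel",
    "generate_vehicle_recording",
    "apply_drug_effect",
    "generate_dose_series",
    "generate_labeled_dataset",
    "mechanism_library",
    "EFFECT_SIZES",
]

EFFECT_SIZES = {"small": 1.2, "medium": 2.0, "large": 3.0}


@dataclass(frozen=True)
class SynthWellConfig:
    """Generator parameters of one well's baseline (vehicle) activity.

    Defaults emulate a mature, rhythmically bursting culture: bursts
    every ~5 s involving 12 of 16 electrodes, 150 spikes per burst, and
    0.3 Hz/electrode of asynchronous background firing.
    """

    n_electrodes: int = N_ELECTRODES
    duration_s: float = 600.0
    burst_rate: float = 12.0  # bursts/min
    burst_duration_s: float = 1.0
    spikes_per_burst: float = 150.0
    participating_electrodes: int = 12
    background_rate: float = 0.3  # Hz/electrode
    timing_jitter_s: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.duration_s, self.burst_rate, self.burst_duration_s,
               self.spikes_per_burst, self.timing_jitter_s) <= 0:
            raise ValueError("rates and durations must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not 1 <= self.participating_electrodes <= self.n_electrodes:
            raise ValueError("participating_electrodes out of range")
        if self.burst_duration_s >= self.period_s:
            raise ValueError(
                f"burst duration {self.burst_duration_s}s >= burst period "
                f"{self.period_s:.3g}s: infeasible configuration"
            )

    @property
    def period_s(self) -> float:
        return 60.0 / self.burst_rate


@dataclass(frozen=True)
class DrugEffectModel:
    """Mechanism-specific multiplier curves over concentration.

    ``effects`` maps a generator parameter ("burst_rate",
    "burst_duration_s", "spikes_per_burst", "participating_electrodes",
    "background_rate", "timing_jitter_s") to its saturating maximal
    multiplier M; the multiplier at concentration c is M^frac with
    frac = c^h / (c^h + ec50^h), so multiplier(0) = 1, the curve is
    monotone toward M, and up- and down-regulation are symmetric folds
    (at the half-max concentration the fold is sqrt(M) either way).
    The electrode count is rounded and clipped to [1, 16] after scaling.
    """

    mechanism: str
    effects: Mapping[str, float]
    risk_class: str
    ec50: float = 1.0
    hill: float = 2.0

    _PARAMS = (
        "burst_rate",
        "burst_duration_s",
        "spikes_per_burst",
        "participating_electrodes",
        "background_rate",
        "timing_jitter_s",
    )

    def __post_init__(self):
        for p, m in self.effects.items():
            if p not in self._PARAMS:
                raise ValueError(f"unknown generator parameter {p!r}")
            if m <= 0:
                raise ValueError("multipliers must be positive")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")

    def multiplier(self, param: str, concentration: float) -> float:
        if concentration < 0:
            raise ValueError("concentration must be >= 0")
        m = self.effects.get(param, 1.0)
        if concentration == 0:
            return 1.0
        frac = concentration**self.hill / (concentration**self.hill + self.ec50**self.hill)
        return float(m**frac)


def apply_drug_effect(
    cfg: SynthWellConfig, model: DrugEffectModel, concentration: float
) -> SynthWellConfig:
    """Scale the generator parameters by the mechanism's multipliers."""
    updates = {
        p: getattr(cfg, p) * model.multiplier(p, concentration)
        for p in DrugEffectModel._PARAMS
    }
    updates["participating_electrodes"] = int(
        min(cfg.n_electrodes, max(1, round(updates["participating_electrodes"])))
    )
    return replace(cfg, **updates)  # SynthWellConfig re-validates feasibility


def _quantize(times: np.ndarray, duration: float) -> np.ndarray:
    """Snap to the spike-table grid, keep inside [0, duration].

    Grid collisions are resolved by nudging the later spike forward one
    quantum (the acquisition dead time exceeds the grid), so no spike is
    silently dropped.
    """
    t = np.sort(np.round(times / _TIME_QUANTUM)).astype(np.int64)
    for i in range(1, t.size):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1
    out = t * _TIME_QUANTUM
    return out[(out >= 0) & (out <= duration)]


def _generate_epoch(
    cfg: SynthWellConfig,
    condition: ConditionLabel,
    well_id: str,
    rng: np.random.Generator,
    participating: np.ndarray | None = None,
) -> WellRecording:
    period = cfg.period_s
    # Gamma-jittered quasi-periodic onsets: one burst per period slot,
    # displaced by centered Gamma noise with s.d. = timing_jitter; the
    # burst count is therefore floor(duration / period) up to edge drops
    n_slots = int(math.floor(cfg.duration_s / period))
    phase = rng.uniform(0.0, max(period - cfg.burst_duration_s, 1e-9))
    shape = 4.0
    scale = cfg.timing_jitter_s / math.sqrt(shape)
    jitter = rng.gamma(shape, scale, size=n_slots) - shape * scale
    onsets = np.sort(np.arange(n_slots) * period + phase + jitter)
    onsets = onsets[(onsets >= 0) & (onsets + cfg.burst_duration_s <= cfg.duration_s)]

    if participating is None:
        # which electrodes sit under the network is a property of the well,
        # not of the epoch; dose-series generation passes a per-well subset
        participating = np.sort(
            rng.choice(cfg.n_electrodes, cfg.participating_electrodes, replace=False)
        )
    elif cfg.participating_electrodes < participating.size:
        # a drug that silences part of the network drops electrodes from
        # the well's own subset, deterministically
        participating = participating[: cfg.participating_electrodes]
    elif cfg.participating_electrodes > participating.size:
        extra = [e for e in range(cfg.n_electrodes) if e not in set(participating)]
        participating = np.sort(
            np.r_[participating, extra[: cfg.participating_electrodes - participating.size]]
        )
    per_elec: list[list[np.ndarray]] = [[] for _ in range(cfg.n_electrodes)]
    for onset in onsets:
        n = int(round(cfg.spikes_per_burst))
        if n == 0:
            continue
        # peaked envelope -> well-defined pooled-rate maximum mid-burst
        offsets = onset + cfg.burst_duration_s * rng.beta(2.0, 2.0, size=n)
        elecs = participating[rng.integers(0, participating.size, size=n)]
        for e in np.unique(elecs):
            per_elec[e].append(offsets[elecs == e])
    if cfg.background_rate > 0:
        for e in range(cfg.n_electrodes):
            n_bg = rng.poisson(cfg.background_rate * cfg.duration_s)
            if n_bg:
                per_elec[e].append(rng.uniform(0, cfg.duration_s, size=n_bg))

    trains = []
    for e in range(cfg.n_electrodes):
        times = np.concatenate(per_elec[e]) if per_elec[e] else np.empty(0)
        trains.append(SpikeTrain(e, _quantize(times, cfg.duration_s)))
    return WellRecording(well_id, cfg.duration_s, tuple(trains), condition)


def generate_vehicle_recording(
    cfg: SynthWellConfig, well_id: str = "W00"
) -> WellRecording:
    """One vehicle (0.1% DMSO) epoch of baseline bursting activity."""
    rng = np.random.default_rng(cfg.seed)
    cond = ConditionLabel(
        compound="DMSO", concentration=0.1, concentration_unit="%v/v",
        is_vehicle=True, risk_class="seizure-free",
    )
    return _generate_epoch(cfg, cond, well_id, rng)


def generate_dose_series(
    cfg: SynthWellConfig,
    model: DrugEffectModel,
    concentrations: Sequence[float],
    seed: int,
    well_id: str = "W00",
    baseline_cv: float = 0.1,
) -> DoseSeriesRecording:
    """Vehicle epoch + one epoch per ascending concentration of one compound.

    Per-well baseline variability (lognormal, cv ``baseline_cv``) on the
    burst rate and burst size is drawn once per well, emulating
    differing initial states between wells.
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("need at least one concentration")
    if any(c2 <= c1 for c1, c2 in zip(concentrations, concentrations[1:])):
        raise ValueError("concentrations must be strictly ascending")
    ss = np.random.SeedSequence(seed)
    well_rng = np.random.default_rng(ss.spawn(1)[0])
    base = replace(
        cfg,
        burst_rate=cfg.burst_rate * well_rng.lognormal(0, baseline_cv),
        spikes_per_burst=cfg.spikes_per_burst * well_rng.lognormal(0, baseline_cv),
    )
    participating = np.sort(
        well_rng.choice(base.n_electrodes, base.participating_electrodes, replace=False)
    )
    epochs = []
    veh_cond = ConditionLabel(
        compound=model.mechanism, concentration=0.1, concentration_unit="%v/v",
        is_vehicle=True, risk_class=model.risk_class,
    )
    epoch_seeds = ss.spawn(1 + len(concentrations))
    epochs.append(
        _generate_epoch(base, veh_cond, well_id, np.random.default_rng(epoch_seeds[0]), participating)
    )
    for conc, es in zip(concentrations, epoch_seeds[1:]):
        dosed = apply_drug_effect(base, model, conc)
        cond = ConditionLabel(
            compound=model.mechanism, concentration=float(conc),
            concentration_unit="uM", is_vehicle=False, risk_class=model.risk_class,
        )
        epochs.append(_generate_epoch(dosed, cond, well_id, np.random.default_rng(es), participating))
    return DoseSeriesRecording(well_id, tuple(epochs))


def mechanism_library(effect_size: str = "large") -> dict[str, DrugEffectModel]:
    """13 positive mechanisms with distinct signatures + a null negative.

    Signatures combine up/down effects on burst rate, burst duration,
    burst size and background rate, echoing the mechanism diversity of
    real convulsant panels (potassium-channel block raising burst rate,
    GABA-A antagonism shortening bursts, glutamatergic agonism raising
    then suppressing firing, ...).  ``effect_size`` in {small, medium,
    large} sets the saturating fold change (x1.2 / x2 / x3; reciprocal
    for downward effects).
    """
    f = EFFECT_SIZES[effect_size]
    g = 1.0 / f
    # signatures are pairwise distinct along axes a raster image expresses:
    # burst rate, burst duration, electrode participation, background
    # firing, rhythm regularity, and ink density (which saturates, so no
    # two signatures differ by within-burst spike count alone)
    pos = {
        "nob_up": {"burst_rate": f},
        "nob_down_sib_up": {"burst_rate": g, "spikes_per_burst": f},
        "ts_down": {"spikes_per_burst": g, "background_rate": g, "burst_rate": g},
        "dob_down": {"burst_duration_s": g},
        "dob_up": {"burst_duration_s": f},
        "rate_down_dob_up": {"burst_rate": g, "burst_duration_s": f},
        "rate_up_dob_down": {"burst_rate": f, "burst_duration_s": g},
        "part_down": {"participating_electrodes": g},
        "bg_up": {"background_rate": f},
        "desync": {"burst_rate": g, "background_rate": f},
        "rate_up_part_down": {"burst_rate": f, "participating_electrodes": g},
        "dob_up_part_down": {"burst_duration_s": f, "participating_electrodes": g},
        "rate_down_part_down": {"burst_rate": g, "participating_electrodes": g},
    }
    lib = {
        name: DrugEffectModel(mechanism=name, effects=eff, risk_class="seizure-causing")
        for name, eff in pos.items()
    }
    lib[NEGATIVE_CLASS] = DrugEffectModel(
        mechanism=NEGATIVE_CLASS, effects={}, risk_class="seizure-free"
    )
    return lib


def generate_labeled_dataset(
    panel: Mapping[str, DrugEffectModel],
    wells_per_compound: int,
    concentrations: Sequence[float],
    seed: int,
    base_cfg: SynthWellConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[DoseSeriesRecording], pd.DataFrame]:
    """A full labeled plate: one dose series per compound x well.

    Returns the series plus a truth table (well, compound, epoch,
    concentration, is_vehicle, risk_class).  When ``out_dir`` is given
    the spike table, metadata sidecar and truth table are also written
    in the formats read back by ``mea_io.read_spike_table``.
    """
    base_cfg = base_cfg or SynthWellConfig()
    ss = np.random.SeedSequence(seed)
    well_seeds = ss.generate_state(len(panel) * wells_per_compound) % (2**31)
    series, truth_rows = [], []
    i = 0
    for name in panel:  # insertion order: deterministic
        model = panel[name]
        for w in range(wells_per_compound):
            well_id = f"{name}_w{w}"
            s = generate_dose_series(
                base_cfg, model, concentrations, seed=int(well_seeds[i]), well_id=well_id
            )
            series.append(s)
            for ei, epoch in enumerate(s.epochs):
                truth_rows.append(
                    {
                        "well": well_id,
                        "compound": name,
                        "epoch": ei,
                        "concentration": epoch.condition.concentration,
                        "is_vehicle": epoch.condition.is_vehicle,
                        "risk_class": model.risk_class,
                    }
                )
            i += 1
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_spike_table(series, out_dir / "spikes.tsv", out_dir / "metadata.yaml")
        truth.to_csv(out_dir / "truth.csv", index=False)
    return series, truth
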