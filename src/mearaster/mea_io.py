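"""Data model and I/O for multiwell MEA recordings.

A 24-well MEA plate carries 16 extracellular electrodes per well.  A
recording session produces, per well, an ordered sequence of 10-minute
epochs: a vehicle (0.1% DMSO) epoch first, then one epoch per cumulatively
administered concentration of a single compound.  This module defines the
in-memory containers for that structure, a plain-text spike-table format
with a metadata sidecar, and spike detection from raw voltage traces
(100-Hz high-pass filter, +/- 5.3 sigma threshold on baseline noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import signal

N_ELECTRODES = 16

__all__ = [
    "N_ELECTRODES",
    "SpikeTrain",
    "ConditionLabel",
    "WellRecording",
    "DoseSeriesRecording",
    "RawTrace",
    "SpikeTableError",
    "read_spike_table",
    "write_spike_table",
    "highpass_filter",
    "estimate_noise_sigma",
    "detect_spikes",
]


class SpikeTableError(ValueError):
    """Raised for malformed spike tables or metadata sidecars."""


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (seconds from epoch start) of one electrode.

    Times are strictly ascending; the electrode index runs 0-15.
    """

    electrode_index: int
    times: np.ndarray

    def __post_init__(self):
        if not 0 <= self.electrode_index < N_ELECTRODES:
            raise ValueError(f"electrode_index {self.electrode_index} out of range 0-{N_ELECTRODES - 1}")
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly ascending")
        if t.size and t[0] < 0:
            raise ValueError("spike times must be non-negative")
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ConditionLabel:
    """What was in the well during one epoch.

    ``concentration`` is a magnitude in ``concentration_unit`` (uM for
    compounds, ``%v/v`` for DMSO).  ``risk_class`` is the compound-level
    seizure-liability label when known.
    """

    compound: str
    concentration: float
    concentration_unit: str = "uM"
    is_vehicle: bool = False
    risk_class: str = "unknown"

    _RISK_CLASSES = ("seizure-causing", "seizure-free", "unknown")

    def __post_init__(self):
        if self.risk_class not in self._RISK_CLASSES:
            raise ValueError(f"risk_class must be one of {self._RISK_CLASSES}")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class WellRecording:
    """One well, one concentration epoch: 16 spike trains + condition."""

    well_id: str
    duration_s: float
    spike_trains: tuple[SpikeTrain, ...]
    condition: ConditionLabel

    def __post_init__(self):
        trains = tuple(self.spike_trains)
        if len(trains) != N_ELECTRODES:
            raise ValueError(f"expected {N_ELECTRODES} spike trains, got {len(trains)}")
        seen = [t.electrode_index for t in trains]
        if sorted(seen) != list(range(N_ELECTRODES)):
            raise ValueError("need exactly one spike train per electrode 0-15")
        for t in trains:
            if t.times.size and t.times[-1] > self.duration_s:
                raise ValueError(
                    f"well {self.well_id}: spike at {t.times[-1]:.5f}s exceeds duration {self.duration_s}s"
                )
        object.__setattr__(self, "spike_trains", tuple(sorted(trains, key=lambda t: t.electrode_index)))

    @property
    def total_spikes(self) -> int:
        return sum(t.n_spikes for t in self.spike_trains)

    def pooled_times(self) -> np.ndarray:
        """All 16 electrodes' spike times merged and sorted."""
        if self.total_spikes == 0:
            return np.empty(0)
        return np.sort(np.concatenate([t.times for t in self.spike_trains]))


@dataclass(frozen=True)
class DoseSeriesRecording:
    """Ordered epochs of one well: vehicle first, then ascending concentrations."""

    well_id: str
    epochs: tuple[WellRecording, ...]

    def __post_init__(self):
        epochs = tuple(self.epochs)
        if not epochs:
            raise ValueError("dose series must contain at least one epoch")
        if not epochs[0].condition.is_vehicle:
            raise ValueError(f"well {self.well_id}: first epoch must be the vehicle epoch")
        compounds = {e.condition.compound for e in epochs if not e.condition.is_vehicle}
        if len(compounds) > 1:
            raise ValueError(f"well {self.well_id}: multiple compounds in one series: {sorted(compounds)}")
        concs = [e.condition.concentration for e in epochs if not e.condition.is_vehicle]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError(f"well {self.well_id}: concentrations must be strictly increasing")
        for e in epochs:
            if e.well_id != self.well_id:
                raise ValueError("epoch well_id mismatch")
        object.__setattr__(self, "epochs", epochs)

    @property
    def vehicle(self) -> WellRecording:
        return self.epochs[0]

    @property
    def compound(self) -> str:
        for e in self.epochs:
            if not e.condition.is_vehicle:
                return e.condition.compound
        return self.epochs[0].condition.compound


@dataclass(frozen=True)
class RawTrace:
    """Raw extracellular voltage samples of one electrode (default 20 kHz)."""

    electrode_index: int
    samples: np.ndarray
    sampling_rate: float = 20_000.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


# ---------------------------------------------------------------------------
# Spike-table format: delimited text (well, electrode, time_s) + YAML sidecar.
#
# The sidecar maps well id -> ordered epoch list; each epoch declares
# compound, concentration, unit, vehicle flag, risk class and duration.
# Epoch boundaries are implicit: each epoch has its own 0-based timeline
# and rows carry an explicit epoch index.
# ---------------------------------------------------------------------------

_TABLE_HEADER = "well\tepoch\telectrode\ttime_s"
_TIME_FMT = "{:.5f}"


def write_spike_table(series: Sequence[DoseSeriesRecording], path, metadata_path) -> None:
    """Write dose-series recordings as a tab-delimited spike table + sidecar.

    Deterministic row order (well, epoch, electrode, time); times printed
    at 1e-5 s precision so a write/read/write cycle is byte-identical.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    lines = [_TABLE_HEADER]
    meta: dict = {"wells": {}}
    for s in series:
        meta["wells"][s.well_id] = [
            {
                "compound": e.condition.compound,
                "concentration": float(e.condition.concentration),
                "unit": e.condition.concentration_unit,
                "vehicle": bool(e.condition.is_vehicle),
                "risk_class": e.condition.risk_class,
                "duration_s": float(e.duration_s),
            }
            for e in s.epochs
        ]
        for ei, epoch in enumerate(s.epochs):
            for train in epoch.spike_trains:
                for t in train.times:
                    lines.append(
                        f"{s.well_id}\t{ei}\t{train.electrode_index}\t" + _TIME_FMT.format(t)
                    )
    path.write_text("\n".join(lines) + "\n")
    metadata_path.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_spike_table(path, metadata_path) -> list[DoseSeriesRecording]:
    """Read a spike table + metadata sidecar back into dose-series records."""
    path, metadata_path = Path(path), Path(metadata_path)
    meta = yaml.safe_load(metadata_path.read_text())
    if not isinstance(meta, dict) or "wells" not in meta:
        raise SpikeTableError(f"{metadata_path}: missing 'wells' section")

    # spikes[(well, epoch, electrode)] -> list of times
    spikes: dict[tuple[str, int, int], list[float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TABLE_HEADER:
            raise SpikeTableError(f"{path}: unexpected header {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                well, epoch_s, elec_s, time_s = line.split("\t")
                epoch, elec, t = int(epoch_s), int(elec_s), float(time_s)
            except ValueError as exc:
                raise SpikeTableError(f"{path}:{ln}: unparseable row {line!r}") from exc
            if well not in meta["wells"]:
                raise SpikeTableError(f"{path}:{ln}: unknown well {well!r}")
            if not 0 <= elec < N_ELECTRODES:
                raise SpikeTableError(f"{path}:{ln}: electrode {elec} out of range")
            if not 0 <= epoch < len(meta["wells"][well]):
                raise SpikeTableError(f"{path}:{ln}: epoch {epoch} undeclared for well {well!r}")
            spikes.setdefault((well, epoch, elec), []).append(t)

    series = []
    for well_id, epoch_meta in meta["wells"].items():
        if not any(em.get("vehicle") for em in epoch_meta):
            raise SpikeTableError(f"well {well_id!r}: no vehicle epoch declared")
        epochs = []
        for ei, em in enumerate(epoch_meta):
            cond = ConditionLabel(
                compound=str(em["compound"]),
                concentration=float(em["concentration"]),
                concentration_unit=str(em.get("unit", "uM")),
                is_vehicle=bool(em.get("vehicle", False)),
                risk_class=str(em.get("risk_class", "unknown")),
            )
            trains = []
            for elec in range(N_ELECTRODES):
                times = np.array(sorted(spikes.get((well_id, ei, elec), [])))
                trains.append(SpikeTrain(elec, times))
            epochs.append(
                WellRecording(well_id, float(em["duration_s"]), tuple(trains), cond)
            )
        series.append(DoseSeriesRecording(well_id, tuple(epochs)))
    return series


# ---------------------------------------------------------------------------
# Spike detection from raw traces
# ---------------------------------------------------------------------------


def highpass_filter(trace: RawTrace, cutoff_hz: float = 100.0) -> RawTrace:
    """High-pass filter a raw trace (4th-order zero-phase Butterworth).

    Removes the DC/LFP component below ``cutoff_hz`` so that threshold
    crossings reflect spike deflections only.
    """
    nyq = trace.sampling_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if not np.all(np.isfinite(trace.samples)):
        raise ValueError("trace contains non-finite samples")
    sos = signal.butter(4, cutoff_hz / nyq, btype="highpass", output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=filtered)


def estimate_noise_sigma(trace: RawTrace) -> float:
    """Standard deviation of the baseline noise during quiescent periods.

    Iterative: sigma over the whole filtered trace; mask +/-2 ms around
    samples exceeding 4 sigma (spike deflections); recompute.  Two passes.
    """
    x = trace.samples
    if x.size == 0 or np.all(x == 0):
        warnings.warn("all-zero trace: noise sigma is 0", stacklevel=2)
        return 0.0
    half_win = max(1, int(round(0.002 * trace.sampling_rate)))
    sigma = float(np.std(x))
    for _ in range(2):
        if sigma == 0:
            break
        hot = np.flatnonzero(np.abs(x) > 4.0 * sigma)
        mask = np.ones(x.size, dtype=bool)
        for i in hot:
            mask[max(0, i - half_win) : i + half_win + 1] = False
        quiet = x[mask]
        if quiet.size < 2:
            break
        sigma = float(np.std(quiet))
    return sigma


def detect_spikes(
    trace: RawTrace,
    sigma: float,
    k: float = 5.3,
    dead_time_s: float = 0.001,
) -> SpikeTrain:
    """Threshold spike detection on a filtered trace.

    A spike is counted where |v| strictly exceeds ``k * sigma``; each
    maximal contiguous supra-threshold run is one event, timed at its
    extreme-|v| sample.  Events closer than ``dead_time_s`` to the
    previous accepted spike are discarded.
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be positive")
    x = trace.samples
    if sigma <= 0 or x.size == 0:
        return SpikeTrain(trace.electrode_index, np.empty(0))
    above = np.abs(x) > k * sigma
    if not above.any():
        return SpikeTrain(trace.electrode_index, np.empty(0))
    # event boundaries = edges of supra-threshold runs
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, x.size]
    times = []
    last = -np.inf
    for s, e in zip(starts, ends):
        peak = s + int(np.argmax(np.abs(x[s:e])))
        t = peak / trace.sampling_rate
        if t - last >= dead_time_s:
            times.append(t)
            last = t
    return SpikeTrain(trace.electrode_index, np.array(times))
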