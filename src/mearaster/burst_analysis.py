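"""Network-burst detection and dose-response burst analytics.

Network bursts — brief epochs of dense, near-synchronous firing across
many electrodes — are detected by a four-step pooled-ISI method:

1. pool all 16 electrodes' spikes into one sorted train;
2. candidate bursts = maximal runs of pooled inter-spike intervals
   <= ``isi_th_s``;
3. merge candidates separated by < ``merge_gap_s``;
4. discard candidates with fewer than ``min_spikes`` spikes or fewer
   than ``min_electrodes`` participating electrodes.

From the detected bursts the five per-epoch parameters are computed:
TS (total spikes), NoB (number of network bursts), IBI (mean
inter-network-burst interval), DoB (mean burst duration), SiB (mean
spikes in a burst).  Dose-response summaries express each parameter as
percent of the well's own vehicle epoch; significance vs. vehicle is
assessed by one-way ANOVA followed by Dunnett's test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mearaster.mea_io import WellRecording

PARAMETERS = ("TS", "NoB", "IBI", "DoB", "SiB")

__all__ = [
    "PARAMETERS",
    "BurstConfig",
    "NetworkBurst",
    "BurstParameterSet",
    "SignificanceResult",
    "detect_network_bursts",
    "compute_burst_parameters",
    "percent_of_control",
    "dose_response_table",
    "dunnett_vs_vehicle",
]


@dataclass(frozen=True)
class BurstConfig:
    """Thresholds of the four-step network-burst detector.

    isi_th_s : maximal pooled inter-spike interval inside a burst (s).
    merge_gap_s : candidate bursts closer than this are merged (s).
    min_spikes : minimal pooled spike count of a burst.
    min_electrodes : minimal number of participating electrodes.
    rate_bin_s : bin width for the pooled-rate peak time (s).
    ibi_convention : "end_to_onset" (default) or "onset_to_onset".
    """

    isi_th_s: float = 0.1
    merge_gap_s: float = 0.1
    min_spikes: int = 50
    min_electrodes: int = 4
    rate_bin_s: float = 0.01
    ibi_convention: str = "end_to_onset"

    def __post_init__(self):
        if self.isi_th_s <= 0 or self.merge_gap_s <= 0 or self.rate_bin_s <= 0:
            raise ValueError("time thresholds must be positive")
        if self.min_spikes < 1 or self.min_electrodes < 1:
            raise ValueError("count thresholds must be >= 1")
        if self.ibi_convention not in ("end_to_onset", "onset_to_onset"):
            raise ValueError("unknown ibi_convention")


@dataclass(frozen=True)
class NetworkBurst:
    t_start: float
    t_end: float
    spike_count: int
    n_electrodes: int
    peak_rate_time: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("burst must have t_start < t_end")
        if not self.t_start <= self.peak_rate_time <= self.t_end:
            raise ValueError("peak_rate_time must lie within the burst")


@dataclass(frozen=True)
class BurstParameterSet:
    """The five burst parameters of one epoch; undefined values are NaN."""

    TS: float
    NoB: float
    IBI: float
    DoB: float
    SiB: float

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARAMETERS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAMETERS])


@dataclass(frozen=True)
class SignificanceResult:
    parameter: str
    concentration: float
    p_adjusted: float
    significant_05: bool
    significant_01: bool


def detect_network_bursts(rec: WellRecording, cfg: BurstConfig | None = None) -> list[NetworkBurst]:
    """Detect network bursts in one epoch with the four-step method."""
    cfg = cfg or BurstConfig()
    pooled, elec = _pooled_with_electrodes(rec)
    if pooled.size == 0:
        return []

    # step 2: maximal runs of pooled ISIs <= isi_th_s
    gaps = np.diff(pooled)
    breaks = np.flatnonzero(gaps > cfg.isi_th_s)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, pooled.size - 1]  # inclusive indices

    # step 3: merge candidates separated by < merge_gap_s
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and pooled[s] - pooled[merged[-1][1]] < cfg.merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # step 4: count/electrode filters
    bursts = []
    for s, e in merged:
        count = e - s + 1
        n_elec = len(set(elec[s : e + 1]))
        if count < cfg.min_spikes or n_elec < cfg.min_electrodes:
            continue
        t0, t1 = pooled[s], pooled[e]
        bursts.append(
            NetworkBurst(
                t_start=float(t0),
                t_end=float(t1) if t1 > t0 else float(t0) + 1e-9,
                spike_count=int(count),
                n_electrodes=int(n_elec),
                peak_rate_time=_peak_rate_time(pooled[s : e + 1], cfg.rate_bin_s),
            )
        )
    return bursts


def _pooled_with_electrodes(rec: WellRecording) -> tuple[np.ndarray, np.ndarray]:
    times, elecs = [], []
    for train in rec.spike_trains:
        times.append(train.times)
        elecs.append(np.full(train.times.size, train.electrode_index))
    t = np.concatenate(times) if times else np.empty(0)
    e = np.concatenate(elecs) if elecs else np.empty(0, dtype=int)
    order = np.argsort(t, kind="stable")
    return t[order], e[order].astype(int)


def _peak_rate_time(times: np.ndarray, bin_s: float) -> float:
    """Center of the fullest rate bin inside a burst; ties -> earliest bin."""
    t0, t1 = times[0], times[-1]
    n_bins = max(1, int(math.ceil((t1 - t0) / bin_s)))
    counts, edges = np.histogram(times, bins=n_bins, range=(t0, t0 + n_bins * bin_s))
    i = int(np.argmax(counts))  # argmax takes the first maximal bin
    center = (edges[i] + edges[i + 1]) / 2.0
    return float(min(max(center, t0), t1))


def compute_burst_parameters(
    rec: WellRecording, bursts: Sequence[NetworkBurst], cfg: BurstConfig | None = None
) -> BurstParameterSet:
    """TS/NoB/IBI/DoB/SiB of one epoch; NaN where undefined.

    IBI is undefined with fewer than 2 bursts, DoB/SiB with fewer than 1.
    """
    cfg = cfg or BurstConfig()
    ts = float(rec.total_spikes)
    nob = float(len(bursts))
    if bursts:
        dob = float(np.mean([b.t_end - b.t_start for b in bursts]))
        sib = float(np.mean([b.spike_count for b in bursts]))
    else:
        dob = sib = math.nan
    if len(bursts) >= 2:
        if cfg.ibi_convention == "onset_to_onset":
            gaps = [b2.t_start - b1.t_start for b1, b2 in zip(bursts, bursts[1:])]
        else:
            gaps = [b2.t_start - b1.t_end for b1, b2 in zip(bursts, bursts[1:])]
        ibi = float(np.mean(gaps))
    else:
        ibi = math.nan
    return BurstParameterSet(TS=ts, NoB=nob, IBI=ibi, DoB=dob, SiB=sib)


def percent_of_control(
    drug: BurstParameterSet,
    vehicle: BurstParameterSet,
) -> dict[str, float]:
    """Each parameter as 100 x drug/vehicle; NaN when vehicle is 0 or NaN."""
    out = {}
    for p in PARAMETERS:
        v, d = getattr(vehicle, p), getattr(drug, p)
        if not math.isfinite(v) or v == 0 or not math.isfinite(d):
            if math.isfinite(d) and (not math.isfinite(v) or v == 0):
                warnings.warn(f"vehicle {p} is 0 or undefined; % of control missing", stacklevel=2)
            out[p] = math.nan
        else:
            out[p] = 100.0 * d / v
    return out


def dose_response_table(per_well_percent: pd.DataFrame) -> pd.DataFrame:
    """Mean % of control +/- SEM per compound x concentration x parameter.

    ``per_well_percent`` has columns (compound, concentration, well,
    parameter, percent); rows with NaN percent are excluded from the
    mean with a logged count.  SEM = sd / sqrt(n) (0 when n = 1).
    """
    df = per_well_percent.copy()
    n_missing = int(df["percent"].isna().sum())
    if n_missing:
        warnings.warn(f"excluding {n_missing} undefined %-of-control values", stacklevel=2)
    df = df.dropna(subset=["percent"])
    rows = []
    for (compound, conc, param), grp in df.groupby(
        ["compound", "concentration", "parameter"], sort=True
    ):
        vals = grp["percent"].to_numpy(float)
        n = vals.size
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "compound": compound,
                "concentration": conc,
                "parameter": param,
                "mean_percent": float(np.mean(vals)),
                "sem": sem,
                "n_wells": int(n),
            }
        )
    return pd.DataFrame(rows, columns=["compound", "concentration", "parameter", "mean_percent", "sem", "n_wells"])


def plot_dose_response(
    table: pd.DataFrame,
    compound: str,
    out_path,
    significance: pd.DataFrame | None = None,
):
    """Per-parameter %-of-control curves (mean ± SEM) for one compound.

    Stars mark concentrations significant vs. vehicle (* p<0.05,
    ** p<0.01) when a significance table is supplied.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table.compound == compound]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for param in PARAMETERS:
        rows = sub[sub.parameter == param].sort_values("concentration")
        if rows.empty:
            continue
        ax.errorbar(rows.concentration, rows.mean_percent, yerr=rows["sem"],
                    marker="o", capsize=2, label=param)
        if significance is not None:
            sig = significance[(significance.compound == compound)
                               & (significance.parameter == param)]
            for _, r in sig.iterrows():
                if r.sig_05:
                    y = float(rows[rows.concentration == r.concentration].mean_percent.iloc[0])
                    ax.annotate("**" if r.sig_01 else "*",
                                (r.concentration, y), textcoords="offset points",
                                xytext=(0, 6), ha="center")
    ax.axhline(100.0, color="gray", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_xlabel("concentration")
    ax.set_ylabel("% of vehicle control")
    ax.set_title(compound)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def dunnett_vs_vehicle(
    groups: Mapping[float, Sequence[float]],
    vehicle: Sequence[float],
    parameter: str = "",
    alpha: float = 0.05,
) -> list[SignificanceResult]:
    """Each concentration vs. vehicle: one-way ANOVA, then Dunnett's test.

    The Dunnett family is all concentrations of one parameter/compound,
    gated on the omnibus ANOVA: when ANOVA p >= alpha no concentration is
    flagged.  Degenerate input (zero variance everywhere) yields p = 1.
    """
    concs = sorted(groups)
    samples = [np.asarray(groups[c], float) for c in concs]
    control = np.asarray(vehicle, float)
    if any(s.size < 2 for s in samples) or control.size < 2:
        raise ValueError("need >= 2 observations per group for ANOVA/Dunnett")

    pooled = np.concatenate(samples + [control])
    if np.allclose(pooled, pooled[0]):
        warnings.warn("zero variance everywhere: p = 1 by convention", stacklevel=2)
        return [SignificanceResult(parameter, c, 1.0, False, False) for c in concs]

    anova_p = float(stats.f_oneway(control, *samples).pvalue)
    dunnett_p = stats.dunnett(*samples, control=control).pvalue
    gate = anova_p < alpha
    out = []
    for c, p in zip(concs, dunnett_p):
        p = float(min(max(p, 0.0), 1.0))
        out.append(
            SignificanceResult(
                parameter=parameter,
                concentration=c,
                p_adjusted=p,
                significant_05=bool(gate and p < 0.05),
                significant_01=bool(gate and p < 0.01),
            )
        )
    return out
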