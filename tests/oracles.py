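"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal method
available (pairwise enumeration, exhaustive scans, plain loops) and
share no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def auc_pairwise(scores, labels) -> float:
    """AUC as the pairwise rank statistic: (concordant + ties/2) / (P*N)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def operating_point_exhaustive(fpr, tpr, slope) -> int:
    """Index of the ROC vertex maximizing TPR - S*FPR; ties -> smallest FPR."""
    best_i, best_val = 0, -np.inf
    order = sorted(range(len(fpr)), key=lambda i: (fpr[i], tpr[i]))
    for i in order:
        v = tpr[i] - slope * fpr[i]
        if v > best_val + 1e-12:
            best_val, best_i = v, i
    return best_i


def pooled_isi_bursts(spike_times_by_electrode, isi_th, merge_gap, min_spikes, min_electrodes):
    """Literal four-step network-burst detection on pooled spikes.

    Returns a list of (t_start, t_end, spike_count, n_electrodes).
    """
    events = []
    for elec, times in enumerate(spike_times_by_electrode):
        events.extend((float(t), elec) for t in times)
    events.sort()
    if not events:
        return []
    # step 2: split where pooled ISI exceeds the threshold
    runs, current = [], [events[0]]
    for prev, nxt in zip(events, events[1:]):
        if nxt[0] - prev[0] <= isi_th:
            current.append(nxt)
        else:
            runs.append(current)
            current = [nxt]
    runs.append(current)
    # step 3: merge runs separated by < merge_gap
    merged = [runs[0]]
    for run in runs[1:]:
        if run[0][0] - merged[-1][-1][0] < merge_gap:
            merged[-1] = merged[-1] + run
        else:
            merged.append(run)
    # step 4: filters
    out = []
    for run in merged:
        electrodes = {e for _, e in run}
        if len(run) >= min_spikes and len(electrodes) >= min_electrodes:
            out.append((run[0][0], run[-1][0], len(run), len(electrodes)))
    return out
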