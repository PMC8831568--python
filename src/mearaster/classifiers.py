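"""Seizure-risk and drug-identification classifiers.

The core models are shallow pattern-recognition networks on the 4096-d
raster-image features: 4096 inputs -> sigmoid hidden layer (9 units for
the 2-class risk model, 120 for the 14-class drug-ID model) -> softmax
output, trained by full-batch Adam on the cross-entropy with early
stopping on a 75/25 window split of the training wells.  Evaluation is
always grouped by well: held-out wells contribute no windows to
training (holdout scheme), or every well is held out in turn with five
replicate models per fold (leave-one-well-out).

Per-window positive probabilities are aggregated to a per-well risk
(fraction of windows called positive, or mean probability) and then to
a per-concentration risk (mean over wells) with a 50% call threshold.

SVM baselines on the same features (linear SVM), and on 34 spike
time-series parameters or the five burst parameters (one-class and
multi-class SVM), are provided through scikit-learn.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC, OneClassSVM

from mearaster.burst_analysis import BurstConfig, compute_burst_parameters, detect_network_bursts
from mearaster.features import FEATURE_DIM, FeatureVector
from mearaster.mea_io import WellRecording

__all__ = [
    "PatternNetSpec",
    "TrainedClassifier",
    "DatasetSplit",
    "FeatureDataset",
    "RiskPrediction",
    "LeaveOneWellOutResult",
    "LeakageError",
    "train_pattern_net",
    "predict_windows",
    "aggregate_risk",
    "run_holdout",
    "run_leave_one_well_out",
    "aggregate_drug_id",
    "train_linear_svm",
    "compute_timeseries_features",
    "one_class_risk_baseline",
    "multiclass_svm_drug_id",
]

TIMESERIES_DIM = 34


class LeakageError(RuntimeError):
    """A test well's windows leaked into training."""


@dataclass(frozen=True)
class PatternNetSpec:
    """Architecture + training knobs of a pattern-recognition network."""

    input_dim: int = FEATURE_DIM
    hidden_units: int = 9
    n_classes: int = 2
    max_iterations: int = 600
    learning_rate: float = 0.01
    l2: float = 1e-3
    patience: int = 20  # validation checks without improvement
    eval_every: int = 5  # iterations between validation checks
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class TrainedClassifier:
    """Trained pattern net: weights, input scaler, class labels, training log.

    Inputs are standardized with the training partition's per-dimension
    mean and s.d. (stored here) before entering the network.
    """

    spec: PatternNetSpec
    w1: np.ndarray  # (input_dim, hidden)
    b1: np.ndarray
    w2: np.ndarray  # (hidden, n_classes)
    b2: np.ndarray
    classes: tuple[str, ...]
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    training_log: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DatasetSplit:
    """75/25 window split within training wells + fully held-out test wells."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_wells: tuple[str, ...]


@dataclass
class FeatureDataset:
    """Feature matrix + window provenance for the training schemes."""

    X: np.ndarray  # (n, input_dim) float32
    labels: np.ndarray  # (n,) str
    wells: np.ndarray  # (n,) str
    compounds: np.ndarray
    concentrations: np.ndarray
    is_vehicle: np.ndarray

    def __post_init__(self):
        n = self.X.shape[0]
        for arr in (self.labels, self.wells, self.compounds, self.concentrations, self.is_vehicle):
            if len(arr) != n:
                raise ValueError("provenance arrays must match the feature matrix")

    @classmethod
    def from_features(
        cls, features: Sequence[FeatureVector], labels: Sequence[str]
    ) -> "FeatureDataset":
        X = np.stack([f.values for f in features]).astype(np.float32)
        return cls(
            X=X,
            labels=np.asarray(labels, dtype=object),
            wells=np.array([f.well_id for f in features], dtype=object),
            compounds=np.array([f.compound for f in features], dtype=object),
            concentrations=np.array([f.concentration for f in features]),
            is_vehicle=np.array([f.is_vehicle for f in features]),
        )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            self.X[idx], self.labels[idx], self.wells[idx],
            self.compounds[idx], self.concentrations[idx], self.is_vehicle[idx],
        )


@dataclass
class RiskPrediction:
    """Window -> well -> concentration risk aggregation."""

    window_probs: np.ndarray
    per_well: dict  # (concentration, well) -> risk
    per_concentration: dict  # concentration -> risk in [0, 1]
    call: dict  # concentration -> bool (risk >= 0.5)
    mode: str


# ---------------------------------------------------------------------------
# Pattern net (numpy, full-batch Adam, early stopping)
# ---------------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(X, w1, b1, w2, b2):
    h = 1.0 / (1.0 + np.exp(-np.clip(X @ w1 + b1, -60.0, 60.0)))
    return h, _softmax(h @ w2 + b2)


def _xent(p: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None))))


def train_pattern_net(
    X: np.ndarray,
    labels: Sequence[str],
    split_train_idx: np.ndarray,
    split_val_idx: np.ndarray,
    spec: PatternNetSpec,
) -> TrainedClassifier:
    """Train a sigmoid-hidden softmax net with early stopping.

    Full-batch Adam on the cross-entropy; the validation partition is
    evaluated every iteration and the best weights are restored after
    ``patience`` checks without improvement.  Deterministic given
    (data, spec.seed).
    """
    X = np.asarray(X, dtype=np.float32)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    labels = np.asarray(labels, dtype=object)
    tr, va = np.asarray(split_train_idx), np.asarray(split_val_idx)
    classes = tuple(sorted(set(labels[np.r_[tr, va]])))
    if len(classes) != spec.n_classes:
        raise ValueError(
            f"training data has {len(classes)} classes, spec declares {spec.n_classes} "
            f"(classes present: {classes})"
        )
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"feature dim {X.shape[1]} != spec.input_dim {spec.input_dim}")
    cls_index = {c: i for i, c in enumerate(classes)}
    y = np.full(len(labels), -1)
    in_scheme = np.isin(labels.astype(str), [str(c) for c in classes])
    y[in_scheme] = [cls_index[l] for l in labels[in_scheme]]
    for c in classes:
        if c not in set(labels[tr]):
            raise ValueError(f"class {c!r} absent from the training partition")

    rng = np.random.default_rng(spec.seed)
    d, h, k = spec.input_dim, spec.hidden_units, spec.n_classes
    # Glorot-uniform init
    lim1, lim2 = math.sqrt(6.0 / (d + h)), math.sqrt(6.0 / (h + k))
    w1 = rng.uniform(-lim1, lim1, (d, h)).astype(np.float32)
    w2 = rng.uniform(-lim2, lim2, (h, k)).astype(np.float32)
    b1 = np.zeros(h, dtype=np.float32)
    b2 = np.zeros(k, dtype=np.float32)

    # standardize inputs on the training partition (stored with the model)
    x_mean = X[tr].mean(axis=0)
    x_scale = X[tr].std(axis=0) + np.float32(1e-6)
    Xtr = (X[tr] - x_mean) / x_scale
    Xva = (X[va] - x_mean) / x_scale
    ytr, yva = y[tr], y[va]
    params = [w1, b1, w2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_val, best_params, since_best = math.inf, [p.copy() for p in params], 0
    losses = []
    n = len(ytr)
    for it in range(1, spec.max_iterations + 1):
        hdn, p = _forward(Xtr, *params)
        loss = _xent(p, ytr)
        # backprop (L2 penalty on the weight matrices only)
        dz2 = p.copy()
        dz2[np.arange(n), ytr] -= 1.0
        dz2 /= n
        gw2 = hdn.T @ dz2 + spec.l2 * params[2]
        gb2 = dz2.sum(axis=0)
        dh = dz2 @ params[2].T * hdn * (1.0 - hdn)
        gw1 = Xtr.T @ dh + spec.l2 * params[0]
        gb1 = dh.sum(axis=0)
        for p_i, g in zip(range(4), (gw1, gb1, gw2, gb2)):
            m[p_i] = beta1 * m[p_i] + (1 - beta1) * g
            v[p_i] = beta2 * v[p_i] + (1 - beta2) * g * g
            mh = m[p_i] / (1 - beta1**it)
            vh = v[p_i] / (1 - beta2**it)
            params[p_i] -= (spec.learning_rate * mh / (np.sqrt(vh) + eps)).astype(np.float32)
        if it % spec.eval_every == 0 or it == spec.max_iterations:
            _, pv = _forward(Xva, *params)
            val_loss = _xent(pv, yva)
            losses.append((loss, val_loss))
            if val_loss < best_val - 1e-6:
                best_val, since_best = val_loss, 0
                best_params = [p.copy() for p in params]
            else:
                since_best += 1
                if since_best >= spec.patience:
                    break
    w1, b1, w2, b2 = best_params
    return TrainedClassifier(
        spec=spec, w1=w1, b1=b1, w2=w2, b2=b2, classes=classes,
        x_mean=x_mean, x_scale=x_scale,
        training_log={"iterations": len(losses), "final_train_loss": losses[-1][0],
                      "best_val_loss": best_val},
    )


def predict_windows(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Per-window class probabilities (rows sum to 1)."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise ValueError(f"expected (n, {model.spec.input_dim}) features, got {X.shape}")
    if model.x_mean is not None:
        X = (X - model.x_mean) / model.x_scale
    _, p = _forward(X, model.w1, model.b1, model.w2, model.b2)
    p = p.astype(np.float64)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_risk(
    positive_probs: np.ndarray,
    wells: Sequence[str],
    concentrations: Sequence[float],
    mode: str = "proportion",
) -> RiskPrediction:
    """Window probabilities -> well risk -> concentration risk.

    mode "proportion": well risk = fraction of its windows with positive
    probability >= 0.5.  mode "mean_prob": well risk = mean positive
    probability.  Concentration risk = mean over wells; call at 50%.
    """
    if mode not in ("proportion", "mean_prob"):
        raise ValueError("mode must be 'proportion' or 'mean_prob'")
    probs = np.asarray(positive_probs, dtype=float)
    wells = np.asarray(wells, dtype=object)
    concs = np.asarray(concentrations)
    if probs.size == 0:
        raise ValueError("empty prediction group")
    per_well: dict = {}
    for key in sorted({(c, w) for c, w in zip(concs, wells)}):
        sel = (concs == key[0]) & (wells == key[1])
        p = probs[sel]
        per_well[key] = float(np.mean(p >= 0.5)) if mode == "proportion" else float(np.mean(p))
    per_conc = {}
    for c in sorted({k[0] for k in per_well}):
        vals = [r for (cc, _), r in per_well.items() if cc == c]
        per_conc[c] = float(np.mean(vals))
    call = {c: r >= 0.5 for c, r in per_conc.items()}
    return RiskPrediction(probs, per_well, per_conc, call, mode)


# ---------------------------------------------------------------------------
# Training schemes
# ---------------------------------------------------------------------------


def make_split(
    dataset: FeatureDataset,
    test_wells: Sequence[str],
    train_fraction: float = 0.75,
    seed: int = 0,
    train_wells: Sequence[str] | None = None,
) -> DatasetSplit:
    """Window-level 75/25 split within training wells; test strictly by well."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1 "
                         "(a validation partition is required for early stopping)")
    test_wells = tuple(test_wells)
    all_wells = set(dataset.wells)
    unknown = set(test_wells) - all_wells
    if unknown:
        raise ValueError(f"unknown test wells {sorted(unknown)}")
    if train_wells is None:
        train_wells = sorted(all_wells - set(test_wells))
    if set(train_wells) & set(test_wells):
        raise LeakageError(
            f"wells {sorted(set(train_wells) & set(test_wells))} appear in both "
            "the training and test sets"
        )
    pool = np.flatnonzero(np.isin(dataset.wells, list(train_wells)))
    rng = np.random.default_rng(seed)
    pool = rng.permutation(pool)
    n_train = int(round(train_fraction * pool.size))
    return DatasetSplit(
        train_idx=np.sort(pool[:n_train]),
        val_idx=np.sort(pool[n_train:]),
        test_wells=test_wells,
    )


def _assert_no_leakage(dataset: FeatureDataset, split: DatasetSplit) -> None:
    used = set(dataset.wells[split.train_idx]) | set(dataset.wells[split.val_idx])
    leak = used & set(split.test_wells)
    if leak:
        raise LeakageError(f"test wells {sorted(leak)} contributed training windows")


def run_holdout(
    dataset: FeatureDataset,
    spec: PatternNetSpec,
    test_wells: Sequence[str],
    train_fraction: float = 0.75,
    train_wells: Sequence[str] | None = None,
) -> tuple[TrainedClassifier, np.ndarray, np.ndarray]:
    """Holdout scheme: train on some wells, evaluate on unlearned wells.

    Returns (model, test window probabilities, test window indices).
    """
    split = make_split(dataset, test_wells, train_fraction, spec.seed, train_wells)
    _assert_no_leakage(dataset, split)
    model = train_pattern_net(dataset.X, dataset.labels, split.train_idx, split.val_idx, spec)
    test_idx = np.flatnonzero(np.isin(dataset.wells, list(split.test_wells)))
    probs = predict_windows(model, dataset.X[test_idx])
    return model, probs, test_idx


@dataclass
class LeaveOneWellOutResult:
    """Per held-out well: averaged window distributions over R replicate models."""

    well_probs: dict  # well -> (n_windows, n_classes) mean distribution
    well_window_idx: dict  # well -> indices into the dataset
    per_model_probs: dict  # well -> list of R (n_windows, n_classes) arrays
    classes: tuple[str, ...]
    n_models: int


def run_leave_one_well_out(
    dataset: FeatureDataset,
    spec: PatternNetSpec,
    replicates: int = 5,
    train_fraction: float = 0.75,
) -> LeaveOneWellOutResult:
    """Each well held out in turn; ``replicates`` models per fold.

    Replicate models differ only by seed (init + split shuffling); the
    held-out well's window distributions are the element-wise mean over
    its replicate models.  W wells x R replicates models are trained.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    wells = sorted(set(dataset.wells))
    if len(wells) < 2:
        raise ValueError("leave-one-well-out needs >= 2 wells")
    well_probs, well_idx, per_model = {}, {}, {}
    classes: tuple[str, ...] = ()
    n_models = 0
    for w in wells:
        reps = []
        test_idx = np.flatnonzero(dataset.wells == w)
        for r in range(replicates):
            rep_spec = PatternNetSpec(
                **{**spec.__dict__, "seed": spec.seed + 1000 * r + zlib.crc32(w.encode()) % 997}
            )
            split = make_split(dataset, (w,), train_fraction, rep_spec.seed)
            _assert_no_leakage(dataset, split)
            model = train_pattern_net(
                dataset.X, dataset.labels, split.train_idx, split.val_idx, rep_spec
            )
            classes = model.classes
            reps.append(predict_windows(model, dataset.X[test_idx]))
            n_models += 1
        well_probs[w] = np.mean(reps, axis=0)
        well_idx[w] = test_idx
        per_model[w] = reps
    return LeaveOneWellOutResult(well_probs, well_idx, per_model, classes, n_models)


def aggregate_drug_id(
    result: LeaveOneWellOutResult, dataset: FeatureDataset
) -> dict[tuple[str, float], tuple[str, np.ndarray]]:
    """Mean class distribution per (compound, concentration) -> argmax call.

    Averages held-out window distributions (already averaged over the
    replicate models) across wells of the same compound/concentration.
    Ties break deterministically toward the first class in sorted order.
    """
    buckets: dict[tuple[str, float], list[np.ndarray]] = {}
    for w, probs in result.well_probs.items():
        idx = result.well_window_idx[w]
        for key in sorted({(c, x) for c, x in zip(dataset.compounds[idx], dataset.concentrations[idx])}):
            sel = (dataset.compounds[idx] == key[0]) & (dataset.concentrations[idx] == key[1])
            buckets.setdefault(key, []).append(probs[sel])
    out = {}
    for key, parts in buckets.items():
        dist = np.concatenate(parts).mean(axis=0)
        out[key] = (result.classes[int(np.argmax(dist))], dist)
    return out


# ---------------------------------------------------------------------------
# SVM baselines
# ---------------------------------------------------------------------------


def train_linear_svm(
    dataset: FeatureDataset,
    test_wells: Sequence[str],
    positive_label: str,
    seed: int = 0,
) -> tuple[SVC, np.ndarray, np.ndarray]:
    """Linear SVM on the same 4096-d features, holdout by well.

    Returns (model, decision values on test windows, test indices);
    decision values serve as ROC scores (positive side = positive class).
    """
    split = make_split(dataset, test_wells, train_fraction=0.75, seed=seed)
    _assert_no_leakage(dataset, split)
    fit_idx = np.sort(np.r_[split.train_idx, split.val_idx])  # SVM has no early stopping
    y = (dataset.labels[fit_idx] == positive_label).astype(int)
    if len(set(y)) < 2:
        raise ValueError("single-class training data")
    model = SVC(kernel="linear", random_state=seed)
    model.fit(dataset.X[fit_idx], y)
    test_idx = np.flatnonzero(np.isin(dataset.wells, list(test_wells)))
    return model, model.decision_function(dataset.X[test_idx]), test_idx


def compute_timeseries_features(rec: WellRecording) -> np.ndarray:
    """34 spike time-series parameters of one epoch.

    Mean firing frequency (spikes/s) and mean inter-spike interval (s)
    for the pooled well, then the same pair for each of the 16
    electrodes.  Undefined ISIs (fewer than 2 spikes) are coded as the
    epoch duration (an upper bound).
    """
    def pair(times: np.ndarray) -> tuple[float, float]:
        rate = times.size / rec.duration_s
        isi = float(np.mean(np.diff(times))) if times.size >= 2 else rec.duration_s
        return rate, isi

    out = list(pair(rec.pooled_times()))
    for train in rec.spike_trains:
        out.extend(pair(train.times))
    vec = np.array(out)
    assert vec.size == TIMESERIES_DIM
    return vec


def burst_parameter_features(rec: WellRecording, cfg: BurstConfig | None = None) -> np.ndarray:
    """The five burst parameters as a feature vector (NaNs -> 0/duration)."""
    cfg = cfg or BurstConfig()
    bursts = detect_network_bursts(rec, cfg)
    params = compute_burst_parameters(rec, bursts, cfg).as_array()
    fill = np.array([0.0, 0.0, rec.duration_s, 0.0, 0.0])
    return np.where(np.isfinite(params), params, fill)


def one_class_risk_baseline(
    train_X: np.ndarray,
    test_X: np.ndarray,
    nu: float = 0.1,
    gamma: str | float = "scale",
) -> tuple[np.ndarray, np.ndarray]:
    """One-class SVM (RBF) trained only on negative/vehicle feature vectors.

    Returns (decision scores, risk flags): a negative decision score
    marks an outlier, i.e. a seizure-risk call.
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.size == 0:
        raise ValueError("empty one-class training set")
    model = OneClassSVM(nu=nu, gamma=gamma)
    model.fit(train_X)
    scores = model.decision_function(np.asarray(test_X, dtype=float))
    return scores, scores < 0


def multiclass_svm_drug_id(
    X: np.ndarray,
    labels: Sequence[str],
    wells: Sequence[str],
    compounds: Sequence[str],
    concentrations: Sequence[float],
    seed: int = 0,
) -> tuple[dict[tuple[str, float], tuple[str, np.ndarray]], int]:
    """Multi-class linear SVM drug identification, leave-one-well-out.

    One model per held-out well (W x 1 models, no replicates).  Per
    (compound, concentration) the mean one-hot vote distribution over
    held-out windows is reported; argmax ties break toward the first
    class in sorted order.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    wells = np.asarray(wells, dtype=object)
    compounds = np.asarray(compounds, dtype=object)
    concentrations = np.asarray(concentrations)
    classes = tuple(sorted(set(labels)))
    buckets: dict[tuple[str, float], list[np.ndarray]] = {}
    n_models = 0
    for w in sorted(set(wells)):
        tr = wells != w
        te = ~tr
        model = SVC(kernel="linear", random_state=seed)
        model.fit(X[tr], labels[tr].astype(str))
        pred = model.predict(X[te])
        n_models += 1
        onehot = np.zeros((pred.size, len(classes)))
        for i, p in enumerate(pred):
            onehot[i, classes.index(p)] = 1.0
        for key in sorted({(c, x) for c, x in zip(compounds[te], concentrations[te])}):
            sel = (compounds[te] == key[0]) & (concentrations[te] == key[1])
            buckets.setdefault(key, []).append(onehot[sel])
    out = {}
    for key, parts in buckets.items():
        dist = np.concatenate(parts).mean(axis=0)
        out[key] = (classes[int(np.argmax(dist))], dist)
    return out, n_models
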