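"""CNN / LSTM classification of preprocessed motor-imagery epochs.

The discriminative signal for left-vs-right imagery is spectral-spatial
(which electrode loses mu/beta power), so the reference model is a shallow
CNN whose square-and-pool stage computes exactly that feature; the LSTM is
the "temporal features" baseline it is compared against on identical
stratified 5-fold splits.

All training is seeded and single-threaded numpy, so results are
bit-reproducible; per-channel z-scoring statistics come from the training
partition only (no information leakage into validation or test folds).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ..core import LABELS, EpochSet, config_hash
from ._nn import FitHistory, LSTMClassifier, ShallowCNN, fit

__all__ = [
    "CNNParams", "LSTMParams", "TrainParams", "ClassifierConfig",
    "TrainedModel", "CVReport", "train", "evaluate", "cross_validate",
    "compare_archs", "compare_training_regimes", "save_model", "load_model",
]


@dataclass
class CNNParams:
    temporal_kernel: int = 11
    n_temporal_filters: int = 8
    n_spatial_filters: int = 16
    pool_factor: int = 4


@dataclass
class LSTMParams:
    hidden_units: int = 64
    n_layers: int = 1
    #: average-pool factor applied along time before the recurrence
    time_pool: int = 5


@dataclass
class TrainParams:
    """Optimization settings shared by both architectures.

    The defaults reflect how the shallow CNN actually learns this task: a
    long loss plateau while the spatial filters align with the modulated
    source, then a sharp transition.  Early stopping is therefore suspended
    for ``min_epochs`` so a plateau (or a lucky early validation loss)
    cannot freeze the model prematurely.
    """

    batch_size: int = 8
    max_epochs: int = 60
    early_stop_patience: int = 10
    #: early stopping is suspended for this many initial epochs
    min_epochs: int = 40
    learning_rate: float = 3e-3
    #: L2 penalty on weight matrices (not biases)
    l2: float = 0.1
    validation_fraction: float = 0.2
    #: seeded re-initializations to escape rare stuck plateaus
    n_restarts: int = 3
    #: validation accuracy at which an attempt counts as converged
    restart_val_accuracy: float = 0.8


@dataclass
class ClassifierConfig:
    arch: str = "cnn"
    cnn: CNNParams = field(default_factory=CNNParams)
    lstm: LSTMParams = field(default_factory=LSTMParams)
    train: TrainParams = field(default_factory=TrainParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("cnn", "lstm"):
            raise ValueError("arch must be 'cnn' or 'lstm'")
        if isinstance(self.cnn, dict):
            self.cnn = CNNParams(**self.cnn)
        if isinstance(self.lstm, dict):
            self.lstm = LSTMParams(**self.lstm)
        if isinstance(self.train, dict):
            self.train = TrainParams(**self.train)
        for name, val in vars(self.cnn).items():
            if val < 1:
                raise ValueError(f"cnn.{name} must be >= 1")
        for name, val in vars(self.lstm).items():
            if val < 1:
                raise ValueError(f"lstm.{name} must be >= 1")
        if not 0.0 < self.train.validation_fraction < 0.5:
            raise ValueError("validation_fraction must lie in (0, 0.5)")


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to apply it to new epochs."""

    arch: str
    net: object  # ShallowCNN | LSTMClassifier
    norm_mean: np.ndarray  # (n_channels,)
    norm_std: np.ndarray
    whiten: np.ndarray  # (n_channels, n_channels) ZCA sphering matrix
    channel_names: list[str]
    n_samples: int
    fs: float
    config: ClassifierConfig
    history: FitHistory | None = None

    def _features(self, es: EpochSet) -> np.ndarray:
        if list(es.channel_names) != list(self.channel_names):
            raise ValueError("channel montage mismatch between model and data")
        if es.n_samples != self.n_samples:
            raise ValueError(
                f"trial length {es.n_samples} != model's {self.n_samples}"
            )
        x = (es.data - self.norm_mean[None, :, None]) / self.norm_std[None, :, None]
        x = np.einsum("dc,bct->bdt", self.whiten, x)
        return _arch_input(x, self.arch, self.config)

    def predict_proba(self, es: EpochSet) -> np.ndarray:
        from ._nn import softmax

        return softmax(self.net.forward(self._features(es)))

    def predict(self, es: EpochSet) -> np.ndarray:
        idx = self.predict_proba(es).argmax(axis=1)
        return np.array([LABELS[i] for i in idx], dtype=object)


@dataclass
class CVReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    std_accuracy: float
    confusions: list[np.ndarray]
    config_hash: str
    seed: int
    k: int

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "confusions": [c.tolist() for c in self.confusions],
            "config_hash": self.config_hash,
            "seed": self.seed,
            "k": self.k,
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _encode_labels(labels: np.ndarray) -> np.ndarray:
    return np.array([LABELS.index(l) for l in labels], dtype=np.int64)


def _arch_input(x: np.ndarray, arch: str, config: ClassifierConfig) -> np.ndarray:
    """(trials, channels, samples) -> network input for the given arch."""
    if arch == "cnn":
        return x
    p = config.lstm.time_pool
    t_used = (x.shape[2] // p) * p
    pooled = x[:, :, :t_used].reshape(x.shape[0], x.shape[1], t_used // p, p).mean(axis=3)
    return pooled.transpose(0, 2, 1)  # (B, T', channels)


def _build_net(arch: str, n_channels: int, n_samples: int,
               config: ClassifierConfig, rng: np.random.Generator):
    if arch == "cnn":
        c = config.cnn
        return ShallowCNN(
            n_channels, n_samples,
            temporal_kernel=c.temporal_kernel,
            n_temporal_filters=c.n_temporal_filters,
            n_spatial_filters=c.n_spatial_filters,
            pool_factor=c.pool_factor,
            rng=rng,
        )
    l = config.lstm
    return LSTMClassifier(
        n_channels, hidden_units=l.hidden_units, n_layers=l.n_layers, rng=rng
    )


def _zca_whitener(x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """ZCA sphering matrix from ``(trials, channels, samples)`` training data.

    Whitening the montage makes the background spatially isotropic, so the
    class-modulated source direction is not drowned by channel correlations
    — without it the spatial filters of the CNN are barely learnable from a
    few hundred trials.  Statistics come from the training partition only.
    """
    flat = x.transpose(1, 0, 2).reshape(x.shape[1], -1)
    cov = flat @ flat.T / flat.shape[1]
    w, v = np.linalg.eigh(cov)
    return (v * (1.0 / np.sqrt(w + eps))) @ v.T


def _stratified_holdout(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class random split; returns (train_idx, val_idx)."""
    val_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(fraction * len(idx))))
        val_idx.extend(idx[:n_val])
    val_idx = np.sort(np.array(val_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
    return train_idx, val_idx


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def train(es_train: EpochSet, config: ClassifierConfig | None = None) -> TrainedModel:
    """Fit the configured architecture on an EpochSet.

    A stratified ``validation_fraction`` of the trials is held out for early
    stopping; per-channel z-scoring statistics are computed on the remaining
    training trials only and stored with the model.

    The CNN's spatial-filter search occasionally draws an initialization
    that never escapes its loss plateau within the epoch budget, so
    training performs up to ``n_restarts`` seeded re-initializations
    (data split and normalization stay fixed), stops as soon as an attempt
    reaches ``restart_val_accuracy`` on the validation split, and keeps the
    attempt with the best validation outcome.  The whole procedure is a
    deterministic function of ``config.seed``.
    """
    config = config or ClassifierConfig()
    if es_train.n_trials < 20:
        raise ValueError(f"need >= 20 trials to train, got {es_train.n_trials}")
    y = _encode_labels(es_train.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(config.seed)
    tr_idx, va_idx = _stratified_holdout(y, config.train.validation_fraction, rng)

    mean = es_train.data[tr_idx].mean(axis=(0, 2))
    std = es_train.data[tr_idx].std(axis=(0, 2))
    std = np.where(std > 0, std, 1.0)
    xn = (es_train.data - mean[None, :, None]) / std[None, :, None]
    whiten = _zca_whitener(xn[tr_idx])
    xn = np.einsum("dc,bct->bdt", whiten, xn)
    X = _arch_input(xn, config.arch, config)

    best = None  # (val_acc, -val_loss, net, history)
    for attempt in range(max(1, config.train.n_restarts)):
        a_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(attempt,)))
        net = _build_net(config.arch, es_train.n_channels, es_train.n_samples,
                         config, a_rng)
        history = fit(
            net, X[tr_idx], y[tr_idx], X[va_idx], y[va_idx],
            batch_size=config.train.batch_size,
            max_epochs=config.train.max_epochs,
            patience=config.train.early_stop_patience,
            min_epochs=config.train.min_epochs,
            learning_rate=config.train.learning_rate,
            weight_decay=config.train.l2,
            rng=a_rng,
        )
        val_acc = history.val_accuracy[history.best_epoch]
        key = (val_acc, -history.val_loss[history.best_epoch])
        if best is None or key > best[0]:
            best = (key, net, history)
        if val_acc >= config.train.restart_val_accuracy:
            break
    _, net, history = best

    return TrainedModel(
        arch=config.arch, net=net, norm_mean=mean, norm_std=std, whiten=whiten,
        channel_names=list(es_train.channel_names),
        n_samples=es_train.n_samples, fs=es_train.fs,
        config=config, history=history,
    )


def evaluate(model: TrainedModel, es_test: EpochSet) -> tuple[float, np.ndarray]:
    """Accuracy and confusion matrix (rows = true class, order left/right)."""
    pred = model.predict(es_test)
    y_true = _encode_labels(es_test.labels)
    y_pred = _encode_labels(pred)
    acc = float(np.mean(y_true == y_pred))
    conf = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    return acc, conf


def make_folds(es: EpochSet, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold assignment, reusable across architectures."""
    y = _encode_labels(es.labels)
    counts = np.bincount(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _subset(es: EpochSet, idx: np.ndarray) -> EpochSet:
    return EpochSet(
        data=es.data[idx], labels=es.labels[idx], fs=es.fs,
        channel_names=list(es.channel_names), cue_index=es.cue_index,
        provenance=dict(es.provenance),
    )


def cross_validate(
    es: EpochSet, k: int = 5, config: ClassifierConfig | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation with seeded fold assignment.

    Each fold trains with seed ``config.seed + fold_index`` so that a
    single unlucky initialization cannot affect every fold at once.
    """
    config = config or ClassifierConfig()
    folds = folds if folds is not None else make_folds(es, k, config.seed)
    if len(folds) != k:
        raise ValueError(f"got {len(folds)} folds for k={k}")
    accs, confs = [], []
    for i, (tr, te) in enumerate(folds):
        fold_cfg = dataclasses.replace(config, seed=config.seed + i)
        model = train(_subset(es, tr), fold_cfg)
        acc, conf = evaluate(model, _subset(es, te))
        accs.append(acc)
        confs.append(conf)
    return CVReport(
        fold_accuracies=[float(a) for a in accs],
        mean_accuracy=float(np.mean(accs)),
        std_accuracy=float(np.std(accs)),
        confusions=confs,
        config_hash=config_hash(config),
        seed=config.seed,
        k=k,
    )


def compare_archs(
    es: EpochSet, configs: list[ClassifierConfig], k: int = 5
) -> dict:
    """Cross-validate several configurations on *identical* folds.

    Returns per-arch reports plus paired per-fold accuracy differences
    (first config minus each other config), the statistic used to compare
    the CNN against the LSTM baseline.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations to compare")
    folds = make_folds(es, k, configs[0].seed)
    reports = {}
    for cfg in configs:
        name = cfg.arch
        if name in reports:
            name = f"{name}_{config_hash(cfg)}"
        reports[name] = cross_validate(es, k, cfg, folds=folds)
    names = list(reports)
    ref = np.array(reports[names[0]].fold_accuracies)
    paired = {
        f"{names[0]}-{other}": (ref - np.array(reports[other].fold_accuracies)).tolist()
        for other in names[1:]
    }
    order = sorted(reports, key=lambda n: -reports[n].mean_accuracy)
    return {"reports": reports, "paired_fold_differences": paired, "ranking": order}


def concat_epochs(sessions: list[EpochSet]) -> EpochSet:
    """Pool several sessions (same montage/fs/geometry) into one EpochSet."""
    first = sessions[0]
    for s in sessions[1:]:
        if (list(s.channel_names) != list(first.channel_names)
                or s.fs != first.fs or s.n_samples != first.n_samples
                or s.cue_index != first.cue_index):
            raise ValueError("sessions differ in montage, rate or trial geometry")
    return EpochSet(
        data=np.concatenate([s.data for s in sessions]),
        labels=np.concatenate([s.labels for s in sessions]),
        fs=first.fs, channel_names=list(first.channel_names),
        cue_index=first.cue_index,
        provenance={"pooled_from": [s.provenance.get("config_hash") for s in sessions]},
    )


def compare_training_regimes(
    sessions: list[EpochSet], config: ClassifierConfig | None = None, k: int = 5
) -> dict:
    """Per-subject vs pooled training comparison.

    Cross-validates the classifier separately within each session and once
    on the pooled trials of all sessions; reports both regimes without
    asserting a direction.
    """
    config = config or ClassifierConfig()
    per_subject = [cross_validate(s, k, config) for s in sessions]
    pooled = cross_validate(concat_epochs(sessions), k, config)
    return {
        "per_subject": per_subject,
        "per_subject_mean": float(np.mean([r.mean_accuracy for r in per_subject])),
        "pooled": pooled,
    }


# ---------------------------------------------------------------------------
# model persistence: config JSON + flat little-endian float64 weight blobs
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "arch": model.arch,
        "channel_names": model.channel_names,
        "n_samples": model.n_samples,
        "fs": model.fs,
        "config": json.loads(json.dumps(_cfg_dict(model.config))),
        "norm_mean": model.norm_mean.tolist(),
        "norm_std": model.norm_std.tolist(),
        "params": {k: list(v.shape) for k, v in model.net.params.items()},
    }
    for name, arr in model.net.params.items():
        (directory / f"weights_{name}.bin").write_bytes(
            np.ascontiguousarray(arr, dtype="<f8").tobytes()
        )
    (directory / "whiten.bin").write_bytes(
        np.ascontiguousarray(model.whiten, dtype="<f8").tobytes()
    )
    (directory / "model.json").write_text(json.dumps(manifest, indent=1))
    return directory


def _cfg_dict(cfg: ClassifierConfig) -> dict:
    return {
        "arch": cfg.arch, "cnn": vars(cfg.cnn), "lstm": vars(cfg.lstm),
        "train": vars(cfg.train), "seed": cfg.seed,
    }


def load_model(directory) -> TrainedModel:
    directory = Path(directory)
    manifest = json.loads((directory / "model.json").read_text())
    cfg = ClassifierConfig(**manifest["config"])
    rng = np.random.default_rng(cfg.seed)
    net = _build_net(
        manifest["arch"], len(manifest["channel_names"]), manifest["n_samples"],
        cfg, rng,
    )
    for name, shape in manifest["params"].items():
        blob = (directory / f"weights_{name}.bin").read_bytes()
        net.params[name] = (
            np.frombuffer(blob, dtype="<f8").reshape(shape).astype(net.dtype)
        )
    n_ch = len(manifest["channel_names"])
    whiten = np.frombuffer((directory / "whiten.bin").read_bytes(),
                           dtype="<f8").reshape(n_ch, n_ch).copy()
    return TrainedModel(
        arch=manifest["arch"], net=net,
        norm_mean=np.array(manifest["norm_mean"]),
        norm_std=np.array(manifest["norm_std"]),
        whiten=whiten,
        channel_names=list(manifest["channel_names"]),
        n_samples=int(manifest["n_samples"]), fs=float(manifest["fs"]),
        config=cfg, history=None,
    )
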