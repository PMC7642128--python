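"""End-to-end orchestration: simulate -> preprocess -> PSD/ERD -> classify.

One master seed deterministically fans out to per-stage seeds (documented
splitting rule: stage seed = ``SeedSequence(master, spawn_key=(stage_index,))``
reduced mod 2**31, with stage indices 0=generate, 1=classify).  Rerunning
with an identical config therefore reproduces the run report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as clf
from . import eeg_io, erd_ers, spectral, synthgen, wavelet_bands
from .core import LABELS, config_hash

logger = logging.getLogger(__name__)

_STAGE_INDEX = {"generate": 0, "classify": 1}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Everything one reproducible run needs; mirrors the YAML layout."""

    generator: synthgen.GeneratorConfig = field(
        default_factory=synthgen.GeneratorConfig
    )
    wavelet: wavelet_bands.WaveletSpec = field(
        default_factory=wavelet_bands.WaveletSpec
    )
    ref_window: tuple[float, float] = erd_ers.DEFAULT_REF_WINDOW
    event_window: tuple[float, float] = erd_ers.DEFAULT_EVENT_WINDOW
    erd_channels: tuple[str, ...] = ("C3", "C4")
    classifier: clf.ClassifierConfig = field(default_factory=clf.ClassifierConfig)
    archs: tuple[str, ...] = ("cnn",)
    k_folds: int = 5
    output_dir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = synthgen.GeneratorConfig(**self.generator)
        if isinstance(self.wavelet, dict):
            self.wavelet = wavelet_bands.WaveletSpec(**self.wavelet)
        if isinstance(self.classifier, dict):
            self.classifier = clf.ClassifierConfig(**self.classifier)
        self.ref_window = tuple(self.ref_window)
        self.event_window = tuple(self.event_window)
        self.archs = tuple(self.archs)
        if not set(self.archs) <= {"cnn", "lstm"}:
            raise ValueError("archs must be drawn from {'cnn', 'lstm'}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _stage(name: str):
    """Decorator adding stage context and timing logs to pipeline steps."""

    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return out
        return inner

    return wrap


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report.

    Every intermediate is persisted under ``config.output_dir``; the report
    (``report.json``) contains only seed-determined quantities, so two runs
    with the same config are bit-identical.  The report is written
    atomically — a failing stage leaves no partial report behind.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise PermissionError(f"output directory {out} is not writable")

    gen_cfg = dataclasses.replace(
        config.generator, seed=stage_seed(config.seed, "generate")
    )
    clf_cfg = dataclasses.replace(
        config.classifier, seed=stage_seed(config.seed, "classify")
    )

    session = _stage("simulate")(synthgen.generate_session)(gen_cfg)
    eeg_io.write_epochs(session, out / "raw_epochs")

    pre = _stage("preprocess")(wavelet_bands.preprocess_epochs)(
        session, config.wavelet, resample=True
    )
    eeg_io.write_epochs(pre, out / "preprocessed_epochs")

    psd_rows = _stage("psd")(_psd_tables)(pre, config.erd_channels)
    _write_csv(out / "psd.csv", psd_rows,
               ["label", "channel", "freq_hz", "psd_uv2_per_hz"])

    erd_tables = _stage("erd")(_erd_tables)(session, config)
    erd_rows = [
        {"label": lab, **row}
        for lab, res in erd_tables.items()
        for row in res.table.to_dict("records")
    ]
    _write_csv(out / "erd.csv", erd_rows,
               ["label", "channel", "band", "f_lo", "f_hi", "E", "R",
                "erd_ers_percent"])

    cv_block = _stage("classify")(_classify)(pre, config, clf_cfg)

    report = {
        "config": _plain_config(config),
        "config_hash": config_hash(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_INDEX},
        "generator_summary": {
            "preset": gen_cfg.preset,
            "n_trials": session.n_trials,
            "class_counts": session.class_counts(),
            "n_channels": session.n_channels,
            "fs": session.fs,
            "n_samples": session.n_samples,
            "provenance": session.provenance,
        },
        "erd_table": erd_rows,
        "cross_validation": cv_block,
        "artifacts": {
            "raw_epochs": "raw_epochs",
            "preprocessed_epochs": "preprocessed_epochs",
            "psd_csv": "psd.csv",
            "erd_csv": "erd.csv",
        },
    }
    blob = json.dumps(report, indent=1, sort_keys=True)
    tmp = out / "report.json.tmp"
    tmp.write_text(blob)
    tmp.replace(out / "report.json")
    return report


def _psd_tables(pre, channels):
    rows = []
    for lab in LABELS:
        sub = pre.select_label(lab)
        for ch in channels:
            res = spectral.epoch_psd(sub.data[:, sub.channel_index(ch), :], sub.fs)
            rows.extend(
                {"label": lab, "channel": ch, "freq_hz": float(f),
                 "psd_uv2_per_hz": float(p)}
                for f, p in zip(res.freqs, res.psd)
            )
    return rows


def _erd_tables(session, config: RunConfig):
    return {
        lab: erd_ers.erd_ers_map(
            session, lab, channels=config.erd_channels,
            ref_window=config.ref_window, event_window=config.event_window,
        )
        for lab in LABELS
    }


def _classify(pre, config: RunConfig, clf_cfg: clf.ClassifierConfig):
    if len(config.archs) == 1:
        cfg = dataclasses.replace(clf_cfg, arch=config.archs[0])
        report = clf.cross_validate(pre, config.k_folds, cfg)
        return {config.archs[0]: report.to_dict()}
    cfgs = [dataclasses.replace(clf_cfg, arch=a) for a in config.archs]
    comp = clf.compare_archs(pre, cfgs, k=config.k_folds)
    return {
        **{name: rep.to_dict() for name, rep in comp["reports"].items()},
        "paired_fold_differences": comp["paired_fold_differences"],
        "ranking": comp["ranking"],
    }


def _plain_config(config: RunConfig) -> dict:
    def plain(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: plain(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, (tuple, list)):
            return [plain(v) for v in o]
        if isinstance(o, float) and np.isinf(o):
            return "inf"
        return o

    return plain(config)


def _write_csv(path: Path, rows: list[dict], columns: list[str]) -> None:
    import pandas as pd

    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
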