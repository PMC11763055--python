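"""Experiment protocols: cross-configuration transfer and train/test ratios.

Two protocols probe generalization:

* **cross-configuration validation** -- train on a single object/background
  configuration, then evaluate on a held-out quarter of it and on the full
  datasets of the remaining configurations.  High-contrast training (e.g.
  DL) transfers to configurations sharing its contrast structure (LL, RL)
  but degrades on dissimilar ones (DR);
* **train/test ratio robustness** -- train on stratified fractions of a
  pooled multi-configuration dataset (75:25 down to 5:95) and measure how
  test accuracy degrades as labelled data shrink.

Both repeat over seeds and report mean +/- standard deviation.  Desk-scale
defaults (object sizes {8, 16, 32}, 100 pairs per direction, 3 seeds) keep
a full protocol within minutes on one CPU; ``paper_scale=True`` restores
the full benchmark conditions (sizes 1..128, 500 pairs per direction,
5 seeds).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CONFIGURATIONS, DatasetSpec, generate_dataset
from .ganglion import count_learnable
from .learning import (EncodedDataset, TrainConfig, encode_dataset,
                       evaluate_accuracy, train_model)
from .lgn import LGNParams

__all__ = [
    "REDUCED_OBJECT_SIZES",
    "REDUCED_PAIRS_PER_DIRECTION",
    "ExperimentReport",
    "stratified_split",
    "parse_ratio",
    "build_config_dataset",
    "run_cross_config_experiment",
    "run_ratio_experiment",
    "summarize_report",
    "read_report",
]

REDUCED_OBJECT_SIZES: tuple[int, ...] = (8, 16, 32)
REDUCED_PAIRS_PER_DIRECTION = 100
REDUCED_SEEDS: tuple[int, ...] = (0, 1, 2)
FULL_OBJECT_SIZES: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128)
FULL_PAIRS_PER_DIRECTION = 500
FULL_SEEDS: tuple[int, ...] = (0, 1, 2, 3, 4)


@dataclasses.dataclass
class ExperimentReport:
    """Tabular result of one protocol plus a structural summary."""

    kind: str
    table: pd.DataFrame
    n_parameters: int
    seeds: tuple[int, ...]


def parse_ratio(ratio: str) -> float:
    """Parse a 'train:test' ratio string into the training fraction."""
    try:
        train, test = (float(part) for part in ratio.split(":"))
    except ValueError as exc:
        raise ValueError(f"malformed ratio {ratio!r}; expected 'train:test'") from exc
    if train <= 0 or test <= 0:
        raise ValueError(f"ratio parts must be positive in {ratio!r}")
    return train / (train + test)


def stratified_split(meta: pd.DataFrame, train_frac: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices, stratified by (config, object_size, direction).

    Each stratum contributes ``round(train_frac * n)`` training samples, so
    direction (and size) balance is preserved to within one pair.  Raises
    if any stratum would leave either side empty.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    keys = [k for k in ("config", "object_size", "direction") if k in meta.columns]
    for key, group in meta.groupby(keys, sort=True):
        idx = group.index.to_numpy()
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(
                f"split {train_frac:.2f} leaves an empty class for stratum {key}")
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def build_config_dataset(config: str, *, object_sizes: Sequence[int],
                         pairs_per_direction: int, data_seed: int,
                         eps_vertical: float = 0,
                         eps_horizontal: float = 1) -> EncodedDataset:
    """Generate and encode one configuration's dataset, deterministically."""
    spec = DatasetSpec(configurations=(config,),
                       object_sizes=tuple(object_sizes),
                       pairs_per_direction=pairs_per_direction,
                       seed=data_seed)
    pairs, _ = generate_dataset(spec)
    return encode_dataset(pairs, eps_vertical, eps_horizontal)


def _scale(paper_scale: bool, object_sizes, pairs_per_direction, seeds):
    if paper_scale:
        return (tuple(object_sizes or FULL_OBJECT_SIZES),
                pairs_per_direction or FULL_PAIRS_PER_DIRECTION,
                tuple(seeds or FULL_SEEDS))
    return (tuple(object_sizes or REDUCED_OBJECT_SIZES),
            pairs_per_direction or REDUCED_PAIRS_PER_DIRECTION,
            tuple(seeds or REDUCED_SEEDS))


def run_cross_config_experiment(train_config: str,
                                train_cfg: TrainConfig | None = None,
                                *,
                                test_configs: Sequence[str] | None = None,
                                object_sizes: Sequence[int] | None = None,
                                pairs_per_direction: int | None = None,
                                seeds: Sequence[int] | None = None,
                                data_seed: int = 20250,
                                holdout_frac: float = 0.25,
                                paper_scale: bool = False) -> ExperimentReport:
    """Train on one configuration, evaluate on it and the others.

    The training configuration is split (1 - holdout_frac):holdout_frac,
    stratified; its held-out portion provides the self-test column and the
    other configurations are evaluated in full.  Repeated over ``seeds``;
    the report holds mean and standard deviation per test configuration
    plus the accuracy on the training portion itself.
    """
    if train_config not in CONFIGURATIONS:
        raise ValueError(f"unknown configuration label {train_config!r}")
    if train_cfg is None:
        train_cfg = TrainConfig()
    if test_configs is None:
        test_configs = CONFIGURATIONS
    for cfg in test_configs:
        if cfg not in CONFIGURATIONS:
            raise ValueError(f"unknown configuration label {cfg!r}")
    object_sizes, pairs_per_direction, seeds = _scale(
        paper_scale, object_sizes, pairs_per_direction, seeds)

    needed = dict.fromkeys([train_config, *test_configs])
    datasets = {
        cfg: build_config_dataset(
            cfg, object_sizes=object_sizes,
            pairs_per_direction=pairs_per_direction,
            data_seed=data_seed + CONFIGURATIONS.index(cfg),
            eps_vertical=train_cfg.eps_vertical,
            eps_horizontal=train_cfg.eps_horizontal)
        for cfg in needed
    }
    ds_train_full = datasets[train_config]
    lparams = LGNParams()

    accs: dict[str, list[float]] = {cfg: [] for cfg in test_configs}
    train_accs: list[float] = []
    n_params = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        tr_idx, hold_idx = stratified_split(ds_train_full.meta,
                                            1.0 - holdout_frac, rng)
        run_cfg = dataclasses.replace(train_cfg, seed=seed)
        params, _ = train_model(ds_train_full.subset(tr_idx), run_cfg)
        n_params = count_learnable(params)
        train_accs.append(evaluate_accuracy(params, lparams,
                                            ds_train_full.subset(tr_idx)))
        for cfg in test_configs:
            if cfg == train_config:
                test_ds = ds_train_full.subset(hold_idx)
            else:
                test_ds = datasets[cfg]
            accs[cfg].append(evaluate_accuracy(params, lparams, test_ds))

    seeds_repr = "|".join(str(s) for s in seeds)
    rows = [{
        "train_config": train_config, "test_config": "train",
        "accuracy_mean": round(float(np.mean(train_accs)), 4),
        "accuracy_std": round(float(np.std(train_accs)), 4),
        "n_runs": len(seeds), "seeds": seeds_repr,
    }]
    for cfg in test_configs:
        rows.append({
            "train_config": train_config, "test_config": cfg,
            "accuracy_mean": round(float(np.mean(accs[cfg])), 4),
            "accuracy_std": round(float(np.std(accs[cfg])), 4),
            "n_runs": len(seeds), "seeds": seeds_repr,
        })
    return ExperimentReport(kind="cross_config",
                            table=pd.DataFrame.from_records(rows),
                            n_parameters=n_params, seeds=tuple(seeds))


def run_ratio_experiment(ratios: Sequence[str] = ("75:25", "50:50", "10:90", "5:95"),
                         train_cfg: TrainConfig | None = None,
                         *,
                         configurations: Sequence[str] = CONFIGURATIONS,
                         object_sizes: Sequence[int] | None = None,
                         pairs_per_direction: int | None = None,
                         seeds: Sequence[int] | None = None,
                         data_seed: int = 20250,
                         paper_scale: bool = False) -> ExperimentReport:
    """Train/test-ratio robustness on a pooled multi-configuration dataset.

    For each ratio the pooled dataset is split stratified by configuration,
    object size and direction; one model is trained per seed and evaluated
    on both portions.
    """
    if train_cfg is None:
        train_cfg = TrainConfig()
    fractions = [parse_ratio(r) for r in ratios]
    object_sizes, pairs_per_direction, seeds = _scale(
        paper_scale, object_sizes, pairs_per_direction, seeds)

    per_config = [
        build_config_dataset(cfg, object_sizes=object_sizes,
                             pairs_per_direction=pairs_per_direction,
                             data_seed=data_seed + CONFIGURATIONS.index(cfg),
                             eps_vertical=train_cfg.eps_vertical,
                             eps_horizontal=train_cfg.eps_horizontal)
        for cfg in configurations
    ]
    pooled = _concat_encoded(per_config)
    lparams = LGNParams()

    rows = []
    n_params = 0
    seeds_repr = "|".join(str(s) for s in seeds)
    for ratio, frac in zip(ratios, fractions):
        tr_accs, te_accs = [], []
        n_train = n_test = 0
        for seed in seeds:
            rng = np.random.default_rng(seed)
            tr_idx, te_idx = stratified_split(pooled.meta, frac, rng)
            n_train, n_test = len(tr_idx), len(te_idx)
            run_cfg = dataclasses.replace(train_cfg, seed=seed)
            params, _ = train_model(pooled.subset(tr_idx), run_cfg)
            n_params = count_learnable(params)
            tr_accs.append(evaluate_accuracy(params, lparams,
                                             pooled.subset(tr_idx)))
            te_accs.append(evaluate_accuracy(params, lparams,
                                             pooled.subset(te_idx)))
        rows.append({
            "split": ratio,
            "n_train": n_train, "n_test": n_test,
            "train_acc_mean": round(float(np.mean(tr_accs)), 4),
            "train_acc_std": round(float(np.std(tr_accs)), 4),
            "test_acc_mean": round(float(np.mean(te_accs)), 4),
            "test_acc_std": round(float(np.std(te_accs)), 4),
            "n_runs": len(seeds), "seeds": seeds_repr,
        })
    return ExperimentReport(kind="ratio",
                            table=pd.DataFrame.from_records(rows),
                            n_parameters=n_params, seeds=tuple(seeds))


def _concat_encoded(datasets: Sequence[EncodedDataset]) -> EncodedDataset:
    if not datasets:
        raise ValueError("no datasets to pool")
    n_interior = datasets[0].n_interior
    for ds in datasets:
        if ds.n_interior != n_interior:
            raise ValueError("pooled datasets must share a frame size")
    offsets = [np.asarray([0], dtype=np.int64)]
    total = 0
    for ds in datasets:
        offsets.append(ds.offsets[1:] + total)
        total += ds.offsets[-1]
    return EncodedDataset(
        patterns=np.concatenate([ds.patterns for ds in datasets]),
        counts=np.concatenate([ds.counts for ds in datasets]),
        offsets=np.concatenate(offsets),
        labels=np.concatenate([ds.labels for ds in datasets]),
        n_interior=n_interior,
        meta=pd.concat([ds.meta for ds in datasets], ignore_index=True))


def summarize_report(report: ExperimentReport, path: str | Path) -> Path:
    """Write the report table as CSV (fractions, 4 decimals); round-trips."""
    if report.table.empty:
        raise ValueError("cannot summarize an empty report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(path, index=False, float_format="%.4f")
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "seeds" in df.columns:
        df["seeds"] = df["seeds"].astype(str)
    return df
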