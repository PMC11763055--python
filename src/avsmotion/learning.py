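"""Loss, analytic gradients, and the gradient-descent training loop.

Training minimizes the cross-entropy E = -sum_m T_m log(D-bar_m) between
the one-hot teacher signal T and the normalized direction sums D-bar, by
plain mini-batch gradient descent on the synaptic weights w and biases q
(all other parameters are fixed).

Two gradient modes are provided:

* ``exact`` (default): the true chain rule through synapse, branch,
  membrane, soma, LGN channel product, pixel summation and sum
  normalization;
* ``paper_literal``: a historically printed simplification of the same
  derivation, kept verbatim for comparison -- the normalization Jacobian
  collapsed to 1, the LGN derivative evaluated at (O - theta) without the
  other-channel product, and the soma derivative evaluated at (v - theta)
  instead of (u - theta).  See docs/methods.md for why these differ.

A central-finite-difference oracle (:func:`numeric_gradient_oracle`) is the
reference implementation the exact mode is verified against.

Implementation note: receptive-field inputs are binary 9-vectors per
channel, so every interior pixel of a frame pair reduces to one of a small
set of 27-bit patterns.  Datasets are stored pattern-compressed (unique
patterns with multiplicities per sample), which makes the exact forward and
backward passes a handful of small matrix products without changing any
value.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .data import FramePair
from .ganglion import GanglionParams, _sigmoid
from .lgn import LGNParams
from .retina import encode_pair

__all__ = [
    "TrainConfig",
    "EncodedDataset",
    "encode_dataset",
    "cross_entropy_loss",
    "forward_batch",
    "backward_gradients",
    "numeric_gradient_oracle",
    "sgd_step",
    "train_model",
    "evaluate_accuracy",
    "predict_dataset",
]

logger = logging.getLogger(__name__)

LOG_CLAMP_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimizer and preprocessing settings for one training run."""

    learning_rate: float = 10.0
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    eps_vertical: float = 0
    eps_horizontal: float = 1
    gradient_mode: str = "exact"
    early_stop_patience: int = 10
    min_delta: float = 1e-4
    normalization: str = "sum"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.gradient_mode not in ("exact", "paper_literal"):
            raise ValueError(f"unknown gradient_mode {self.gradient_mode!r}")


@dataclasses.dataclass
class EncodedDataset:
    """Pattern-compressed retinal encodings of a labelled dataset.

    ``patterns`` stacks each sample's unique binary input patterns,
    ``counts`` their pixel multiplicities, and ``offsets`` delimits sample
    i's rows as ``patterns[offsets[i]:offsets[i+1]]``.  Sums over a
    sample's interior pixels become count-weighted sums over its rows.
    """

    patterns: np.ndarray   # (R, 9, C) uint8
    counts: np.ndarray     # (R,) float64
    offsets: np.ndarray    # (N+1,) int64
    labels: np.ndarray     # (N,) int, direction labels 1..8
    n_interior: int        # interior pixels per frame (A-2)*(B-2)
    meta: pd.DataFrame | None = None  # per-sample config/object_size/direction

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "EncodedDataset":
        idx = np.asarray(idx)
        rows, starts = self._gather_rows(idx)
        lengths = self.offsets[idx + 1] - self.offsets[idx]
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        meta = None
        if self.meta is not None:
            meta = self.meta.iloc[idx].reset_index(drop=True)
        return EncodedDataset(patterns=self.patterns[rows],
                              counts=self.counts[rows],
                              offsets=offsets,
                              labels=self.labels[idx],
                              n_interior=self.n_interior,
                              meta=meta)

    def _gather_rows(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row indices for samples ``idx`` plus per-sample start offsets."""
        lengths = self.offsets[idx + 1] - self.offsets[idx]
        rows = np.concatenate(
            [np.arange(self.offsets[i], self.offsets[i + 1]) for i in idx])
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        return rows, starts


def encode_dataset(pairs: Sequence[FramePair], eps_vertical: float = 0,
                   eps_horizontal: float = 1) -> EncodedDataset:
    """Encode and pattern-compress every pair of a dataset."""
    if len(pairs) == 0:
        raise ValueError("cannot encode an empty dataset")
    all_patterns: list[np.ndarray] = []
    all_counts: list[np.ndarray] = []
    offsets = [0]
    labels = np.empty(len(pairs), dtype=np.int64)
    records = []
    n_interior = None
    for i, pair in enumerate(pairs):
        X = encode_pair(pair.frame_t, pair.frame_t1, eps_vertical, eps_horizontal)
        P = X.shape[0]
        if n_interior is None:
            n_interior = P
        elif n_interior != P:
            raise ValueError("all pairs must share a frame size")
        uniq, counts = np.unique(X.reshape(P, -1), axis=0, return_counts=True)
        all_patterns.append(uniq.reshape(len(uniq), 9, -1))
        all_counts.append(counts.astype(float))
        offsets.append(offsets[-1] + len(uniq))
        labels[i] = pair.direction_label
        records.append({"config": pair.config, "object_size": pair.object_size,
                        "direction": pair.direction_label})
    return EncodedDataset(patterns=np.concatenate(all_patterns),
                          counts=np.concatenate(all_counts),
                          offsets=np.asarray(offsets, dtype=np.int64),
                          labels=labels,
                          n_interior=int(n_interior),
                          meta=pd.DataFrame.from_records(records))


def cross_entropy_loss(D_norm: np.ndarray, T: np.ndarray,
                       clamp: float = LOG_CLAMP_EPS) -> float:
    """Cross entropy -sum_m T_m log(D-bar_m); batched over leading axes.

    Probabilities at the true label below ``clamp`` are clamped (with a
    warning) so that a degenerate field yields a large finite loss.
    """
    D_norm = np.asarray(D_norm, dtype=float)
    T = np.asarray(T, dtype=float)
    p_true = np.sum(T * D_norm, axis=-1)
    if np.any(p_true < clamp):
        warnings.warn("true-direction probability clamped in cross-entropy",
                      RuntimeWarning, stacklevel=2)
        p_true = np.maximum(p_true, clamp)
    return float(np.mean(-np.log(p_true)))


def _stable_log_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.where(z >= 0, -np.log1p(np.exp(-np.abs(z))),
                   z - np.log1p(np.exp(-np.abs(z))))
    return out


def forward_batch(ds: EncodedDataset, idx: np.ndarray, gparams: GanglionParams,
                  lparams: LGNParams, normalization: str = "sum") -> dict:
    """Forward pass over samples ``idx``; returns all backward intermediates.

    The cache holds per-pattern-row tensors (synapse endpoint values S0/S1,
    branch b, soma O, channel product, LGN field) plus per-sample direction
    sums D, normalized outputs, predictions and the mean loss.
    """
    idx = np.asarray(idx)
    rows, starts = ds._gather_rows(idx)
    Xr = ds.patterns[rows].astype(float)          # (R, 9, C)
    counts = ds.counts[rows]
    labels = ds.labels[idx]
    B = len(idx)

    d = gparams.d[..., None]                       # (I, J, M, 1)
    z0 = (-gparams.q) / d
    z1 = (gparams.w - gparams.q) / d
    S0, S1 = _sigmoid(z0), _sigmoid(z1)            # (I, J, M, C)
    logS0, logS1 = _stable_log_sigmoid(z0), _stable_log_sigmoid(z1)

    # log b = sum_i log S(x_i) = sum_i log S0 + sum_i x_i (log S1 - log S0)
    base = logS0.sum(axis=0)                       # (J, M, C)
    logb = base[None] + np.einsum("ric,ijmc->rjmc", Xr, logS1 - logS0,
                                  optimize=True)
    b = np.exp(logb)                               # (R, J, M, C)
    u = np.sum(gparams.v[None] * b, axis=1)        # (R, M, C)
    O = _sigmoid(gparams.lam[None] * (u - gparams.theta[None]))
    Oprod = np.prod(O, axis=-1)                    # (R, M)
    Mf = _sigmoid(lparams.lam[None] * (Oprod - lparams.theta[None]))

    D = np.add.reduceat(counts[:, None] * Mf, starts, axis=0)  # (B, M)
    if normalization == "sum":
        Z = D.sum(axis=1)
        D_norm = D / Z[:, None]
    elif normalization == "image_area":
        Z = np.full(B, float(ds.n_interior))
        D_norm = D / Z[:, None]
    else:
        raise ValueError(f"unknown normalization mode {normalization!r}")
    predictions = np.argmax(D, axis=1) + 1
    T = np.zeros((B, D.shape[1]))
    T[np.arange(B), labels - 1] = 1.0
    loss = cross_entropy_loss(D_norm, T)

    row_sample = np.repeat(np.arange(B), np.diff(np.append(starts, len(rows))))
    return {
        "Xr": Xr, "counts": counts, "starts": starts, "row_sample": row_sample,
        "S0": S0, "S1": S1, "b": b, "u": u, "O": O, "Oprod": Oprod, "Mf": Mf,
        "D": D, "Z": Z, "D_norm": D_norm, "T": T, "labels": labels,
        "predictions": predictions, "loss": loss, "batch_size": B,
        "normalization": normalization,
    }


def backward_gradients(cache: dict, gparams: GanglionParams,
                       lparams: LGNParams,
                       mode: str = "exact") -> tuple[np.ndarray, np.ndarray]:
    """Batch-mean gradients of the loss w.r.t. w and q.

    ``exact`` differentiates the forward computation as implemented;
    ``paper_literal`` substitutes the printed simplified factors for the
    normalization, LGN and soma stages (the synapse-local factors
    dS/dw = (x/d) S (1-S) and dS/dq = -(1/d) S (1-S) are common to both).
    """
    required = ("Xr", "counts", "b", "O", "Oprod", "Mf", "D", "T", "row_sample")
    for key in required:
        if key not in cache:
            raise ValueError(f"forward cache is missing intermediate {key!r}")
    Xr, counts, row_sample = cache["Xr"], cache["counts"], cache["row_sample"]
    b, O, Oprod, Mf = cache["b"], cache["O"], cache["Oprod"], cache["Mf"]
    D, T, Z, B = cache["D"], cache["T"], cache["Z"], cache["batch_size"]

    if mode == "exact":
        # dE/dD_m through D-bar: 1/Z - T_m/D_m (sum mode), -T_m/D_m (area mode)
        if cache["normalization"] == "sum":
            gD = 1.0 / Z[:, None] - T / D
        else:
            gD = -T / D
        gMf = gD[row_sample] * counts[:, None]               # (R, M)
        gOprod = gMf * lparams.lam[None] * Mf * (1.0 - Mf)
        with np.errstate(divide="ignore", invalid="ignore"):
            others = Oprod[:, :, None] / np.maximum(O, np.finfo(float).tiny)
        gO = gOprod[:, :, None] * others                     # (R, M, C)
        gu = gO * gparams.lam[None] * O * (1.0 - O)
        gb = gparams.v[None] * gu[:, None]                   # (R, J, M, C)
    elif mode == "paper_literal":
        gDbar = -T / np.maximum(cache["D_norm"], LOG_CLAMP_EPS)
        gMf = gDbar[row_sample] * counts[:, None]            # Jacobian factor := 1
        s = _sigmoid(lparams.lam[None, :, None] * (O - lparams.theta[None, :, None]))
        gO = gMf[:, :, None] * lparams.lam[None, :, None] * s * (1.0 - s)
        s_soma = _sigmoid(gparams.lam[None] * (gparams.v - gparams.theta[None]))
        dO_db = gparams.v * gparams.lam[None] * s_soma * (1.0 - s_soma)  # (J, M, C)
        gb = gO[:, None] * dO_db[None]
    else:
        raise ValueError(f"unknown gradient mode {mode!r}")

    A = gb * b                                               # (R, J, M, C)
    XA = np.einsum("ric,rjmc->ijmc", Xr, A, optimize=True)
    Asum = A.sum(axis=0)                                     # (J, M, C)
    d = gparams.d[..., None]
    S0, S1 = cache["S0"], cache["S1"]
    # per-synapse factors: (b/S) * dS/dw = b (1-S) x / d; likewise for q
    gw = (1.0 - S1) / d * XA / B
    gq = -((1.0 - S0) * Asum[None] + (S0 - S1) * XA) / d / B
    return gw, gq


def numeric_gradient_oracle(fun, x0: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference gradient estimate, one coordinate at a time.

    Reference implementation for verifying analytic gradients; O(step^2)
    accurate and independent of any backward-pass code path.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    x0 = np.asarray(x0, dtype=float)
    grad = np.empty_like(x0)
    flat = x0.ravel()
    gflat = grad.ravel()
    for k in range(flat.size):
        orig = flat[k]
        flat[k] = orig + step
        fp = fun(x0)
        flat[k] = orig - step
        fm = fun(x0)
        flat[k] = orig
        gflat[k] = (fp - fm) / (2.0 * step)
    return grad


def sgd_step(params: GanglionParams, gw: np.ndarray, gq: np.ndarray,
             learning_rate: float) -> GanglionParams:
    """One gradient-descent update: w <- w - eta gw, q <- q - eta gq."""
    for name, g in (("w", gw), ("q", gq)):
        if not np.all(np.isfinite(g)):
            bad = tuple(int(k) for k in np.argwhere(~np.isfinite(np.asarray(g)))[0])
            raise FloatingPointError(
                f"non-finite gradient for {name} at coordinate {tuple(bad)}")
    out = params.copy()
    out.w -= learning_rate * np.asarray(gw)
    out.q -= learning_rate * np.asarray(gq)
    return out


def train_model(dataset: EncodedDataset | Sequence[FramePair],
                config: TrainConfig,
                gparams: GanglionParams | None = None,
                lparams: LGNParams | None = None,
                ) -> tuple[GanglionParams, pd.DataFrame]:
    """Mini-batch gradient descent with seeded shuffling and early stopping.

    Returns the trained parameters and a per-epoch history (epoch,
    train_loss, train_acc).  Training accuracy is the fraction of correct
    argmax predictions over the epoch's forward passes (before each
    update).  Training stops early once the epoch loss has not improved by
    ``min_delta`` for ``early_stop_patience`` consecutive epochs.
    Deterministic given ``config.seed``.
    """
    if not isinstance(dataset, EncodedDataset):
        if len(dataset) == 0:
            raise ValueError("cannot train on an empty dataset")
        dataset = encode_dataset(dataset, config.eps_vertical, config.eps_horizontal)
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    rng = np.random.default_rng(config.seed)
    if gparams is None:
        gparams = GanglionParams.init_random(rng)
    if lparams is None:
        lparams = LGNParams(n_directions=gparams.n_directions)

    n = len(dataset)
    history = []
    best_loss = np.inf
    first_loss = None
    improved_once = False
    stale = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        n_correct = 0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            cache = forward_batch(dataset, idx, gparams, lparams,
                                  config.normalization)
            gw, gq = backward_gradients(cache, gparams, lparams,
                                        config.gradient_mode)
            gparams = sgd_step(gparams, gw, gq, config.learning_rate)
            losses.append(cache["loss"] * len(idx))
            n_correct += int(np.sum(cache["predictions"] == cache["labels"]))
        epoch_loss = float(np.sum(losses) / n)
        epoch_acc = n_correct / n
        history.append({"epoch": epoch, "train_loss": epoch_loss,
                        "train_acc": epoch_acc})
        logger.info("epoch %d: loss=%.5f acc=%.4f", epoch, epoch_loss, epoch_acc)
        if first_loss is None:
            first_loss = epoch_loss
        if epoch_loss < best_loss - config.min_delta:
            best_loss = epoch_loss
            stale = 0
            if epoch_loss < first_loss - config.min_delta:
                improved_once = True
        else:
            stale += 1
            # the plateau counter only arms once training has left the
            # initial flat region, so slow starts are not cut short
            if improved_once and stale >= config.early_stop_patience:
                logger.info("early stop at epoch %d (loss plateau)", epoch)
                break
    return gparams, pd.DataFrame.from_records(history)


def predict_dataset(gparams: GanglionParams, lparams: LGNParams,
                    dataset: EncodedDataset, batch_size: int = 512,
                    normalization: str = "sum") -> np.ndarray:
    """Argmax direction predictions for every sample."""
    preds = np.empty(len(dataset), dtype=np.int64)
    order = np.arange(len(dataset))
    for lo in range(0, len(dataset), batch_size):
        idx = order[lo:lo + batch_size]
        cache = forward_batch(dataset, idx, gparams, lparams, normalization)
        preds[idx] = cache["predictions"]
    return preds


def evaluate_accuracy(gparams: GanglionParams, lparams: LGNParams,
                      dataset: EncodedDataset | Sequence[FramePair],
                      eps_vertical: float = 0, eps_horizontal: float = 1,
                      batch_size: int = 512) -> float:
    """Fraction of pairs whose predicted direction matches the label."""
    if not isinstance(dataset, EncodedDataset):
        dataset = encode_dataset(dataset, eps_vertical, eps_horizontal)
    preds = predict_dataset(gparams, lparams, dataset, batch_size)
    return float(np.mean(preds == dataset.labels))
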