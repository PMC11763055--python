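"""Learnable dendritic ganglion neuron (synapse -> branch -> membrane -> soma).

One neuron per (direction m, channel c) scans every interior receptive
field of the frame pair.  Its four layers are:

* synapse: ``S_ij = sigmoid((w_ij * x_i - q_ij) / d_ij)`` on the binary
  inputs x_i; the (w, q) pair makes a synapse excitatory, inhibitory,
  constant-1 or constant-0;
* branch: ``b_j = prod_i S_ij`` -- a multiplicative dendritic branch;
* membrane: ``u = sum_j v_j b_j``;
* soma: ``O = sigmoid(lambda * (u - theta))``.

Only w and q are learnable.  With the defaults I=9 synapses, J=1 branch,
M=8 directions and C=3 channels the model has 9 * 2 * 8 * 3 = 432
learnable parameters.  The distance d (sigmoid temperature), branch weight
v, soma slope lambda and threshold theta are fixed hyperparameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .data import DIRECTION_OFFSETS
from .retina import CENTER_SLOT, SLOT_OFFSETS

__all__ = [
    "GanglionParams",
    "GanglionActivation",
    "synapse_activation",
    "connection_state",
    "branch_output",
    "membrane_potential",
    "soma_output",
    "ganglion_forward",
    "count_learnable",
    "ideal_direction_params",
    "direction_slot",
    "save_checkpoint",
    "load_checkpoint",
]

_CHECKPOINT_VERSION = 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # Split form avoids overflow warnings for large |z|.
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def direction_slot(m: int) -> int:
    """0-based receptive-field slot index whose offset equals direction m."""
    offset = DIRECTION_OFFSETS[m]
    return SLOT_OFFSETS.index(offset)


@dataclasses.dataclass
class GanglionParams:
    """Parameters of all I x J x M x C dendritic ganglion neurons.

    ``w``/``q`` (learnable) have shape (I, J, M, C); ``d`` has shape
    (I, J, M); ``v`` has shape (J, M, C); ``lam``/``theta`` have shape
    (M, C).  Defaults: d = 0.5 (slope-2 synapse sigmoids), v = 1,
    lam = 5, theta = 0.5.
    """

    w: np.ndarray
    q: np.ndarray
    d: np.ndarray
    v: np.ndarray
    lam: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.w.ndim != 4 or self.w.shape != self.q.shape:
            raise ValueError("w and q must share an (I, J, M, C) shape")
        I, J, M, C = self.w.shape
        self.d = np.broadcast_to(np.asarray(self.d, dtype=float), (I, J, M)).copy()
        self.v = np.broadcast_to(np.asarray(self.v, dtype=float), (J, M, C)).copy()
        self.lam = np.broadcast_to(np.asarray(self.lam, dtype=float), (M, C)).copy()
        self.theta = np.broadcast_to(np.asarray(self.theta, dtype=float), (M, C)).copy()
        if np.any(self.d <= 0):
            raise ValueError("distance d must be strictly positive")
        if np.any(self.lam <= 0):
            raise ValueError("soma slope lambda must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.w.shape

    @property
    def n_synapses(self) -> int:
        return self.w.shape[0]

    @property
    def n_branches(self) -> int:
        return self.w.shape[1]

    @property
    def n_directions(self) -> int:
        return self.w.shape[2]

    @property
    def n_channels(self) -> int:
        return self.w.shape[3]

    def copy(self) -> "GanglionParams":
        return GanglionParams(w=self.w.copy(), q=self.q.copy(), d=self.d.copy(),
                              v=self.v.copy(), lam=self.lam.copy(),
                              theta=self.theta.copy())

    @classmethod
    def init_random(cls, rng: np.random.Generator, n_synapses: int = 9,
                    n_branches: int = 1, n_directions: int = 8,
                    n_channels: int = 3, d: float = 0.5, v: float = 1.0,
                    lam: float = 5.0, theta: float = 0.5,
                    scheme: str = "gated") -> "GanglionParams":
        """Seeded random initialization of the learnable w, q.

        ``gated`` (default) encodes the innate On-pathway structure: the
        centre synapse -- fed by the bipolar change detector -- starts in
        its excitatory state, while the surround (horizontal-cell) synapses
        start just inside the constant-1 region with small random
        perturbations, so branches transmit and direction selectivity is
        acquired by learning.  Without the innate gate the response
        component shared by all eight direction neurons is loss-neutral
        under sum normalization and gradient descent cannot learn the gate
        (see docs/methods.md).

        ``uniform`` draws w, q independently from U(-1, 1); it leaves the
        model at chance and is used for untrained-baseline controls.
        """
        shape = (n_synapses, n_branches, n_directions, n_channels)
        if scheme == "uniform":
            w = rng.uniform(-1.0, 1.0, size=shape)
            q = rng.uniform(-1.0, 1.0, size=shape)
        elif scheme == "gated":
            # surround: S(0) ~ S(1) ~ sigmoid(2) = 0.88, weakly constant-1
            w = d * rng.uniform(-0.1, 0.1, size=shape)
            q = d * rng.uniform(-2.2, -1.8, size=shape)
            center = n_synapses // 2  # slot 5 for the 3x3 field
            # centre: S(0) = sigmoid(-2) = 0.12 < 0.5 < S(1) = sigmoid(2)
            w[center] = d * rng.uniform(3.8, 4.2, size=w[center].shape)
            q[center] = d * rng.uniform(1.8, 2.2, size=q[center].shape)
        else:
            raise ValueError(f"unknown init scheme {scheme!r}")
        return cls(w=w, q=q, d=d, v=v, lam=lam, theta=theta)


def count_learnable(params: GanglionParams) -> int:
    """Number of learnable parameters (w and q entries)."""
    return params.w.size + params.q.size


@dataclasses.dataclass(frozen=True)
class GanglionActivation:
    """All intermediates of one forward pass at one (m, c, centre)."""

    S: np.ndarray  # (I, J) synapse outputs in (0, 1)
    b: np.ndarray  # (J,) branch outputs in (0, 1)
    u: float       # membrane potential
    O: float       # soma output in (0, 1)


def synapse_activation(x, w, q, d):
    """Synapse output ``sigmoid((w * x - q) / d)``; elementwise."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance d must be strictly positive")
    x = np.asarray(x, dtype=float)
    return _sigmoid((np.asarray(w, dtype=float) * x - np.asarray(q, dtype=float)) / d)


def connection_state(w: float, q: float, d: float = 0.2) -> str:
    """Classify a synapse by its outputs at x = 0 and x = 1.

    (low, high) -> excitatory, (high, low) -> inhibitory,
    (high, high) -> constant-1, (low, low) -> constant-0, thresholded at 0.5.
    """
    s0 = float(synapse_activation(0.0, w, q, d))
    s1 = float(synapse_activation(1.0, w, q, d))
    low0, low1 = s0 < 0.5, s1 < 0.5
    if low0 and not low1:
        return "excitatory"
    if not low0 and low1:
        return "inhibitory"
    if not low0 and not low1:
        return "constant-1"
    return "constant-0"


def branch_output(S: np.ndarray) -> np.ndarray:
    """Branch output: product of the branch's synapse outputs (axis 0)."""
    return np.prod(np.asarray(S, dtype=float), axis=0)


def membrane_potential(b: np.ndarray, v: np.ndarray):
    """Membrane potential: branch outputs weighted by v and summed."""
    b = np.asarray(b, dtype=float)
    v = np.asarray(v, dtype=float)
    if b.shape != v.shape:
        raise ValueError(f"branch/weight shapes differ: {b.shape} vs {v.shape}")
    return float(np.sum(v * b))


def soma_output(u, lam, theta):
    """Soma output ``sigmoid(lambda * (u - theta))``."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("soma slope lambda must be strictly positive")
    return _sigmoid(lam * (np.asarray(u, dtype=float) - np.asarray(theta, dtype=float)))


def ganglion_forward(x: np.ndarray, params: GanglionParams, m: int,
                     c: int) -> GanglionActivation:
    """Forward pass of the (m, c) neuron on one 9-vector of binary inputs.

    ``m`` is the 1-based direction label, ``c`` the 0-based channel.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_synapses,):
        raise ValueError(f"expected {params.n_synapses} inputs, got shape {x.shape}")
    mi = m - 1
    S = synapse_activation(x[:, None], params.w[:, :, mi, c],
                           params.q[:, :, mi, c], params.d[:, :, mi])
    b = branch_output(S)
    u = membrane_potential(b, params.v[:, mi, c])
    O = float(soma_output(u, params.lam[mi, c], params.theta[mi, c]))
    return GanglionActivation(S=S, b=b, u=u, O=O)


def ideal_direction_params(n_branches: int = 1, n_directions: int = 8,
                           n_channels: int = 3, d: float = 0.2, v: float = 1.0,
                           lam: float = 5.0, theta: float = 0.5) -> GanglionParams:
    """Hand-constructed direction-selective parameters.

    For each direction m the neuron is excitatory at the centre slot (the
    bipolar change detector must fire) and at the slot matching m's
    displacement (the horizontal match along the motion direction), and
    constant-1 everywhere else.  Used as a behavioural oracle: it predicts
    the true direction on high-contrast pairs without any learning.
    """
    shape = (9, n_branches, n_directions, n_channels)
    w = np.zeros(shape)
    q = np.full(shape, -1.0)  # w=0, q=-1 -> constant-1 at d=0.2
    for m in range(1, n_directions + 1):
        for slot in (CENTER_SLOT, direction_slot(m)):
            w[slot, :, m - 1, :] = 2.0
            q[slot, :, m - 1, :] = 1.0  # excitatory: S(0)<<0.5<<S(1)
    return GanglionParams(w=w, q=q, d=d, v=v, lam=lam, theta=theta)


def save_checkpoint(params: GanglionParams, path: str | Path) -> Path:
    """Write a flat, versioned, text (JSON) checkpoint.

    Floats are serialized by repr, which round-trips binary64 exactly.
    """
    path = Path(path)
    payload = {
        "format": "avsmotion-ganglion-checkpoint",
        "version": _CHECKPOINT_VERSION,
        "shape": list(params.shape),
        "arrays": {
            name: getattr(params, name).ravel().tolist()
            for name in ("w", "q", "d", "v", "lam", "theta")
        },
    }
    path.write_text(json.dumps(payload))
    return path


def load_checkpoint(path: str | Path) -> GanglionParams:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "avsmotion-ganglion-checkpoint":
        raise ValueError(f"{path} is not a ganglion checkpoint")
    if payload.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {payload.get('version')}")
    I, J, M, C = payload["shape"]
    arr = {k: np.asarray(vals, dtype=float) for k, vals in payload["arrays"].items()}
    return GanglionParams(w=arr["w"].reshape(I, J, M, C),
                          q=arr["q"].reshape(I, J, M, C),
                          d=arr["d"].reshape(I, J, M),
                          v=arr["v"].reshape(J, M, C),
                          lam=arr["lam"].reshape(M, C),
                          theta=arr["theta"].reshape(M, C))
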