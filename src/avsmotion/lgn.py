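"""LGN integration of the three channels and the global direction readout.

The lateral geniculate nucleus is modelled as a fixed (non-learnable)
dendritic neuron per direction and pixel: the three per-channel soma
outputs are multiplied -- activation requires all three channels -- and
passed through a sigmoid,

    M_m(a, b) = sigmoid(lambda_m * (O^R * O^G * O^B - theta_m)).

Global direction evidence is the sum over all valid (interior) receptive
fields, D_m = sum_{a,b} M_m(a, b); the normalized outputs D-bar feed the
cross-entropy loss and the predicted direction is argmax_m D_m.

Normalization modes: ``sum`` (default) divides by the total over
directions, giving a probability simplex, which a cross-entropy loss
requires; ``image_area`` divides by the pixel count A*B instead.  The two
modes coincide for the argmax readout but not for the loss surface; the
area mode exists because the printed simplification of the learning rule
implies it (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ganglion import GanglionParams, _sigmoid
from .retina import encode_pair

__all__ = [
    "LGNParams",
    "DirectionField",
    "lgn_integrate",
    "direction_sums",
    "normalize_outputs",
    "predict_direction",
    "forward_field",
]


@dataclasses.dataclass
class LGNParams:
    """Fixed per-direction soma slope and threshold of the LGN neuron."""

    lam: np.ndarray = 5.0
    theta: np.ndarray = 0.5
    n_directions: int = 8

    def __post_init__(self) -> None:
        self.lam = np.broadcast_to(np.asarray(self.lam, dtype=float),
                                   (self.n_directions,)).copy()
        self.theta = np.broadcast_to(np.asarray(self.theta, dtype=float),
                                     (self.n_directions,)).copy()
        if np.any(self.lam <= 0):
            raise ValueError("LGN slope lambda must be strictly positive")


@dataclasses.dataclass(frozen=True)
class DirectionField:
    """LGN activations and global sums of one frame pair.

    ``M`` has shape (P, 8) over interior pixels in row-major order;
    ``D`` is the 8-vector of direction sums; ``D_norm`` its normalization;
    ``prediction`` the argmax direction label in 1..8.
    """

    M: np.ndarray
    D: np.ndarray
    D_norm: np.ndarray
    prediction: int


def lgn_integrate(O: np.ndarray, params: LGNParams, m: int | None = None):
    """LGN activation from the three per-channel soma outputs.

    ``O`` is an array whose last axis has length 3 (channels).  With ``m``
    given (1-based), the m-th slope/threshold apply to every entry;
    otherwise the second-to-last axis must enumerate all directions.
    """
    O = np.asarray(O, dtype=float)
    if O.shape[-1] != 3:
        raise ValueError(f"expected 3 channels on the last axis, got {O.shape}")
    prod = np.prod(O, axis=-1)
    if m is not None:
        lam, theta = params.lam[m - 1], params.theta[m - 1]
    else:
        lam, theta = params.lam, params.theta
    return _sigmoid(lam * (prod - theta))


def direction_sums(M: np.ndarray) -> np.ndarray:
    """Global direction sums D_m over the field's pixel axis (axis 0)."""
    return np.asarray(M, dtype=float).sum(axis=0)


def normalize_outputs(D: np.ndarray, mode: str = "sum",
                      area: int | None = None) -> np.ndarray:
    """Normalize direction sums; ``sum`` yields a probability simplex."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("direction sums must be non-negative")
    if mode == "sum":
        total = D.sum()
        if total == 0:
            raise ValueError("degenerate field: all direction sums are zero")
        return D / total
    if mode == "image_area":
        if area is None or area <= 0:
            raise ValueError("image_area normalization needs a positive area")
        return D / float(area)
    raise ValueError(f"unknown normalization mode {mode!r}")


def predict_direction(D: np.ndarray) -> int:
    """Argmax direction label (1..8); ties break toward the smallest label."""
    return int(np.argmax(np.asarray(D))) + 1


def forward_field(frame_t: np.ndarray | None, frame_t1: np.ndarray | None,
                  gparams: GanglionParams, lparams: LGNParams | None = None,
                  *, encoded: np.ndarray | None = None,
                  eps_vertical: float = 0, eps_horizontal: float = 1,
                  normalization: str = "sum") -> DirectionField:
    """Full forward pass of one frame pair through retina, ganglia and LGN.

    Either a frame pair or a precomputed retinal encoding (P, 9, C) may be
    supplied.  Grayscale frames (HxW or HxWx1) are accepted by replicating
    the single channel across the three cone types.
    """
    if lparams is None:
        lparams = LGNParams(n_directions=gparams.n_directions)
    if encoded is None:
        frame_t = _as_rgb(frame_t)
        frame_t1 = _as_rgb(frame_t1)
        encoded = encode_pair(frame_t, frame_t1, eps_vertical, eps_horizontal)
    X = np.asarray(encoded, dtype=float)  # (P, 9, C)
    # synapse/branch/membrane/soma for every pixel, direction and channel
    S = _sigmoid((gparams.w[None] * X[:, :, None, None, :] - gparams.q[None])
                 / gparams.d[None, :, :, :, None])          # (P, I, J, M, C)
    b = np.prod(S, axis=1)                                   # (P, J, M, C)
    u = np.sum(gparams.v[None] * b, axis=1)                  # (P, M, C)
    O = _sigmoid(gparams.lam[None] * (u - gparams.theta[None]))
    M = lgn_integrate(O, lparams)                            # (P, M)
    D = direction_sums(M)
    D_norm = normalize_outputs(D, mode=normalization, area=X.shape[0])
    return DirectionField(M=M, D=D, D_norm=D_norm, prediction=predict_direction(D))


def _as_rgb(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = frame[:, :, None]
    if frame.ndim == 3 and frame.shape[2] == 1:
        frame = np.repeat(frame, 3, axis=2)
    return frame
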