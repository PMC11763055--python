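"""Retinal front end: cone-cell channel split and On-Off binarization.

The three cone types are modelled as the R/G/B planes of the frame.  Two
cell types then binarize a frame pair per channel:

* bipolar cells give the *vertical* On-Off response -- a temporal change
  detector at each pixel: 1 iff ``|x(t) - x(t+dt)| > eps_vertical``;
* horizontal cells give the *horizontal* On-Off response -- a spatial match
  detector between the centre pixel at time t and each cell of its 3x3
  receptive field at time t+dt: 1 iff ``|x_center(t) - x'_i(t+dt)| <
  eps_horizontal``.

Slots i = 1..9 index the 3x3 field in reading order (slot 2 is the cell
above the centre, slot 5 the centre itself).  The per-pixel input vector of
the downstream dendritic neuron takes slot 5 from the vertical map and the
remaining slots from the horizontal maps.

Boundary conventions: a difference exactly equal to a threshold falls on
the "off" branch (the defining inequalities are strict), and only centres
with a full 3x3 neighbourhood inside the grid are valid -- no intensity is
fabricated beyond the border, so maps at border centres are left zero and
downstream sums run over the interior.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "SLOT_OFFSETS",
    "CENTER_SLOT",
    "OnOffMaps",
    "split_channels",
    "vertical_onoff",
    "horizontal_onoff",
    "compute_onoff_maps",
    "assemble_rf_inputs",
    "encode_pair",
    "interior_shape",
]

#: (drow, dcol) of receptive-field slot i, 0-based index i-1, reading order.
SLOT_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 0), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

#: 0-based index of the centre slot (i = 5).
CENTER_SLOT = 4

#: Default thresholds: any integer intensity change fires a bipolar cell,
#: and a horizontal cell requires an exact integer intensity match.
DEFAULT_EPS_VERTICAL = 0
DEFAULT_EPS_HORIZONTAL = 1


def _check_frames(frame_t: np.ndarray, frame_t1: np.ndarray) -> tuple[int, int, int]:
    frame_t = np.asarray(frame_t)
    frame_t1 = np.asarray(frame_t1)
    if frame_t.shape != frame_t1.shape:
        raise ValueError(f"frame shapes differ: {frame_t.shape} vs {frame_t1.shape}")
    if frame_t.ndim != 3:
        raise ValueError("frames must be HxWxC")
    return frame_t.shape


def split_channels(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an HxWx3 frame into its R, G, B intensity matrices (lossless)."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 frame, got shape {frame.shape}")
    return frame[:, :, 0], frame[:, :, 1], frame[:, :, 2]


def vertical_onoff(frame_t: np.ndarray, frame_t1: np.ndarray,
                   eps_vertical: float = DEFAULT_EPS_VERTICAL) -> np.ndarray:
    """Bipolar-cell map, shape (H, W, C): 1 iff ``|x(t) - x(t+dt)| > eps``."""
    if eps_vertical < 0:
        raise ValueError("eps_vertical must be >= 0")
    _check_frames(frame_t, frame_t1)
    diff = np.abs(frame_t.astype(np.int16) - frame_t1.astype(np.int16))
    return (diff > eps_vertical).astype(np.uint8)


def horizontal_onoff(frame_t: np.ndarray, frame_t1: np.ndarray,
                     eps_horizontal: float = DEFAULT_EPS_HORIZONTAL) -> np.ndarray:
    """Horizontal-cell maps, shape (H, W, 9, C).

    Slot i at centre (a, b) is 1 iff the centre intensity at time t matches
    (within ``eps_horizontal``, strictly) the i-th cell of the 3x3 field
    around (a, b) at time t+dt.  Border centres, whose field leaves the
    grid, are left zero and are excluded downstream.
    """
    if eps_horizontal <= 0:
        raise ValueError("eps_horizontal must be > 0")
    H, W, C = _check_frames(frame_t, frame_t1)
    xt = frame_t.astype(np.int16)
    xt1 = frame_t1.astype(np.int16)
    out = np.zeros((H, W, 9, C), dtype=np.uint8)
    if H < 3 or W < 3:
        return out
    center = xt[1:-1, 1:-1]
    for slot, (dr, dc) in enumerate(SLOT_OFFSETS):
        nb = xt1[1 + dr:H - 1 + dr, 1 + dc:W - 1 + dc]
        out[1:-1, 1:-1, slot] = np.abs(center - nb) < eps_horizontal
    return out


@dataclasses.dataclass(frozen=True)
class OnOffMaps:
    """Binary On-Off responses of one frame pair.

    ``vertical``: (H, W, C) bipolar map; ``horizontal``: (H, W, 9, C)
    horizontal-cell maps (zero at border centres).
    """

    vertical: np.ndarray
    horizontal: np.ndarray
    eps_vertical: float
    eps_horizontal: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.vertical.shape[:2]


def compute_onoff_maps(frame_t: np.ndarray, frame_t1: np.ndarray,
                       eps_vertical: float = DEFAULT_EPS_VERTICAL,
                       eps_horizontal: float = DEFAULT_EPS_HORIZONTAL) -> OnOffMaps:
    return OnOffMaps(
        vertical=vertical_onoff(frame_t, frame_t1, eps_vertical),
        horizontal=horizontal_onoff(frame_t, frame_t1, eps_horizontal),
        eps_vertical=eps_vertical,
        eps_horizontal=eps_horizontal,
    )


def assemble_rf_inputs(onoff: OnOffMaps, center: tuple[int, int],
                       channel: int) -> np.ndarray:
    """The 9-vector feeding one dendritic neuron at an interior centre.

    Slot 5 comes from the vertical (bipolar) map, all other slots from the
    horizontal maps.
    """
    H, W = onoff.shape
    r, c = center
    if not (1 <= r <= H - 2 and 1 <= c <= W - 2):
        raise ValueError(f"centre {center} has no full 3x3 field in a {H}x{W} grid")
    x = onoff.horizontal[r, c, :, channel].astype(np.uint8).copy()
    x[CENTER_SLOT] = onoff.vertical[r, c, channel]
    return x


def interior_shape(shape: tuple[int, int]) -> tuple[int, int]:
    H, W = shape
    return max(H - 2, 0), max(W - 2, 0)


def encode_pair(frame_t: np.ndarray, frame_t1: np.ndarray,
                eps_vertical: float = DEFAULT_EPS_VERTICAL,
                eps_horizontal: float = DEFAULT_EPS_HORIZONTAL) -> np.ndarray:
    """Binary neuron inputs for every interior centre, shape (P, 9, C).

    P = (H-2)*(W-2) interior centres in row-major order; equivalent to
    calling :func:`assemble_rf_inputs` at each centre, but vectorized.
    """
    if eps_vertical < 0:
        raise ValueError("eps_vertical must be >= 0")
    if eps_horizontal <= 0:
        raise ValueError("eps_horizontal must be > 0")
    H, W, C = _check_frames(frame_t, frame_t1)
    if H < 3 or W < 3:
        raise ValueError("frames must be at least 3x3")
    xt = frame_t.astype(np.int16)
    xt1 = frame_t1.astype(np.int16)
    center = xt[1:-1, 1:-1]
    P = (H - 2) * (W - 2)
    x = np.empty((P, 9, C), dtype=np.uint8)
    for slot, (dr, dc) in enumerate(SLOT_OFFSETS):
        nb = xt1[1 + dr:H - 1 + dr, 1 + dc:W - 1 + dc]
        if slot == CENTER_SLOT:
            resp = np.abs(center - nb) > eps_vertical
        else:
            resp = np.abs(center - nb) < eps_horizontal
        x[:, slot, :] = resp.reshape(P, C)
    return x
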