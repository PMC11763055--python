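"""Synthetic moving-object dataset for motion-direction detection.

Each sample is a pair of same-sized 8-bit RGB frames: the scene at time t
and at t + Delta-t, where a connected object has translated by exactly one
pixel in one of the eight compass directions while the background stays
static.  Objects and backgrounds are drawn from three intensity categories:

* ``dark``     -- every pixel value 0,
* ``constant`` -- one RGB triplet, drawn once per region with each channel
  uniform on [1, 255], shared by every cell of the region ("light"),
* ``random``   -- every cell and channel i.i.d. uniform on [0, 255].

Combining an object category with a background category yields the eight
configurations DL, DR, LD, LL, LR, RD, RL, RR (object letter first; the
dark-on-dark case is excluded because an invisible object has no motion
label).  The benchmark default is a 32x32 grid, eight object sizes
{1, 2, 4, 8, 16, 32, 64, 128} and 500 pairs per direction per size, i.e.
4000 pairs per (configuration, size).

Coordinates are 0-based (row, col) with row 0 at the top.  Direction labels
m = 1..8 enumerate the 3x3 neighbourhood of a pixel in reading order,
skipping the centre: 1=up-left, 2=up, 3=up-right, 4=left, 5=right,
6=down-left, 7=down, 8=down-right.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CONFIGURATIONS",
    "DIRECTIONS",
    "DIRECTION_OFFSETS",
    "DatasetSpec",
    "FramePair",
    "grow_object_mask",
    "sample_region_colors",
    "render_motion_pair",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

CONFIGURATIONS: tuple[str, ...] = ("DL", "DR", "LD", "LL", "LR", "RD", "RL", "RR")

#: Unit displacement (drow, dcol) for each direction label m = 1..8.
DIRECTION_OFFSETS: dict[int, tuple[int, int]] = {
    1: (-1, -1), 2: (-1, 0), 3: (-1, 1),
    4: (0, -1),              5: (0, 1),
    6: (1, -1), 7: (1, 0), 8: (1, 1),
}

DIRECTIONS: tuple[int, ...] = tuple(range(1, 9))

_CATEGORY_BY_LETTER = {"D": "dark", "L": "constant", "R": "random"}

_MANIFEST_COLUMNS = ("id", "config", "object_size", "direction",
                     "frame_t_path", "frame_t1_path")


@dataclasses.dataclass(frozen=True)
class DatasetSpec:
    """Declarative description of a synthetic motion dataset.

    Defaults are the full benchmark conditions: 32x32x3 frames, all eight
    object/background configurations, object sizes 1..128 and 500 pairs per
    direction per size.
    """

    image_height: int = 32
    image_width: int = 32
    configurations: tuple[str, ...] = CONFIGURATIONS
    object_sizes: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128)
    pairs_per_direction: int = 500
    directions: tuple[int, ...] = DIRECTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 3 or self.image_width < 3:
            raise ValueError("grid must be at least 3x3")
        if not self.configurations:
            raise ValueError("configurations must be non-empty")
        for cfg in self.configurations:
            if cfg == "DD":
                raise ValueError("DD (dark object on dark background) carries no label")
            if cfg not in CONFIGURATIONS:
                raise ValueError(f"unknown configuration {cfg!r}")
        area = self.image_height * self.image_width
        for size in self.object_sizes:
            if not 1 <= size <= area:
                raise ValueError(f"object size {size} exceeds grid area {area}")
        if self.pairs_per_direction < 1:
            raise ValueError("pairs_per_direction must be >= 1")
        for m in self.directions:
            if m not in DIRECTION_OFFSETS:
                raise ValueError(f"unknown direction label {m}")

    @property
    def n_pairs(self) -> int:
        return (len(self.configurations) * len(self.object_sizes)
                * len(self.directions) * self.pairs_per_direction)

    def to_dict(self) -> dict:
        return {
            "image_height": self.image_height,
            "image_width": self.image_width,
            "configurations": list(self.configurations),
            "object_sizes": list(self.object_sizes),
            "pairs_per_direction": self.pairs_per_direction,
            "directions": list(self.directions),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSpec":
        d = dict(d)
        for key in ("configurations", "object_sizes", "directions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class FramePair:
    """Two 8-bit RGB frames plus the ground-truth motion label.

    ``object_mask_t`` holds the object's (row, col) cells at time t; it may
    be ``None`` for pairs reloaded from disk, where only frames and labels
    round-trip.
    """

    frame_t: np.ndarray
    frame_t1: np.ndarray
    direction_label: int
    config: str
    object_size: int
    object_mask_t: frozenset[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        for name in ("frame_t", "frame_t1"):
            frame = getattr(self, name)
            if frame.ndim != 3 or frame.shape[2] != 3:
                raise ValueError(f"{name} must be HxWx3, got {frame.shape}")
            if frame.dtype != np.uint8:
                raise ValueError(f"{name} must be uint8")
        if self.frame_t.shape != self.frame_t1.shape:
            raise ValueError("frames must share a shape")
        if self.direction_label not in DIRECTION_OFFSETS:
            raise ValueError(f"direction label {self.direction_label} not in 1..8")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame_t.shape[:2]

    def validate(self) -> None:
        """Check the full set of sample invariants (used by tests).

        The mask must be 4-connected with exactly ``object_size`` members,
        the labelled shift must stay in-grid, and every pixel outside
        mask-union-shifted-mask must be identical between the frames.
        """
        if self.object_mask_t is None:
            raise ValueError("cannot validate a pair without its object mask")
        mask = self.object_mask_t
        if len(mask) != self.object_size:
            raise AssertionError("mask size differs from object_size")
        if not _is_4_connected(mask):
            raise AssertionError("object mask is not 4-connected")
        H, W = self.shape
        dr, dc = DIRECTION_OFFSETS[self.direction_label]
        shifted = {(r + dr, c + dc) for r, c in mask}
        for r, c in mask | shifted:
            if not (0 <= r < H and 0 <= c < W):
                raise AssertionError("object leaves the grid")
        touched = np.zeros((H, W), dtype=bool)
        for r, c in mask | shifted:
            touched[r, c] = True
        if not np.array_equal(self.frame_t[~touched], self.frame_t1[~touched]):
            raise AssertionError("background changed between frames")


def _is_4_connected(cells: Iterable[tuple[int, int]]) -> bool:
    cells = set(cells)
    if not cells:
        return False
    seen = set()
    stack = [next(iter(cells))]
    while stack:
        r, c = stack.pop()
        if (r, c) in seen:
            continue
        seen.add((r, c))
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in cells and nb not in seen:
                stack.append(nb)
    return seen == cells


def grow_object_mask(size: int, grid: tuple[int, int],
                     rng: np.random.Generator) -> frozenset[tuple[int, int]]:
    """Grow a 4-connected object of ``size`` cells by seeded random accretion.

    The object is confined to the grid interior with a one-cell margin on
    every edge, so that any of the eight unit shifts stays in bounds.  Growth
    starts from a uniformly chosen cell and repeatedly annexes a uniformly
    chosen unfilled 4-neighbour of the current region; within the
    (H-2)x(W-2) margin region such growth can never get stuck before the
    region is full.
    """
    H, W = grid
    if H < 3 or W < 3:
        raise ValueError("grid must be at least 3x3 to leave a one-cell margin")
    capacity = (H - 2) * (W - 2)
    if not 1 <= size <= capacity:
        raise ValueError(
            f"object size {size} cannot be placed with margin in a {H}x{W} grid "
            f"(capacity {capacity})")

    def in_region(r: int, c: int) -> bool:
        return 1 <= r <= H - 2 and 1 <= c <= W - 2

    start = (int(rng.integers(1, H - 1)), int(rng.integers(1, W - 1)))
    mask = {start}
    frontier = {nb for nb in _neighbors4(*start) if in_region(*nb)}
    while len(mask) < size:
        choices = sorted(frontier)
        cell = choices[int(rng.integers(len(choices)))]
        mask.add(cell)
        frontier.discard(cell)
        for nb in _neighbors4(*cell):
            if in_region(*nb) and nb not in mask:
                frontier.add(nb)
    return frozenset(mask)


def _neighbors4(r: int, c: int):
    return (r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)


def sample_region_colors(category: str, n_cells: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw per-cell RGB triplets for one region, shape ``(n_cells, 3)``.

    ``dark``: all zeros.  ``constant``: a single triplet with each channel
    uniform on [1, 255], shared by all cells.  ``random``: every cell and
    channel independent uniform on [0, 255].
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if category == "dark":
        return np.zeros((n_cells, 3), dtype=np.uint8)
    if category == "constant":
        triplet = rng.integers(1, 256, size=3, dtype=np.int64)
        return np.broadcast_to(triplet, (n_cells, 3)).astype(np.uint8)
    if category == "random":
        return rng.integers(0, 256, size=(n_cells, 3), dtype=np.int64).astype(np.uint8)
    raise ValueError(f"unknown color category {category!r}")


def render_motion_pair(mask: Iterable[tuple[int, int]],
                       object_colors: np.ndarray,
                       background_colors: np.ndarray,
                       direction: int,
                       config: str = "LD") -> FramePair:
    """Paint the static background, then the object at t and at t+Delta-t.

    ``object_colors`` is aligned with ``sorted(mask)`` (row-major); the same
    per-cell colors translate with the object, and cells the object vacates
    revert to the background.
    """
    mask = frozenset(mask)
    bg = np.asarray(background_colors, dtype=np.uint8)
    if bg.ndim != 3 or bg.shape[2] != 3:
        raise ValueError("background_colors must be HxWx3")
    H, W = bg.shape[:2]
    cells = sorted(mask)
    colors = np.asarray(object_colors, dtype=np.uint8)
    if colors.shape != (len(cells), 3):
        raise ValueError("object_colors must be (len(mask), 3)")
    dr, dc = DIRECTION_OFFSETS[direction]
    rows = np.fromiter((r for r, _ in cells), dtype=np.intp, count=len(cells))
    cols = np.fromiter((c for _, c in cells), dtype=np.intp, count=len(cells))
    if ((rows + dr < 0).any() or (rows + dr >= H).any()
            or (cols + dc < 0).any() or (cols + dc >= W).any()):
        raise ValueError(f"shift {direction} moves the object out of the {H}x{W} grid")
    frame_t = bg.copy()
    frame_t[rows, cols] = colors
    frame_t1 = bg.copy()
    frame_t1[rows + dr, cols + dc] = colors
    return FramePair(frame_t=frame_t, frame_t1=frame_t1,
                     direction_label=direction, config=config,
                     object_size=len(cells), object_mask_t=mask)


def generate_dataset(spec: DatasetSpec) -> tuple[list[FramePair], pd.DataFrame]:
    """Generate all pairs of ``spec`` deterministically from its seed.

    Returns the pairs and an in-memory manifest with one row per pair
    (columns id, config, object_size, direction).  In the LL configuration
    the background triplet is resampled if it coincides with the object
    triplet in all three channels, which would make the object invisible.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    pairs: list[FramePair] = []
    records: list[dict] = []
    for config in spec.configurations:
        obj_cat = _CATEGORY_BY_LETTER[config[0]]
        bg_cat = _CATEGORY_BY_LETTER[config[1]]
        for size in spec.object_sizes:
            for m in spec.directions:
                for _ in range(spec.pairs_per_direction):
                    mask = grow_object_mask(size, (H, W), rng)
                    obj_colors = sample_region_colors(obj_cat, size, rng)
                    bg = sample_region_colors(bg_cat, H * W, rng).reshape(H, W, 3)
                    if obj_cat == "constant" and bg_cat == "constant":
                        while np.array_equal(obj_colors[0], bg[0, 0]):
                            bg = sample_region_colors(bg_cat, H * W, rng).reshape(H, W, 3)
                    pair = render_motion_pair(mask, obj_colors, bg, m, config=config)
                    records.append({
                        "id": len(pairs),
                        "config": config,
                        "object_size": size,
                        "direction": m,
                    })
                    pairs.append(pair)
    return pairs, pd.DataFrame.from_records(records)


def write_dataset(pairs: Sequence[FramePair], directory: str | Path) -> Path:
    """Persist pairs as lossless 8-bit RGB PNGs plus a CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames_dir = directory / "frames"
    frames_dir.mkdir(exist_ok=True)
    records = []
    for idx, pair in enumerate(pairs):
        t_name = f"pair{idx:06d}_t.png"
        t1_name = f"pair{idx:06d}_t1.png"
        Image.fromarray(pair.frame_t, mode="RGB").save(frames_dir / t_name)
        Image.fromarray(pair.frame_t1, mode="RGB").save(frames_dir / t1_name)
        mask_repr = ""
        if pair.object_mask_t is not None:
            mask_repr = ";".join(f"{r},{c}" for r, c in sorted(pair.object_mask_t))
        records.append({
            "id": idx,
            "config": pair.config,
            "object_size": pair.object_size,
            "direction": pair.direction_label,
            "frame_t_path": f"frames/{t_name}",
            "frame_t1_path": f"frames/{t1_name}",
            "object_mask": mask_repr,
        })
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return directory


def read_dataset(directory: str | Path) -> list[FramePair]:
    """Reload a dataset written by :func:`write_dataset`, bit-exactly."""
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv under {directory}")
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns {missing}")
    pairs: list[FramePair] = []
    for _, row in manifest.iterrows():
        frames = []
        for col in ("frame_t_path", "frame_t1_path"):
            path = directory / str(row[col])
            if not path.exists():
                raise FileNotFoundError(
                    f"manifest row id={row['id']}: missing frame file {path}")
            with Image.open(path) as img:
                frames.append(np.asarray(img.convert("RGB"), dtype=np.uint8))
        mask = None
        mask_repr = str(row.get("object_mask", "") or "")
        if mask_repr:
            mask = frozenset(
                (int(r), int(c))
                for r, c in (cell.split(",") for cell in mask_repr.split(";")))
        try:
            pair = FramePair(frame_t=frames[0], frame_t1=frames[1],
                             direction_label=int(row["direction"]),
                             config=str(row["config"]),
                             object_size=int(row["object_size"]),
                             object_mask_t=mask)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"manifest row id={row['id']}: {exc}") from exc
        pairs.append(pair)
    return pairs
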