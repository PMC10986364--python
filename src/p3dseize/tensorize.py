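"""Spatial tensorization: electrode grid layout, per-cell z-scoring, and
assembly of the T=2 sequence of N x H x W feature blocks the model consumes.

The 23 referential electrodes are pinned onto a 4 x 7 grid ordered
anterior-to-posterior (rows) and left-to-right (columns); 5 cells are empty
and carry 0 after standardization (the standardized mean), which keeps
convolutions well-defined. Standardization statistics are a pure function
of the training split — fitting them per CV fold avoids train/test leakage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureBlock

logger = logging.getLogger(__name__)

GRID_H, GRID_W = 4, 7

_DEFAULT_ROWS = (
    (None, "AF7", "AF3", None, "AF4", "AF8", None),
    ("FT9", "FT7", "FC3", "FCz", "FC4", "FT8", "FT10"),
    ("T7", "TP7", "CP3", "CPz", "CP4", "TP8", "T8"),
    (None, "PO7", "PO3", "PO4", "PO8", "P8", None),
)

DEFAULT_GRID_MAPPING: dict[str, tuple[int, int]] = {
    name: (r, c)
    for r, row in enumerate(_DEFAULT_ROWS)
    for c, name in enumerate(row)
    if name is not None
}


@dataclass(frozen=True)
class GridLayout:
    mapping: dict[str, tuple[int, int]]
    empty_cells: tuple[tuple[int, int], ...]

    def __post_init__(self):
        cells = list(self.mapping.values())
        if len(set(cells)) != len(cells):
            raise ValueError("grid mapping must be injective")
        for r, c in cells:
            if not (0 <= r < GRID_H and 0 <= c < GRID_W):
                raise ValueError(f"cell {(r, c)} outside the {GRID_H}x{GRID_W} grid")
        if len(self.mapping) + len(self.empty_cells) != GRID_H * GRID_W:
            raise ValueError("mapped + empty cells must cover the grid")

    @property
    def shape(self) -> tuple[int, int]:
        return (GRID_H, GRID_W)

    def to_json(self) -> str:
        return json.dumps({k: list(v) for k, v in sorted(self.mapping.items())})

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def build_grid_layout(
    channel_names,
    custom_mapping: dict[str, tuple[int, int]] | None = None,
) -> GridLayout:
    """Place electrodes on the 4 x 7 grid (canonical layout, overridable)."""
    channel_names = list(channel_names)
    if len(set(channel_names)) != len(channel_names):
        raise ValueError("duplicate electrode names in input")
    source = custom_mapping if custom_mapping is not None else DEFAULT_GRID_MAPPING
    mapping = {}
    unknown = [n for n in channel_names if n not in source]
    if unknown:
        raise ValueError(f"no grid position for electrode(s): {unknown}")
    for n in channel_names:
        mapping[n] = tuple(source[n])
    occupied = set(mapping.values())
    if len(occupied) != len(mapping):
        raise ValueError("two electrodes map to the same grid cell")
    empty = tuple(
        (r, c) for r in range(GRID_H) for c in range(GRID_W) if (r, c) not in occupied
    )
    return GridLayout(mapping=mapping, empty_cells=empty)


@dataclass
class ScalerStats:
    """Per-(feature, grid-cell) mean and standard deviation from a training split."""

    mean: np.ndarray  # (features, H, W)
    sd: np.ndarray  # (features, H, W)
    feature_names: tuple[str, ...]
    layout_digest: str

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.mean.tobytes())
        h.update(self.sd.tobytes())
        h.update(",".join(self.feature_names).encode())
        return h.hexdigest()[:16]


def _grid_values(block: FeatureBlock, layout: GridLayout) -> np.ndarray:
    """(windows, steps, features, H, W) with empty cells NaN."""
    w, s, f, _ = block.values.shape
    grid = np.full((w, s, f, GRID_H, GRID_W), np.nan)
    for ci, name in enumerate(block.channel_names):
        r, c = layout.mapping[name]
        grid[:, :, :, r, c] = block.values[:, :, :, ci]
    return grid


def fit_scaler(train_block: FeatureBlock, layout: GridLayout) -> ScalerStats:
    """Estimate z-score statistics on training rows only (windows x steps pooled)."""
    w, s, f, _ = train_block.values.shape
    flat = train_block.values.reshape(w * s, f, -1)  # pool windows x steps
    ch_mean = flat.mean(axis=0) if w else np.zeros(flat.shape[1:])
    ch_sd = flat.std(axis=0) if w else np.zeros(flat.shape[1:])
    mean = np.zeros((f, GRID_H, GRID_W))
    sd = np.zeros((f, GRID_H, GRID_W))
    for ci, name in enumerate(train_block.channel_names):
        r, c = layout.mapping[name]
        mean[:, r, c] = ch_mean[:, ci]
        sd[:, r, c] = ch_sd[:, ci]
    mapped = np.zeros((GRID_H, GRID_W), dtype=bool)
    for r, c in layout.mapping.values():
        mapped[r, c] = True
    n_const = int((sd[:, mapped] == 0).sum()) if w else 0
    if n_const > 0:
        logger.warning(
            "%d constant (feature, cell) columns; standardized to 0", n_const
        )
    return ScalerStats(mean, sd, train_block.feature_names, layout.digest())


@dataclass
class TensorSample:
    """One model input: (T, N, H, W, 1) standardized feature tensor."""

    data: np.ndarray
    label: int
    window_id: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 5 or self.data.shape[-1] != 1:
            raise ValueError("tensor must have shape (T, N, H, W, 1)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("tensor contains non-finite values")


def apply_scaler(block: FeatureBlock, layout: GridLayout,
                 stats: ScalerStats) -> np.ndarray:
    """Standardize onto the grid: (windows, steps, features, H, W); empty cells 0."""
    if tuple(stats.feature_names) != tuple(block.feature_names):
        raise ValueError(
            f"scaler fitted for features {stats.feature_names}, "
            f"block has {block.feature_names}"
        )
    grid = _grid_values(block, layout)
    sd_safe = np.where(stats.sd > 0, stats.sd, 1.0)
    z = (grid - stats.mean) / sd_safe
    z = np.where(stats.sd > 0, z, 0.0)  # constant columns pass through as 0
    return np.nan_to_num(z)  # empty cells -> 0


def assemble_tensor(
    block: FeatureBlock,
    layout: GridLayout,
    stats: ScalerStats,
    labels=None,
    window_ids=None,
) -> list[TensorSample]:
    """Build the per-window (T=2, N, H, W, 1) model inputs.

    Placement is by electrode name, so channel order in the block is
    irrelevant. Requires both 3-s steps to be present.
    """
    w, s, f, _ = block.values.shape
    if s != 2:
        raise ValueError(f"expected 2 steps per window, got {s}")
    z = apply_scaler(block, layout, stats)  # (w, 2, f, H, W)
    data = z[..., None]  # single input channel
    if labels is None:
        labels = np.zeros(w, dtype=int)
    if window_ids is None:
        window_ids = np.arange(w)
    return [
        TensorSample(data[i], int(labels[i]), int(window_ids[i])) for i in range(w)
    ]


def stack_samples(samples: list[TensorSample]) -> tuple[np.ndarray, np.ndarray]:
    """(n, T, N, H, W, 1) array plus label vector."""
    X = np.stack([s.data for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    return X, y
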