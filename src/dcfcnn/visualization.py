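"""Feature-map capture from the multiscale stem and tiled grid rendering.

Maps are captured with read-only hooks on a single forward pass in
evaluation mode; capturing never perturbs subsequent predictions. Grids
render each map independently min-max normalised to [0, 255] (constant maps
become mid-gray), tiled row-major with ``ceil(n_channels / columns)`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .architecture import DCFCNN
from .exceptions import DataError, UnknownUnitError

__all__ = ["FeatureMapStack", "extract_feature_maps", "render_grid", "save_grid"]


@dataclass
class FeatureMapStack:
    """Activations of one unit: (C, H, W) maps plus provenance."""

    unit: str
    maps: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 3:
            raise DataError(f"expected (C, H, W) maps, got {self.maps.shape}")

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]


def extract_feature_maps(model: DCFCNN, image: np.ndarray,
                         unit_names) -> list[FeatureMapStack]:
    """Capture the named units' activations for one preprocessed image.

    ``image`` is (3, H, W) or (1, 3, H, W); valid unit names come from
    ``model.capture_points()`` (the four MSF paths, the fused MSF output and
    the branch-fusion node).
    """
    valid = model.capture_points()
    names = list(unit_names)
    for n in names:
        if n not in valid:
            raise UnknownUnitError(n, valid)
    x = np.asarray(image)
    if x.ndim == 3:
        x = x[None]
    capture = {n: None for n in names}
    model.forward(x, training=False, capture=capture)
    stacks = []
    for n in names:
        maps = capture[n]
        if maps is None:  # pragma: no cover - guarded by capture_points
            raise UnknownUnitError(n, valid)
        stacks.append(FeatureMapStack(unit=n, maps=maps[0]))
    return stacks


def render_grid(stack: FeatureMapStack, columns: int = 8,
                per_map_norm: bool = True, gap: int = 2) -> np.ndarray:
    """Tile a stack into one uint8 grayscale grid image.

    Each map is min-max scaled to [0, 255] (per map by default, globally
    over the stack otherwise); zero-range maps render as mid-gray 128.
    """
    if stack.n_channels == 0:
        raise DataError("empty feature-map stack")
    if columns < 1:
        raise DataError("columns must be >= 1")
    maps = stack.maps.astype(np.float64)
    c, h, w = maps.shape
    if not per_map_norm:
        gmin, gmax = maps.min(), maps.max()
    tiles = []
    for m in maps:
        lo, hi = (m.min(), m.max()) if per_map_norm else (gmin, gmax)
        if hi - lo < 1e-12:
            tiles.append(np.full((h, w), 128, dtype=np.uint8))
        else:
            tiles.append(np.rint((m - lo) / (hi - lo) * 255.0).astype(np.uint8))
    rows = -(-c // columns)  # ceil
    grid = np.full((rows * h + gap * (rows - 1),
                    columns * w + gap * (columns - 1)), 0, dtype=np.uint8)
    for i, tile in enumerate(tiles):
        r, col = divmod(i, columns)
        y0, x0 = r * (h + gap), col * (w + gap)
        grid[y0:y0 + h, x0:x0 + w] = tile
    return grid


def save_grid(stack: FeatureMapStack, path, columns: int = 8,
              per_map_norm: bool = True) -> Path:
    """Render and write one grid PNG; returns the written path."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(render_grid(stack, columns=columns,
                                per_map_norm=per_map_norm)).save(out)
    return out
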