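"""PNG heatmap rendering of lattice states.

Fixed two-channel convention: sensitive population on the green channel,
antagonist on the red channel, composite as their overlay (so mixed
compartments render yellow).  Purely cosmetic output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .lattice import LatticeState

__all__ = ["render_layer", "render_composite", "save_state_pngs"]

_SCALE = 8  # nearest-neighbor upscale so 51x51 grids are legible


def _to_channel(grid: np.ndarray) -> np.ndarray:
    return (np.clip(np.asarray(grid, dtype=float), 0.0, 1.0) * 255).astype(np.uint8)


def render_layer(grid: np.ndarray, channel: str) -> Image.Image:
    """Single-layer image on the green ('s') or red ('a') channel."""
    v = _to_channel(grid)
    rgb = np.zeros((*v.shape, 3), dtype=np.uint8)
    rgb[..., 1 if channel == "s" else 0] = v
    img = Image.fromarray(rgb, mode="RGB")
    return img.resize((v.shape[1] * _SCALE, v.shape[0] * _SCALE), Image.NEAREST)


def render_composite(state: LatticeState) -> Image.Image:
    """Both strains in one image: sensitive green, antagonist red."""
    rgb = np.zeros((*state.shape, 3), dtype=np.uint8)
    rgb[..., 0] = _to_channel(state.a)
    rgb[..., 1] = _to_channel(state.s)
    img = Image.fromarray(rgb, mode="RGB")
    return img.resize(
        (state.shape[1] * _SCALE, state.shape[0] * _SCALE), Image.NEAREST
    )


def save_state_pngs(state: LatticeState, out_dir: str | Path, stem: str) -> list[str]:
    """Write sensitive, antagonist and composite PNGs; return file names."""
    out_dir = Path(out_dir)
    names = []
    for suffix, img in (
        ("sensitive", render_layer(state.s, "s")),
        ("antagonist", render_layer(state.a, "a")),
        ("composite", render_composite(state)),
    ):
        name = f"{stem}_{suffix}.png"
        img.save(out_dir / name)
        names.append(name)
    return names
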