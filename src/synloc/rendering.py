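"""LI visualization: membrane signal color-coded by localization index.

The display encodes two quantities per pixel: the LI picks the color from
a diverging colormap whose midpoint is pinned at LI = 1 (so red means
local enrichment, blue depletion with the default map), and the membrane
brightness scales the color's intensity, so dim membrane regions fade to
black instead of shouting unreliable ratios.  Censored voxels are black.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps
from matplotlib.colors import TwoSlopeNorm

from .li_core import LIMap
from .volume_io import Volume

__all__ = ["RenderSpec", "render_li_overlay", "save_render"]


@dataclass
class RenderSpec:
    """Display parameters for the LI overlay.

    li_range clips the color scale; it must bracket 1 so the midpoint is
    meaningful.  The default (0.5, 2.0) puts symmetric fold-changes at
    symmetric distances from the midpoint only approximately — it is a
    linear scale chosen for simplicity, recorded in output metadata.
    intensity_gamma shapes the brightness response to membrane signal.
    """

    colormap: str = "coolwarm"
    li_range: tuple[float, float] = (0.5, 2.0)
    intensity_gamma: float = 1.0
    projection: Literal["single_slice", "max_intensity"] = "single_slice"

    def __post_init__(self) -> None:
        lo, hi = self.li_range
        if not lo < 1.0 < hi:
            raise ValueError(f"li_range must bracket 1 (lo < 1 < hi), got {self.li_range}")
        if self.intensity_gamma <= 0:
            raise ValueError(f"intensity_gamma must be > 0, got {self.intensity_gamma}")


def _select_plane(
    limap: LIMap,
    membrane: np.ndarray,
    spec: RenderSpec,
    axis: int,
    index: int | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick the (li, membrane, valid) 2D fields to display."""
    if spec.projection == "single_slice":
        if index is None:
            index = limap.li.shape[axis] // 2
        sl = [slice(None)] * 3
        sl[axis] = index
        sl = tuple(sl)
        return limap.li[sl], membrane[sl], limap.valid[sl]
    # max-intensity projection: the membrane channel picks the displayed
    # voxel along each ray and its LI rides along.
    arg = np.argmax(membrane, axis=axis)
    idx = np.expand_dims(arg, axis=axis)
    take = lambda a: np.take_along_axis(a, idx, axis=axis).squeeze(axis)
    return take(limap.li), take(membrane), take(limap.valid)


def render_li_overlay(
    limap: LIMap,
    volume: Volume,
    membrane_channel: str = "membrane",
    spec: RenderSpec | None = None,
    axis: int = 0,
    index: int | None = None,
) -> np.ndarray:
    """Render an RGB image (floats in [0, 1]) of LI-colored membrane.

    A pure function of its inputs: identical arguments give identical
    images.  ``axis``/``index`` select the slice (or the projection axis
    for ``spec.projection="max_intensity"``, in which case ``index`` is
    ignored).
    """
    spec = spec or RenderSpec()
    membrane = volume.channel(membrane_channel)
    if membrane.shape != limap.li.shape:
        raise ValueError("LI map and volume shapes differ")
    if not limap.valid.any():
        raise ValueError("LI map has no valid voxels; nothing to render")

    li2d, mem2d, valid2d = _select_plane(limap, membrane, spec, axis, index)

    lo, hi = spec.li_range
    norm = TwoSlopeNorm(vmin=lo, vcenter=1.0, vmax=hi)
    cmap = colormaps[spec.colormap]
    li_clipped = np.clip(np.where(valid2d, li2d, 1.0), lo, hi)
    colors = cmap(norm(li_clipped))[..., :3]

    mem_max = membrane.max()
    brightness = np.zeros_like(mem2d)
    if mem_max > 0:
        brightness = (mem2d / mem_max) ** spec.intensity_gamma
    rgb = colors * brightness[..., None]
    rgb[~valid2d] = 0.0
    return rgb


def save_render(path, rgb: np.ndarray) -> None:
    """Write an RGB float image in [0, 1] as 8-bit PNG/TIFF."""
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8))
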