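"""Render per-region scores onto atlas voxels.

Maps a score per region (a correlation with a focal region, a lasso
coefficient, a bootstrap selection frequency, ...) onto the atlas masks as
an RGB overlay stack plus a z maximum-intensity projection.  The default
scheme is a sequential blue ramp for scored regions with the focal region
drawn in a reserved red, so the focal candidate is visually distinct from
the regions that merely correlate with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import RegionAtlas
from .errors import UnknownRegionError, ValidationError

__all__ = ["RegionScoreMap", "render_region_stack", "save_render"]

_FOCAL_RGB = (220, 30, 30)


@dataclass
class RegionScoreMap:
    """Finite score per region, an optional focal region, and a color ramp.

    ``vmin``/``vmax`` default to the score range; ``cmap`` is any matplotlib
    colormap name (sequential 'Blues' by default).  The focal region is not
    part of the ramp — it gets the reserved highlight color.
    """

    scores: dict
    focal: str | None = None
    vmin: float | None = None
    vmax: float | None = None
    cmap: str = "Blues"

    def __post_init__(self) -> None:
        if not self.scores and self.focal is None:
            raise ValidationError("empty score map")
        vals = np.asarray(list(self.scores.values()), dtype=np.float64)
        if vals.size and not np.isfinite(vals).all():
            raise ValidationError("scores must be finite")
        self.scores = {k: float(v) for k, v in self.scores.items() if k != self.focal}

    def ramp_limits(self) -> tuple[float, float]:
        vals = list(self.scores.values())
        lo = self.vmin if self.vmin is not None else (min(vals) if vals else 0.0)
        hi = self.vmax if self.vmax is not None else (max(vals) if vals else 1.0)
        if hi <= lo:
            hi = lo + 1.0
        return lo, hi


def render_region_stack(
    atlas: RegionAtlas, scores: RegionScoreMap
) -> tuple[np.ndarray, np.ndarray]:
    """Paint scored regions onto the atlas space.

    Returns ``(stack, projection)``: an RGB uint8 volume ``(z, y, x, 3)``
    and its z maximum projection ``(y, x, 3)``.  Where masks overlap the
    higher-scoring region wins; the focal region (if any) is always painted
    on top in the reserved highlight color.  Pure function of its inputs.
    """
    from matplotlib import colormaps

    for rid in list(scores.scores) + ([scores.focal] if scores.focal else []):
        atlas.region(rid)  # raises UnknownRegionError
    cmap = colormaps[scores.cmap]
    lo, hi = scores.ramp_limits()
    stack = np.zeros(atlas.shape + (3,), dtype=np.uint8)
    flat = stack.reshape(-1, 3)
    # ascending score order so higher scores overwrite lower on shared voxels
    for rid, score in sorted(scores.scores.items(), key=lambda t: t[1]):
        frac = (score - lo) / (hi - lo)
        rgb = (np.asarray(cmap(float(np.clip(frac, 0.0, 1.0)))[:3]) * 255).astype(np.uint8)
        flat[atlas.region(rid).indices] = rgb
    if scores.focal is not None:
        flat[atlas.region(scores.focal).indices] = _FOCAL_RGB
    projection = stack.max(axis=0)
    return stack, projection


def save_render(
    stack: np.ndarray, projection: np.ndarray, stack_path, projection_path
) -> None:
    """Write the overlay as multi-page TIFF and the projection as PNG."""
    import tifffile
    from matplotlib import image as mpl_image

    tifffile.imwrite(stack_path, stack)
    mpl_image.imsave(projection_path, projection)
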