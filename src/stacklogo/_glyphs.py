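"""Letter glyph outlines as normalized vector paths.

Glyphs are taken once from the DejaVu Sans Bold outline that ships with
matplotlib, normalized to the unit box (y up), and then stretched
non-uniformly into each stack cell.  Working with path outlines rather
than text elements keeps both the SVG and the rasterized output free of
text-metric nondeterminism.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.path import Path
from matplotlib.textpath import TextPath

_FONT = FontProperties(family="DejaVu Sans", weight="bold")


@lru_cache(maxsize=64)
def glyph_outline(letter: str) -> tuple[np.ndarray, np.ndarray]:
    """(vertices, codes) of ``letter`` normalized to the unit box, y up."""
    tp = TextPath((0, 0), letter, size=100.0, prop=_FONT)
    verts = np.asarray(tp.vertices, float).copy()
    codes = np.asarray(tp.codes, np.uint8).copy()
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    verts = (verts - lo) / span
    return verts, codes


def glyph_svg_path(letter: str, x: float, y_top: float, w: float, h: float) -> str:
    """SVG path data for ``letter`` filling the rect (x, y_top, w, h).

    SVG's y axis points down, so the normalized y-up outline is flipped:
    X = x + u*w, Y = y_top + (1 - v)*h.
    """
    verts, codes = glyph_outline(letter)
    X = x + verts[:, 0] * w
    Y = y_top + (1.0 - verts[:, 1]) * h
    parts: list[str] = []
    i = 0
    n = len(codes)
    while i < n:
        c = codes[i]
        if c == Path.MOVETO:
            parts.append(f"M{X[i]:.3f},{Y[i]:.3f}")
            i += 1
        elif c == Path.LINETO:
            parts.append(f"L{X[i]:.3f},{Y[i]:.3f}")
            i += 1
        elif c == Path.CURVE3:
            parts.append(f"Q{X[i]:.3f},{Y[i]:.3f} {X[i+1]:.3f},{Y[i+1]:.3f}")
            i += 2
        elif c == Path.CURVE4:
            parts.append(
                f"C{X[i]:.3f},{Y[i]:.3f} {X[i+1]:.3f},{Y[i+1]:.3f} {X[i+2]:.3f},{Y[i+2]:.3f}"
            )
            i += 3
        elif c == Path.CLOSEPOLY:
            parts.append("Z")
            i += 1
        else:  # pragma: no cover - DejaVu outlines only use the codes above
            i += 1
    return "".join(parts)


def glyph_mpl_path(letter: str, x: float, y_top: float, w: float, h: float) -> Path:
    """Matplotlib Path for the same cell, in a y-down pixel coordinate frame."""
    verts, codes = glyph_outline(letter)
    out = np.empty_like(verts)
    out[:, 0] = x + verts[:, 0] * w
    out[:, 1] = y_top + (1.0 - verts[:, 1]) * h
    return Path(out, codes.astype(np.uint8))
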