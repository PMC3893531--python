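"""Logo serialization (JSON document) and static rendering (SVG / PNG).

The JSON document is the seam for interactive viewers: it carries, for every
position, the drawn stack *and* the full per-letter probability and score
vectors, so a click-to-inspect widget can be built on top of it without
re-deriving anything.  The SVG renderer draws uniform-width letter stacks
with a value table underneath: occupancy (blue shading, stronger = lower
occupancy) and, for profile logos, insert probability and expected insert
length (red shading, stronger = higher).  A non-white insert-probability
cell also produces a thin matching red bar immediately after its stack.
The overview renderer compresses letters into colored bars so hundreds of
positions fit one panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._glyphs import glyph_mpl_path, glyph_svg_path
from .alignment_io import Alphabet
from .errors import LogoError
from .logo_core import NEG_INF, Logo, LogoPosition

DOCUMENT_VERSION = "stacklogo-1"

NUCLEOTIDE_COLORS = {
    "A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839", "U": "#d62839",
}
# amino colors keyed by physicochemistry: hydrophobic black, polar green,
# basic blue, acidic red, aromatic purple, special-cases olive/orange
AMINO_COLORS = {
    "A": "#33322e", "V": "#33322e", "L": "#33322e", "I": "#33322e", "M": "#33322e",
    "S": "#109648", "T": "#109648", "N": "#109648", "Q": "#109648",
    "K": "#255c99", "R": "#255c99", "H": "#4a7db5",
    "D": "#d62839", "E": "#d62839",
    "F": "#8d5a97", "W": "#8d5a97", "Y": "#8d5a97",
    "C": "#c5a14e", "G": "#e07020", "P": "#e07020",
}

_BLUE = (33, 102, 172)
_RED = (178, 24, 43)


@dataclass(frozen=True)
class StyleOptions:
    """Rendering knobs: geometry in pixels, colors, heat-map cap."""

    stack_width: float = 28.0
    stack_height: float = 170.0
    y_max: float | None = None
    letter_colors: dict[str, str] | None = None
    insert_len_cap: float = 10.0
    margin_left: float = 46.0
    margin_right: float = 12.0
    margin_top: float = 12.0
    row_height: float = 16.0
    overview_bar_width: float = 3.0

    def colors_for(self, alphabet: Alphabet) -> dict[str, str]:
        base = NUCLEOTIDE_COLORS if alphabet.kind in ("dna", "rna") else AMINO_COLORS
        merged = dict(base)
        if self.letter_colors:
            merged.update(self.letter_colors)
        return merged

    @classmethod
    def from_file(cls, handle) -> "StyleOptions":
        """Read a small ``key = value`` style file; ``color.X`` sets a letter color."""
        kwargs: dict = {}
        colors: dict[str, str] = {}
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("color."):
                colors[key[6:].upper()] = value
            elif key in ("stack_width", "stack_height", "y_max", "insert_len_cap",
                         "row_height", "overview_bar_width"):
                kwargs[key] = float(value)
            else:
                raise LogoError(f"unknown style key {key!r}")
        if colors:
            kwargs["letter_colors"] = colors
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# heat map


def heatmap_color(value: float, channel: str) -> str:
    """Hex cell color for the gap-parameter table.

    ``occupancy`` runs saturated blue (0) to white (1); ``insert_prob``
    white (0) to saturated red (1); ``insert_len`` white (length 1) to red
    (length >= cap, default 10).  Values outside the domain are clamped.
    """
    if channel == "occupancy":
        t = 1.0 - min(max(value, 0.0), 1.0)
        base = _BLUE
    elif channel == "insert_prob":
        t = min(max(value, 0.0), 1.0)
        base = _RED
    elif channel == "insert_len":
        t = min(max((value - 1.0) / 9.0, 0.0), 1.0)
        base = _RED
    else:
        raise ValueError(f"unknown heat-map channel {channel!r}")
    rgb = tuple(round(255 + (b - 255) * t) for b in base)
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _heatmap_color_len(value: float, cap: float) -> str:
    t = min(max((value - 1.0) / max(cap - 1.0, 1e-9), 0.0), 1.0)
    rgb = tuple(round(255 + (b - 255) * t) for b in _RED)
    return "#{:02x}{:02x}{:02x}".format(*rgb)


# ---------------------------------------------------------------------------
# JSON document


def _num(x: float) -> float:
    # canonical float: parsing and re-serializing reproduces the same bytes
    return float(format(float(x), ".12g"))


def _score_json(s: float) -> float | None:
    return None if s == NEG_INF else _num(s)


def to_document(logo: Logo) -> dict:
    """The logo as a plain JSON-ready dict (deterministic key order)."""
    positions = []
    for pos in logo.positions:
        entry: dict = {
            "k": int(pos.position),
            "source_column": int(pos.source_column),
            "info_content": _num(pos.info_content),
            "occupancy": _num(pos.occupancy),
        }
        if pos.insert_probability is not None:
            entry["insert_probability"] = _num(pos.insert_probability)
        if pos.expected_insert_length is not None:
            entry["expected_insert_length"] = _num(pos.expected_insert_length)
        entry["stack"] = [[a, _num(h)] for a, h in pos.stack]
        entry["probs"] = {a: _num(p) for a, p in zip(logo.alphabet.letters,
                                                     pos.full_distribution)}
        entry["scores"] = {a: _score_json(s) for a, s in zip(logo.alphabet.letters,
                                                             pos.scores)}
        positions.append(entry)
    return {
        "version": DOCUMENT_VERSION,
        "alphabet_kind": logo.alphabet.kind,
        "alphabet": list(logo.alphabet.letters),
        "height_mode": logo.height_mode,
        "processing": logo.processing,
        "max_height": _num(logo.max_height),
        "background": [_num(q) for q in logo.background],
        "positions": positions,
    }


def to_json(logo: Logo) -> str:
    """Serialize ``logo`` to its JSON document (deterministic bytes)."""
    return json.dumps(to_document(logo), separators=(",", ":"), allow_nan=False)


def validate_document(doc: dict) -> None:
    """Structural check of a logo document; raises LogoError on problems."""
    required = ("version", "alphabet_kind", "alphabet", "height_mode",
                "processing", "max_height", "background", "positions")
    for key in required:
        if key not in doc:
            raise LogoError(f"logo document missing key {key!r}")
    if doc["version"] != DOCUMENT_VERSION:
        raise LogoError(f"unsupported document version {doc['version']!r}")
    letters = doc["alphabet"]
    for entry in doc["positions"]:
        for key in ("k", "source_column", "info_content", "occupancy",
                    "stack", "probs", "scores"):
            if key not in entry:
                raise LogoError(f"position entry missing key {key!r}")
        if set(entry["probs"]) != set(letters) or set(entry["scores"]) != set(letters):
            raise LogoError("probs/scores must cover the full alphabet")


def from_json(text: str) -> Logo:
    """Rebuild a :class:`Logo` from its JSON document."""
    doc = json.loads(text)
    validate_document(doc)
    background = np.array(doc["background"], float)
    alphabet = Alphabet.from_kind(doc["alphabet_kind"], background)
    positions = []
    for entry in doc["positions"]:
        scores = np.array(
            [NEG_INF if entry["scores"][a] is None else entry["scores"][a]
             for a in alphabet.letters]
        )
        positions.append(LogoPosition(
            position=entry["k"],
            stack=[(a, h) for a, h in entry["stack"]],
            info_content=entry["info_content"],
            occupancy=entry["occupancy"],
            source_column=entry["source_column"],
            full_distribution=np.array([entry["probs"][a] for a in alphabet.letters]),
            scores=scores,
            insert_probability=entry.get("insert_probability"),
            expected_insert_length=entry.get("expected_insert_length"),
        ))
    return Logo(
        positions=positions,
        alphabet=alphabet,
        height_mode=doc["height_mode"],
        processing=doc["processing"],
        max_height=doc["max_height"],
        background=background,
    )


# ---------------------------------------------------------------------------
# drawing primitives (shared by the SVG writer and the PNG painter)


@dataclass(frozen=True)
class _Rect:
    x: float; y: float; w: float; h: float
    fill: str
    stroke: str | None = None
    cls: str | None = None


@dataclass(frozen=True)
class _Line:
    x1: float; y1: float; x2: float; y2: float
    color: str = "#222222"
    width: float = 1.0


@dataclass(frozen=True)
class _Glyph:
    letter: str; x: float; y: float; w: float; h: float
    fill: str


@dataclass(frozen=True)
class _Text:
    x: float; y: float; s: str
    size: float = 9.0
    anchor: str = "middle"
    color: str = "#222222"
    rotate: float | None = None


@dataclass(frozen=True)
class _Group:
    cls: str
    items: tuple


def _fmt_pct(v: float) -> str:
    pct = v * 100.0
    if pct >= 99.5:
        return "100%"
    return f"{format(pct, '.2g')}%"


def _fmt_len(v: float) -> str:
    return format(v, ".2g")


def _axis_max(logo: Logo, style: StyleOptions) -> float:
    if style.y_max is not None:
        return style.y_max
    if logo.height_mode == "score":
        tallest = max((p.stack_height for p in logo.positions), default=1.0)
        return max(tallest, 1e-6)
    return logo.max_height


def _layout(logo: Logo, style: StyleOptions, start: int = 1,
            end: int | None = None) -> tuple[list, float, float]:
    """Primitive list plus canvas size for the detailed logo drawing."""
    if not logo.positions:
        raise LogoError("cannot render a logo with zero positions")
    if end is None:
        end = len(logo.positions)
    positions = logo.positions[start - 1:end]
    colors = style.colors_for(logo.alphabet)
    sw, sh = style.stack_width, style.stack_height
    ml, mt = style.margin_left, style.margin_top
    rh = style.row_height
    axis_max = _axis_max(logo, style)
    scale = sh / axis_max
    y_base = mt + sh

    rows: list[str] = ["occupancy"]
    if logo.is_profile:
        rows += ["insert_prob", "insert_len"]

    prims: list = []
    width = ml + len(positions) * sw + style.margin_right
    height = y_base + len(rows) * rh + rh + 6

    # y axis
    axis_label = "score (bits)" if logo.height_mode == "score" else "bits"
    prims.append(_Line(ml - 4, mt, ml - 4, y_base))
    for frac in (0.0, 0.5, 1.0):
        yv = y_base - frac * sh
        prims.append(_Line(ml - 8, yv, ml - 4, yv))
        prims.append(_Text(ml - 10, yv + 3, format(frac * axis_max, ".3g"),
                           size=8.0, anchor="end"))
    prims.append(_Text(12, y_base - sh / 2, axis_label, size=9.0,
                       anchor="middle", rotate=-90))

    for i, pos in enumerate(positions):
        x = ml + i * sw
        glyphs = []
        cum = 0.0
        for letter, h in pos.stack:
            gh = h * scale
            if gh > 0:
                y_top = y_base - cum - gh
                gx = x + sw * 0.07
                glyphs.append(_Glyph(letter, gx, y_top, sw * 0.86, gh,
                                     colors.get(letter, "#555555")))
            cum += gh
        prims.append(_Group(cls="stack", items=tuple(glyphs)))

        # gap-parameter table cells
        for r, row in enumerate(rows):
            cy = y_base + r * rh
            if row == "occupancy":
                fill = heatmap_color(pos.occupancy, "occupancy")
                label = _fmt_pct(pos.occupancy)
            elif row == "insert_prob":
                fill = heatmap_color(pos.insert_probability, "insert_prob")
                label = _fmt_pct(pos.insert_probability)
            else:
                fill = _heatmap_color_len(pos.expected_insert_length,
                                          style.insert_len_cap)
                label = _fmt_len(pos.expected_insert_length)
            prims.append(_Rect(x, cy, sw, rh, fill=fill, stroke="#dddddd",
                               cls=f"gapcell {row}"))
            prims.append(_Text(x + sw / 2, cy + rh - 4.5, label, size=7.5))

        # a non-white insert cell gets a thin matching bar after the stack
        if logo.is_profile and pos.insert_probability > 0.0:
            bar_fill = heatmap_color(pos.insert_probability, "insert_prob")
            prims.append(_Rect(x + sw - 1.5, mt, 3.0, sh, fill=bar_fill,
                               cls="insert-bar"))

        prims.append(_Text(x + sw / 2, y_base + len(rows) * rh + rh - 4,
                           str(pos.position), size=8.0))
    return prims, width, height


def _overview_layout(logo: Logo, start: int, end: int,
                     style: StyleOptions) -> tuple[list, float, float]:
    if not 1 <= start <= end <= len(logo.positions):
        raise LogoError(
            f"overview range {start}..{end} outside logo positions 1..{len(logo.positions)}"
        )
    colors = style.colors_for(logo.alphabet)
    bw = style.overview_bar_width
    sh = style.stack_height
    mt = 4.0
    axis_max = _axis_max(logo, style)
    scale = sh / axis_max
    prims: list = []
    for i, pos in enumerate(logo.positions[start - 1:end]):
        x = 4.0 + i * (bw + 1.0)
        cum = 0.0
        bars = []
        for letter, h in pos.stack:
            bh = h * scale
            if bh > 0:
                bars.append(_Rect(x, mt + sh - cum - bh, bw, bh,
                                  fill=colors.get(letter, "#555555"), cls="bar"))
            cum += bh
        prims.append(_Group(cls="stack", items=tuple(bars)))
    width = 8.0 + (end - start + 1) * (bw + 1.0)
    return prims, width, mt + sh + 4.0


# ---------------------------------------------------------------------------
# SVG writer


def _svg_of(prim) -> str:
    if isinstance(prim, _Group):
        inner = "".join(_svg_of(p) for p in prim.items)
        return f'<g class="{prim.cls}">{inner}</g>'
    if isinstance(prim, _Rect):
        cls = f' class="{prim.cls}"' if prim.cls else ""
        stroke = f' stroke="{prim.stroke}"' if prim.stroke else ""
        return (f'<rect{cls} x="{prim.x:.2f}" y="{prim.y:.2f}" width="{prim.w:.2f}"'
                f' height="{prim.h:.2f}" fill="{prim.fill}"{stroke}/>')
    if isinstance(prim, _Line):
        return (f'<line x1="{prim.x1:.2f}" y1="{prim.y1:.2f}" x2="{prim.x2:.2f}"'
                f' y2="{prim.y2:.2f}" stroke="{prim.color}" stroke-width="{prim.width}"/>')
    if isinstance(prim, _Glyph):
        d = glyph_svg_path(prim.letter, prim.x, prim.y, prim.w, prim.h)
        return f'<path class="letter letter-{prim.letter}" d="{d}" fill="{prim.fill}"/>'
    if isinstance(prim, _Text):
        transform = ""
        if prim.rotate is not None:
            transform = f' transform="rotate({prim.rotate:g} {prim.x:.2f} {prim.y:.2f})"'
        anchor = {"start": "start", "middle": "middle", "end": "end"}[prim.anchor]
        return (f'<text x="{prim.x:.2f}" y="{prim.y:.2f}" font-family="DejaVu Sans,sans-serif"'
                f' font-size="{prim.size:g}" text-anchor="{anchor}"'
                f' fill="{prim.color}"{transform}>{prim.s}</text>')
    raise TypeError(f"unknown primitive {prim!r}")


def _svg_text(prims: list, width: float, height: float) -> str:
    body = "".join(_svg_of(p) for p in prims)
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.0f}" height="{height:.0f}" '
        f'viewBox="0 0 {width:.0f} {height:.0f}">'
        f'<rect x="0" y="0" width="{width:.0f}" height="{height:.0f}" fill="#ffffff"/>'
        f"{body}</svg>"
    )


def to_svg(logo: Logo, style: StyleOptions | None = None) -> str:
    """Render the full logo (stacks + gap table + position numbers) as SVG."""
    style = style or StyleOptions()
    prims, w, h = _layout(logo, style)
    return _svg_text(prims, w, h)


def overview_svg(logo: Logo, start: int = 1, end: int | None = None,
                 style: StyleOptions | None = None) -> str:
    """Compressed overview: each letter becomes a thin colored bar, no text."""
    style = style or StyleOptions()
    if end is None:
        end = len(logo.positions)
    prims, w, h = _overview_layout(logo, start, end, style)
    return _svg_text(prims, w, h)


# ---------------------------------------------------------------------------
# PNG painter (same primitives, drawn with matplotlib's Agg canvas)


def _paint(prims, ax) -> None:
    import matplotlib.patches as mpatches

    for prim in prims:
        if isinstance(prim, _Group):
            _paint(prim.items, ax)
        elif isinstance(prim, _Rect):
            ax.add_patch(mpatches.Rectangle(
                (prim.x, prim.y), prim.w, prim.h, facecolor=prim.fill,
                edgecolor=prim.stroke or "none", linewidth=0.5))
        elif isinstance(prim, _Line):
            ax.plot([prim.x1, prim.x2], [prim.y1, prim.y2],
                    color=prim.color, linewidth=prim.width)
        elif isinstance(prim, _Glyph):
            path = glyph_mpl_path(prim.letter, prim.x, prim.y, prim.w, prim.h)
            ax.add_patch(mpatches.PathPatch(path, facecolor=prim.fill,
                                            edgecolor="none"))
        elif isinstance(prim, _Text):
            ha = {"start": "left", "middle": "center", "end": "right"}[prim.anchor]
            ax.text(prim.x, prim.y, prim.s, fontsize=prim.size, ha=ha,
                    va="baseline", color=prim.color,
                    rotation=prim.rotate or 0, rotation_mode="anchor")


def _png_from_prims(prims, width: float, height: float, path, dpi: int = 100) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(width / dpi, height / dpi), dpi=dpi)
    ax = fig.add_axes((0, 0, 1, 1))
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # pixel frame: y grows downward, as in SVG
    ax.axis("off")
    ax.add_patch(__import__("matplotlib.patches", fromlist=["Rectangle"]).Rectangle(
        (0, 0), width, height, facecolor="#ffffff", edgecolor="none"))
    _paint(prims, ax)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def to_png(logo: Logo, path, style: StyleOptions | None = None, dpi: int = 100) -> None:
    """Rasterize the detailed logo; pixel size equals the SVG's declared size."""
    style = style or StyleOptions()
    prims, w, h = _layout(logo, style)
    _png_from_prims(prims, round(w), round(h), path, dpi=dpi)


def overview_png(logo: Logo, path, start: int = 1, end: int | None = None,
                 style: StyleOptions | None = None, dpi: int = 100) -> None:
    style = style or StyleOptions()
    if end is None:
        end = len(logo.positions)
    prims, w, h = _overview_layout(logo, start, end, style)
    _png_from_prims(prims, round(w), round(h), path, dpi=dpi)
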