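"""Deterministic geometry for the four comparison views.

All four views share the same per-variant visual encoding: color is the
display impact (pathogenic red, benign gray, protective blue,
pharmacogenetic purple) with a polka-dot pattern overlaid for carrier
status, and glyph size is rarity -- the rarer the allele, the larger the
arc/rectangle/bubble.

The sunburst and linear views allocate one *global slot* per distinct
variant, ordered shared-first (the comparison's class order) and sized
proportionally to rarity, with a uniform gap between slots. A glyph is then
emitted in every ring/row whose person carries the variant, at the
variant's global slot, so shared variants line up radially/vertically.

Everything here is pure geometry on normalized units; :func:`render_svg`
turns a layout into a standalone, byte-deterministic SVG document.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Mapping, Sequence
from xml.sax.saxutils import escape

from .errors import ArityError, IdentityError
from .models import (
    BaseImpact,
    Certainty,
    ComparisonReport,
    DisplayImpact,
    VariantKey,
)

__all__ = [
    "StyleKey",
    "Arc",
    "Rect",
    "VennBubble",
    "TableRow",
    "style_for",
    "sunburst_layout",
    "linear_layout",
    "venn_layout",
    "table_view",
    "render_svg",
    "layout_to_json",
    "DEFAULT_GAP_FRACTION",
]

#: Gap between adjacent slots, as a fraction of the mean slot width.
DEFAULT_GAP_FRACTION = 0.2

_COLOR_FOR_IMPACT = {
    DisplayImpact.PATHOGENIC: "red",
    DisplayImpact.BENIGN: "gray",
    DisplayImpact.PROTECTIVE: "blue",
    DisplayImpact.PHARMACOGENETIC: "purple",
    DisplayImpact.CARRIER: "red",  # carrier keeps the pathogenic hue
}

_SVG_FILL = {"red": "#c62828", "gray": "#9e9e9e", "blue": "#1565c0", "purple": "#6a1b9a"}


@dataclass(frozen=True)
class StyleKey:
    """Fill color plus the carrier polka-dot flag."""

    color: str
    pattern: bool = False


@dataclass(frozen=True)
class Arc:
    """One sunburst glyph: an angular interval on one person's ring."""

    ring_index: int  # 0 = outermost
    start_angle: float  # degrees
    extent: float  # degrees, > 0
    style: StyleKey
    key: VariantKey


@dataclass(frozen=True)
class Rect:
    """One linear-view glyph: an x interval on one person's row."""

    row_index: int  # 0 = top
    x_offset: float  # normalized [0, 1)
    width: float  # normalized, > 0
    height: float  # normalized
    style: StyleKey
    key: VariantKey


@dataclass(frozen=True)
class VennBubble:
    """One two-set Venn glyph: a circle in its membership region."""

    region: str  # left_only | shared | right_only
    cx: float
    cy: float
    radius: float
    style: StyleKey
    key: VariantKey


@dataclass(frozen=True)
class TableRow:
    """One tabular-report row: variant fields plus a per-person mark."""

    variant_name: str
    category: str
    impact: BaseImpact
    certainty: Certainty
    allele_frequency: float
    effect_summary: str
    marks: Mapping[str, str]  # person_id -> present | carrier | absent
    key: VariantKey


def style_for(display_impact: DisplayImpact) -> StyleKey:
    """Visual style of a display impact: color plus carrier dot pattern."""
    display_impact = DisplayImpact(display_impact)
    return StyleKey(
        color=_COLOR_FOR_IMPACT[display_impact],
        pattern=display_impact is DisplayImpact.CARRIER,
    )


def _slot_table(
    cmp: ComparisonReport, gap_fraction: float
) -> tuple[list[tuple[VariantKey, float, float, tuple[str, ...], Mapping]], float]:
    """Global slots in class order, in abstract units.

    Returns ``(slots, gap)`` where each slot is (key, start, extent,
    signature, per_person) and ``gap`` is the uniform inter-slot gap, all in
    the same abstract units; slots + gaps total ``total_units =
    sum(sizes) * (1 + gap_fraction)``.
    """
    items = list(cmp.entries())
    slots = []
    if not items:
        return slots, 0.0
    sizes = [next(iter(e.per_person.values())).rarity_size for _, e in items]
    gap = gap_fraction * (sum(sizes) / len(sizes))
    cursor = 0.0
    for (sig, entry), size in zip(items, sizes):
        slots.append((entry.key, cursor, size, sig, entry.per_person))
        cursor += size + gap
    return slots, gap


def _slot_scale(slots, gap: float) -> float:
    """Total abstract units spanned by slots + trailing gaps."""
    return sum(s[2] for s in slots) + gap * len(slots)


def _check_order(order: Sequence[str], persons: tuple[str, ...], what: str):
    if sorted(order) != sorted(persons) or len(set(order)) != len(order):
        raise IdentityError(
            f"{what} must be a permutation of the compared persons"
        )


def sunburst_layout(
    cmp: ComparisonReport,
    ring_order: Sequence[str] | None = None,
    gap_fraction: float = DEFAULT_GAP_FRACTION,
) -> list[Arc]:
    """Concentric-ring layout: one full circle per person.

    Ring ``i`` (0 = outermost) belongs to ``ring_order[i]`` (default: the
    comparison's person order, first person outermost). Slots plus uniform
    gaps are normalized to total 360 degrees; an arc is emitted in every
    ring whose person carries the variant, at the variant's global slot, so
    shared variants are radially aligned.
    """
    order = tuple(ring_order) if ring_order is not None else cmp.persons
    _check_order(order, cmp.persons, "ring_order")
    ring_of = {p: i for i, p in enumerate(order)}
    slots, gap = _slot_table(cmp, gap_fraction)
    if not slots:
        return []
    unit = 360.0 / _slot_scale(slots, gap)
    arcs: list[Arc] = []
    for key, start, size, sig, per_person in slots:
        for person in sig:
            arcs.append(
                Arc(
                    ring_index=ring_of[person],
                    start_angle=start * unit,
                    extent=size * unit,
                    style=style_for(per_person[person].display_impact),
                    key=key,
                )
            )
    return arcs


def linear_layout(
    cmp: ComparisonReport,
    row_order: Sequence[str] | None = None,
    gap_fraction: float = DEFAULT_GAP_FRACTION,
) -> list[Rect]:
    """Aligned-rows layout: one horizontal row per person (0 = top).

    Each distinct variant gets one global x slot in [0, 1), shared-first,
    width proportional to rarity; a rectangle is emitted in every carrying
    person's row at that slot, so shared variants are vertically aligned.
    """
    order = tuple(row_order) if row_order is not None else cmp.persons
    _check_order(order, cmp.persons, "row_order")
    row_of = {p: i for i, p in enumerate(order)}
    slots, gap = _slot_table(cmp, gap_fraction)
    if not slots:
        return []
    unit = 1.0 / _slot_scale(slots, gap)
    height = 0.8 / len(order)  # row band is 1/N tall; rect fills 80% of it
    rects: list[Rect] = []
    for key, start, size, sig, per_person in slots:
        for person in sig:
            rects.append(
                Rect(
                    row_index=row_of[person],
                    x_offset=start * unit,
                    width=size * unit,
                    height=height,
                    style=style_for(per_person[person].display_impact),
                    key=key,
                )
            )
    return rects


_VENN_REGIONS = ("left_only", "shared", "right_only")
_VENN_BOXES = {  # (x0, y0, x1, y1) in the unit square
    "left_only": (0.0, 0.0, 1.0 / 3.0, 1.0),
    "shared": (1.0 / 3.0, 0.0, 2.0 / 3.0, 1.0),
    "right_only": (2.0 / 3.0, 0.0, 1.0, 1.0),
}


def venn_layout(cmp: ComparisonReport) -> list[VennBubble]:
    """Two-set Venn layout: left-only, shared, and right-only bubbles.

    Only defined for 2-person comparisons. Bubble radius is proportional to
    rarity with a single scale across all three regions, so radius ordering
    matches rarity ordering globally. Packing is deterministic: within each
    region, bubbles sorted by descending radius (ties by key) are placed
    row-major on a grid inscribed in the region's bounding box; the scale
    is chosen so grid cells can never produce overlapping or out-of-box
    circles.
    """
    if len(cmp.persons) != 2:
        raise ArityError(
            f"the Venn view compares exactly 2 persons, got {len(cmp.persons)}"
        )
    left, right = cmp.persons
    region_of_sig = {
        (left, right): "shared",
        (left,): "left_only",
        (right,): "right_only",
    }
    per_region: dict[str, list] = {r: [] for r in _VENN_REGIONS}
    for sig, entry in cmp.entries():
        size = next(iter(entry.per_person.values())).rarity_size
        per_region[region_of_sig[sig]].append((entry, size))

    # one radius scale for all regions, small enough for the fullest grid
    tightest = math.inf
    grids: dict[str, tuple[int, int, float, float]] = {}
    for region, members in per_region.items():
        if not members:
            continue
        x0, y0, x1, y1 = _VENN_BOXES[region]
        k = len(members)
        cols = math.ceil(math.sqrt(k))
        rows = math.ceil(k / cols)
        cell_w = (x1 - x0) / cols
        cell_h = (y1 - y0) / rows
        grids[region] = (cols, rows, cell_w, cell_h)
        tightest = min(tightest, cell_w, cell_h)
    if not grids:
        return []
    max_size = max(size for members in per_region.values() for _, size in members)
    r_unit = 0.45 * tightest / max_size

    bubbles: list[VennBubble] = []
    for region in _VENN_REGIONS:
        members = per_region[region]
        if not members:
            continue
        members.sort(key=lambda item: (-item[1], item[0].key))
        cols, _rows, cell_w, cell_h = grids[region]
        x0, y0, _x1, _y1 = _VENN_BOXES[region]
        for idx, (entry, size) in enumerate(members):
            row, col = divmod(idx, cols)
            person = next(p for p in cmp.persons if p in entry.per_person)
            bubbles.append(
                VennBubble(
                    region=region,
                    cx=x0 + (col + 0.5) * cell_w,
                    cy=y0 + (row + 0.5) * cell_h,
                    radius=size * r_unit,
                    style=style_for(entry.per_person[person].display_impact),
                    key=entry.key,
                )
            )
    return bubbles


def table_view(cmp: ComparisonReport) -> list[TableRow]:
    """Tabular report: one row per distinct variant, sorted by category then
    name, with a present/carrier/absent mark for every compared person."""
    rows: list[TableRow] = []
    for _sig, entry in cmp.entries():
        effect = entry.effect
        marks = {}
        for person in cmp.persons:
            v = entry.per_person.get(person)
            if v is None:
                marks[person] = "absent"
            elif v.display_impact is DisplayImpact.CARRIER:
                marks[person] = "carrier"
            else:
                marks[person] = "present"
        rows.append(
            TableRow(
                variant_name=effect.variant_name,
                category=effect.category,
                impact=effect.base_impact,
                certainty=effect.certainty,
                allele_frequency=effect.allele_frequency,
                effect_summary=effect.effect_summary,
                marks=marks,
                key=entry.key,
            )
        )
    rows.sort(key=lambda r: (r.category, r.variant_name))
    return rows


# ---------------------------------------------------------------------------
# SVG rendering

_CANVAS = 1000.0


def _fmt(x: float) -> str:
    return format(x, ".6f")


def _svg_header(parts: list[str]) -> None:
    parts.append('<?xml version="1.0" encoding="UTF-8"?>')
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{int(_CANVAS)}" height="{int(_CANVAS)}" '
        f'viewBox="0 0 {int(_CANVAS)} {int(_CANVAS)}">'
    )


def _pattern_defs(styles: set[StyleKey]) -> list[str]:
    """SVG <pattern> defs for every polka-dot style in use."""
    colors = sorted({s.color for s in styles if s.pattern})
    if not colors:
        return []
    parts = ["<defs>"]
    for color in colors:
        fill = _SVG_FILL[color]
        parts.append(
            f'<pattern id="polka-{color}" patternUnits="userSpaceOnUse" '
            f'width="8" height="8">'
            f'<rect width="8" height="8" fill="{fill}"/>'
            f'<circle cx="4" cy="4" r="2" fill="#ffffff"/>'
            f"</pattern>"
        )
    parts.append("</defs>")
    return parts


def _fill_of(style: StyleKey) -> str:
    return f"url(#polka-{style.color})" if style.pattern else _SVG_FILL[style.color]


def _arc_path(arc: Arc, n_rings: int) -> str:
    cx = cy = _CANVAS / 2.0
    outer_radius = 0.48 * _CANVAS
    ring_depth = (outer_radius - 0.08 * _CANVAS) / n_rings
    r_out = outer_radius - arc.ring_index * ring_depth
    r_in = r_out - 0.75 * ring_depth
    a0 = math.radians(arc.start_angle - 90.0)  # 0 degrees at 12 o'clock
    a1 = math.radians(arc.start_angle + arc.extent - 90.0)
    large = 1 if arc.extent > 180.0 else 0
    x0o, y0o = cx + r_out * math.cos(a0), cy + r_out * math.sin(a0)
    x1o, y1o = cx + r_out * math.cos(a1), cy + r_out * math.sin(a1)
    x1i, y1i = cx + r_in * math.cos(a1), cy + r_in * math.sin(a1)
    x0i, y0i = cx + r_in * math.cos(a0), cy + r_in * math.sin(a0)
    return (
        f"M {_fmt(x0o)} {_fmt(y0o)} "
        f"A {_fmt(r_out)} {_fmt(r_out)} 0 {large} 1 {_fmt(x1o)} {_fmt(y1o)} "
        f"L {_fmt(x1i)} {_fmt(y1i)} "
        f"A {_fmt(r_in)} {_fmt(r_in)} 0 {large} 0 {_fmt(x0i)} {_fmt(y0i)} Z"
    )


def render_svg(layout: Sequence, sink: IO[str]) -> None:
    """Render a layout (arcs, rects, bubbles, or table rows) as standalone
    SVG with one ``class="glyph"`` element per layout element.

    Output is byte-deterministic for identical inputs. An empty layout
    yields a valid SVG with zero glyph elements.
    """
    parts: list[str] = []
    _svg_header(parts)
    if layout:
        kinds = {type(el) for el in layout}
        if len(kinds) != 1:
            raise TypeError("mixed layout element types")
        kind = kinds.pop()
        if kind is not TableRow:
            parts.extend(_pattern_defs({el.style for el in layout}))
        if kind is Arc:
            _render_arcs(layout, parts)
        elif kind is Rect:
            _render_rects(layout, parts)
        elif kind is VennBubble:
            _render_bubbles(layout, parts)
        elif kind is TableRow:
            _render_table(layout, parts)
        else:
            raise TypeError(f"cannot render {kind.__name__}")
    parts.append("</svg>")
    sink.write("\n".join(parts) + "\n")


def _render_arcs(arcs: Sequence[Arc], parts: list[str]) -> None:
    n_rings = max(a.ring_index for a in arcs) + 1
    for arc in arcs:
        parts.append(
            f'<path class="glyph" d="{_arc_path(arc, n_rings)}" '
            f'fill="{_fill_of(arc.style)}" '
            f'data-key="{escape(arc.key[0])}:{escape(arc.key[1])}"/>'
        )


def _render_rects(rects: Sequence[Rect], parts: list[str]) -> None:
    n_rows = max(r.row_index for r in rects) + 1
    band = _CANVAS / n_rows
    for r in rects:
        y = r.row_index * band + 0.1 * band
        parts.append(
            f'<rect class="glyph" x="{_fmt(r.x_offset * _CANVAS)}" '
            f'y="{_fmt(y)}" width="{_fmt(r.width * _CANVAS)}" '
            f'height="{_fmt(r.height * _CANVAS)}" '
            f'fill="{_fill_of(r.style)}" '
            f'data-key="{escape(r.key[0])}:{escape(r.key[1])}"/>'
        )


def _render_bubbles(bubbles: Sequence[VennBubble], parts: list[str]) -> None:
    # region separators
    for x in (1.0 / 3.0, 2.0 / 3.0):
        parts.append(
            f'<line x1="{_fmt(x * _CANVAS)}" y1="0" '
            f'x2="{_fmt(x * _CANVAS)}" y2="{_fmt(_CANVAS)}" '
            f'stroke="#cccccc" stroke-width="1"/>'
        )
    for b in bubbles:
        parts.append(
            f'<circle class="glyph" cx="{_fmt(b.cx * _CANVAS)}" '
            f'cy="{_fmt(b.cy * _CANVAS)}" r="{_fmt(b.radius * _CANVAS)}" '
            f'fill="{_fill_of(b.style)}" '
            f'data-key="{escape(b.key[0])}:{escape(b.key[1])}"/>'
        )


def _render_table(rows: Sequence[TableRow], parts: list[str]) -> None:
    row_height = min(40.0, _CANVAS / (len(rows) + 1))
    persons = list(rows[0].marks)
    header = " | ".join(["variant", "category", "impact", "certainty"] + persons)
    parts.append(
        f'<text x="10" y="{_fmt(0.75 * row_height)}" '
        f'font-family="monospace" font-size="14">{escape(header)}</text>'
    )
    for i, row in enumerate(rows, start=1):
        cells = [
            row.variant_name,
            row.category,
            row.impact.value,
            row.certainty.value,
        ] + [f"{p}:{row.marks[p]}" for p in persons]
        parts.append(
            f'<text class="glyph" x="10" y="{_fmt((i + 0.75) * row_height)}" '
            f'font-family="monospace" font-size="12" '
            f'data-key="{escape(row.key[0])}:{escape(row.key[1])}">'
            f"{escape(' | '.join(cells))}</text>"
        )


# ---------------------------------------------------------------------------
# JSON dumps (for front ends)

_JSON_KIND = {Arc: "arcs", Rect: "rects", VennBubble: "bubbles", TableRow: "rows"}


def layout_to_json(layout: Sequence) -> dict:
    """Layout as a plain-dict document, e.g. ``{"arcs": [...]}``."""
    if not layout:
        return {"elements": []}
    kind = type(layout[0])
    name = _JSON_KIND.get(kind)
    if name is None:
        raise TypeError(f"cannot serialize {kind.__name__}")
    out = []
    for el in layout:
        if kind is TableRow:
            out.append(
                {
                    "variant_name": el.variant_name,
                    "category": el.category,
                    "impact": el.impact.value,
                    "certainty": el.certainty.value,
                    "allele_frequency": el.allele_frequency,
                    "effect_summary": el.effect_summary,
                    "marks": dict(el.marks),
                    "key": list(el.key),
                }
            )
        else:
            d = {
                "style": {"color": el.style.color, "pattern": el.style.pattern},
                "key": list(el.key),
            }
            if kind is Arc:
                d.update(
                    ring_index=el.ring_index,
                    start_angle=el.start_angle,
                    extent=el.extent,
                )
            elif kind is Rect:
                d.update(
                    row_index=el.row_index,
                    x_offset=el.x_offset,
                    width=el.width,
                    height=el.height,
                )
            else:
                d.update(region=el.region, cx=el.cx, cy=el.cy, radius=el.radius)
            out.append(d)
    return {name: out}
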