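"""Geometry of the four views: alignment, closure, non-overlap, encoding."""

from __future__ import annotations

import io
import math
import xml.etree.ElementTree as ET
from collections import defaultdict

import pytest

from conftest import make_annotated, make_family, random_comparison
from oracles import interval_overlaps
from variantcompare.comparison import compare
from variantcompare.errors import ArityError, IdentityError
from variantcompare.layout import (
    StyleKey,
    layout_to_json,
    linear_layout,
    render_svg,
    style_for,
    sunburst_layout,
    table_view,
    venn_layout,
)
from variantcompare.models import DisplayImpact, PersonReport

SEEDS = [0, 1, 2, 3, 4]


def _report(person_id, variants):
    return PersonReport(person_id=person_id, variants=tuple(variants))


class TestStyleFor:
    @pytest.mark.parametrize(
        "impact, color, pattern",
        [
            (DisplayImpact.PATHOGENIC, "red", False),
            (DisplayImpact.BENIGN, "gray", False),
            (DisplayImpact.PROTECTIVE, "blue", False),
            (DisplayImpact.PHARMACOGENETIC, "purple", False),
            (DisplayImpact.CARRIER, "red", True),
        ],
    )
    def test_color_and_pattern_encoding(self, impact, color, pattern):
        assert style_for(impact) == StyleKey(color=color, pattern=pattern)

    def test_mapping_is_a_bijection_onto_five_styles(self):
        styles = {style_for(i) for i in DisplayImpact}
        assert len(styles) == len(DisplayImpact)


def _distinct_slots(glyphs, start_attr, extent_attr):
    slots = {}
    for g in glyphs:
        slots[g.key] = (getattr(g, start_attr), getattr(g, extent_attr))
    return slots


class TestSunburst:
    def test_single_variant_single_ring(self):
        a = _report("a", [make_annotated()])
        b = _report("b", [])
        arcs = sunburst_layout(compare([a, b]))
        assert len(arcs) == 1
        assert arcs[0].ring_index == 0  # first person outermost by default
        assert arcs[0].extent > 0

    def test_shared_variants_are_radially_aligned(self):
        for seed in SEEDS:
            cmp = random_comparison(seed, 4)
            arcs = sunburst_layout(cmp)
            by_key = defaultdict(list)
            for arc in arcs:
                by_key[arc.key].append((arc.start_angle, arc.extent))
            for key, intervals in by_key.items():
                assert len(set(intervals)) == 1, key

    @pytest.mark.parametrize("seed", SEEDS)
    def test_slots_and_gaps_close_to_360_degrees(self, seed):
        cmp = random_comparison(seed, 3)
        arcs = sunburst_layout(cmp)
        slots = sorted(set((a.start_angle, a.extent) for a in arcs))
        # uniform gap between consecutive slots, and after the last one
        gaps = [
            s2 - (s1 + e1) for (s1, e1), (s2, _e2) in zip(slots, slots[1:])
        ]
        gaps.append(360.0 - (slots[-1][0] + slots[-1][1]))
        assert max(gaps) - min(gaps) < 1e-9
        total = sum(e for _s, e in slots) + sum(gaps)
        assert abs(total - 360.0) < 1e-9

    @pytest.mark.parametrize("seed", SEEDS)
    def test_no_overlaps_within_a_ring(self, seed):
        cmp = random_comparison(seed, 4)
        arcs = sunburst_layout(cmp)
        per_ring = defaultdict(list)
        for arc in arcs:
            per_ring[arc.ring_index].append((arc.start_angle, arc.extent))
        for ring, intervals in per_ring.items():
            assert interval_overlaps(intervals) == []

    def test_ring_order_parameter_and_default(self):
        cmp = random_comparison(0, 4)
        default = sunburst_layout(cmp)
        rings = {a.ring_index for a in default}
        assert rings <= {0, 1, 2, 3}
        reversed_order = list(cmp.persons)[::-1]
        flipped = sunburst_layout(cmp, ring_order=reversed_order)
        by_key_default = {(a.key, a.ring_index) for a in default}
        by_key_flipped = {
            (a.key, len(cmp.persons) - 1 - a.ring_index) for a in flipped
        }
        assert by_key_default == by_key_flipped

    def test_invalid_ring_order_raises(self):
        cmp = random_comparison(0, 2)
        with pytest.raises(IdentityError):
            sunburst_layout(cmp, ring_order=["parent1", "stranger"])

    def test_empty_comparison_gives_empty_layout(self):
        cmp = compare([_report("a", []), _report("b", [])])
        assert sunburst_layout(cmp) == []

    def test_shared_slots_precede_singleton_slots(self):
        for seed in SEEDS:
            cmp = random_comparison(seed, 3)
            arcs = sunburst_layout(cmp)
            full_sig = cmp.classes.get(cmp.persons, ())
            full_keys = {e.key for e in full_sig}
            singleton_keys = {
                e.key
                for sig, entries in cmp.classes.items()
                if len(sig) == 1
                for e in entries
            }
            slots = _distinct_slots(arcs, "start_angle", "extent")
            for fk in full_keys:
                for sk in singleton_keys:
                    assert slots[fk][0] < slots[sk][0]


class TestLinear:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_no_overlaps_within_a_row(self, seed):
        cmp = random_comparison(seed, 4)
        rects = linear_layout(cmp)
        per_row = defaultdict(list)
        for r in rects:
            per_row[r.row_index].append((r.x_offset, r.width))
        for row, intervals in per_row.items():
            assert interval_overlaps(intervals) == []

    def test_fully_shared_comparison_rows_are_identical(self):
        variants = [
            make_annotated(rsid=f"rs{i}", variant_name=f"GENE{i}-X{i}Y",
                           allele_frequency=0.01 * (i + 1))
            for i in range(5)
        ]
        cmp = compare([_report("a", variants), _report("b", variants)])
        rects = linear_layout(cmp)
        rows = defaultdict(set)
        for r in rects:
            rows[r.row_index].add((r.x_offset, r.width))
        assert rows[0] == rows[1]

    def test_shared_slots_precede_unique_slot(self):
        shared = [
            make_annotated(rsid=f"rs{i}", variant_name=f"GENE{i}-X{i}Y")
            for i in range(2)
        ]
        unique = make_annotated(rsid="rs9", variant_name="GENE9-X9Y")
        cmp = compare(
            [_report("a", shared + [unique]), _report("b", shared)]
        )
        rects = linear_layout(cmp)
        unique_x = min(r.x_offset for r in rects if r.key == unique.key)
        shared_x = max(r.x_offset for r in rects if r.key != unique.key)
        assert shared_x < unique_x

    def test_shared_variants_vertically_aligned(self):
        cmp = random_comparison(2, 4)
        rects = linear_layout(cmp)
        by_key = defaultdict(set)
        for r in rects:
            by_key[r.key].add((r.x_offset, r.width))
        assert all(len(s) == 1 for s in by_key.values())

    def test_one_row_per_person_in_given_order(self):
        cmp = random_comparison(0, 4)
        rects = linear_layout(cmp, row_order=list(cmp.persons))
        per_row_keys = defaultdict(set)
        for r in rects:
            per_row_keys[r.row_index].add(r.key)
        for i, person in enumerate(cmp.persons):
            assert per_row_keys[i] == cmp.keys_for(person)


class TestVenn:
    def test_four_person_comparison_is_an_arity_error(self):
        cmp = random_comparison(0, 4)
        with pytest.raises(ArityError):
            venn_layout(cmp)

    def test_region_assignment_matches_membership(self):
        shared = make_annotated(rsid="rs1", variant_name="GENE1-X1Y")
        only_a = make_annotated(rsid="rs2", variant_name="GENE2-X2Y")
        only_b = make_annotated(rsid="rs3", variant_name="GENE3-X3Y")
        cmp = compare(
            [_report("a", [shared, only_a]), _report("b", [shared, only_b])]
        )
        regions = {b.key: b.region for b in venn_layout(cmp)}
        assert regions[shared.key] == "shared"
        assert regions[only_a.key] == "left_only"
        assert regions[only_b.key] == "right_only"

    @pytest.mark.parametrize("seed", SEEDS)
    def test_bubbles_never_overlap(self, seed):
        cmp = random_comparison(seed, 2)
        bubbles = venn_layout(cmp)
        for i, b1 in enumerate(bubbles):
            for b2 in bubbles[i + 1:]:
                dist = math.hypot(b1.cx - b2.cx, b1.cy - b2.cy)
                assert dist >= b1.radius + b2.radius - 1e-12

    @pytest.mark.parametrize("seed", SEEDS)
    def test_bubbles_stay_inside_their_region_box(self, seed):
        boxes = {
            "left_only": (0.0, 1 / 3),
            "shared": (1 / 3, 2 / 3),
            "right_only": (2 / 3, 1.0),
        }
        for b in venn_layout(random_comparison(seed, 2)):
            x0, x1 = boxes[b.region]
            assert x0 <= b.cx - b.radius and b.cx + b.radius <= x1
            assert 0.0 <= b.cy - b.radius and b.cy + b.radius <= 1.0


class TestEncodingFaithfulness:
    """Glyph size ordering must match rarity (inverse frequency) ordering."""

    @pytest.mark.parametrize("seed", SEEDS)
    def test_all_three_geometries(self, seed):
        cmp = random_comparison(seed, 2)
        freq = {}
        for _sig, e in cmp.entries():
            freq[e.key] = e.effect.allele_frequency
        arcs = {a.key: a.extent for a in sunburst_layout(cmp)}
        rects = {r.key: r.width for r in linear_layout(cmp)}
        bubbles = {b.key: b.radius for b in venn_layout(cmp)}
        for sizes in (arcs, rects, bubbles):
            keys = sorted(sizes, key=lambda k: freq[k])
            ordered = [sizes[k] for k in keys]
            assert all(a > b for a, b in zip(ordered, ordered[1:]))


class TestTableView:
    def test_marks_distinguish_carrier_from_present(self):
        het = make_annotated(zygosity="heterozygous")  # carrier
        hom = make_annotated(zygosity="homozygous")    # pathogenic
        cmp = compare([_report("a", [het]), _report("b", [hom])])
        (row,) = table_view(cmp)
        assert row.marks == {"a": "carrier", "b": "present"}

    def test_absent_mark_and_row_count(self):
        cmp = random_comparison(1, 4)
        rows = table_view(cmp)
        assert len(rows) == len(cmp.all_keys())
        for row in rows:
            assert set(row.marks) == set(cmp.persons)
            carriers = {
                p
                for sig, e in cmp.entries()
                if e.key == row.key
                for p in sig
            }
            for p in cmp.persons:
                assert (row.marks[p] == "absent") == (p not in carriers)

    def test_rows_sorted_by_category_then_name(self):
        rows = table_view(random_comparison(2, 3))
        ordering = [(r.category, r.variant_name) for r in rows]
        assert ordering == sorted(ordering)


class TestRenderSVG:
    def _svg(self, elements) -> str:
        sink = io.StringIO()
        render_svg(elements, sink)
        return sink.getvalue()

    def _glyph_count(self, svg_text: str) -> int:
        root = ET.fromstring(svg_text)
        return sum(
            1 for el in root.iter() if el.attrib.get("class") == "glyph"
        )

    def test_empty_layout_is_valid_svg_with_zero_glyphs(self):
        text = self._svg([])
        assert self._glyph_count(text) == 0

    def test_byte_determinism(self):
        cmp = random_comparison(0, 4)
        assert self._svg(sunburst_layout(cmp)) == self._svg(sunburst_layout(cmp))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_glyph_count_equals_layout_element_count(self, seed):
        cmp = random_comparison(seed, 3)
        cmp2 = random_comparison(seed, 2)
        for elements in (
            sunburst_layout(cmp),
            linear_layout(cmp),
            venn_layout(cmp2),
            table_view(cmp),
        ):
            assert self._glyph_count(self._svg(elements)) == len(elements)

    def test_carrier_glyphs_use_polka_pattern_fill(self):
        het = make_annotated(zygosity="heterozygous")
        cmp = compare([_report("a", [het]), _report("b", [])])
        text = self._svg(sunburst_layout(cmp))
        assert 'fill="url(#polka-red)"' in text
        assert "<pattern" in text


class TestLayoutJSON:
    def test_kind_keys(self):
        cmp = random_comparison(0, 2)
        assert "arcs" in layout_to_json(sunburst_layout(cmp))
        assert "rects" in layout_to_json(linear_layout(cmp))
        assert "bubbles" in layout_to_json(venn_layout(cmp))
        assert "rows" in layout_to_json(table_view(cmp))
        assert layout_to_json([]) == {"elements": []}
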