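"""Dendrogram orders, zone classification, DCI, spine estimates, areas."""

import math

import numpy as np
import pytest

from pcarbor.morphology import MorphPoint, NeuronMorphology, Section
from pcarbor.morphometrics import (
    build_dendrogram,
    classify_zones,
    count_primary_dendrites,
    dci,
    estimate_spines,
    morphometric_report,
    surface_area,
)

from .conftest import make_morphology, straight_points, y_tree


class TestDendrogram:
    def test_single_unbranched_dendrite(self):
        m = make_morphology(
            [(0, "dendrite", straight_points((0, 0, 0), (0, 50, 0), 1.0))]
        )
        dg = build_dendrogram(m)
        (node,) = dg.nodes.values()
        assert node.order == 1 and node.is_tip

    def test_symmetric_two_level_tree(self):
        dg = build_dendrogram(y_tree())
        assert sorted(n.order for n in dg.nodes.values()) == [1, 2, 2]
        assert len(dg.tips) == 2

    def test_orders_match_independent_path_count(self, human_morph):
        # oracle: walk the parent chain of every tip, counting dendritic
        # sections on the soma path
        dg = build_dendrogram(human_morph)
        for tip in dg.tips:
            sec = human_morph.sections[tip.section_id]
            count = 0
            while sec is not None and sec.stype == "dendrite":
                count += 1
                sec = human_morph.sections.get(sec.parent_id)
            assert count == tip.order

    def test_no_dendrites_is_an_error(self):
        m = make_morphology(
            [(0, "axon", straight_points((0, 0, 0), (0, 50, 0), 1.0))]
        )
        with pytest.raises(Exception, match="dendritic"):
            build_dendrogram(m)

    def test_newick_export_has_one_leaf_per_tip(self, mouse_morph):
        import dendropy

        dg = build_dendrogram(mouse_morph)
        tree = dendropy.Tree.get(data=dg.to_newick(mouse_morph), schema="newick")
        assert len(tree.leaf_nodes()) == len(dg.tips)


class TestZones:
    @pytest.mark.parametrize(
        "diameter, zone, targets",
        [
            (0.5, "spiny", {"aa", "SC"}),
            (0.2, "spiny", {"aa"}),
            (1.0, "spiny", {"pf", "SC"}),
            (0.75, "spiny", {"pf", "SC"}),
            (2.0, "trunk", {"cf"}),
            (1.6, "trunk", {"cf"}),
            (3.3, "trunk", {"cf"}),
            (3.31, "main_trunk", {"cf"}),
        ],
    )
    def test_diameter_rules(self, diameter, zone, targets):
        m = make_morphology(
            [(0, "dendrite", straight_points((0, 0, 0), (0, 50, 0), diameter))]
        )
        (label,) = classify_zones(m).values()
        assert label.zone == zone
        assert set(label.synaptic_targets) == targets

    def test_partition_is_exhaustive_and_exclusive(self, human_morph):
        zones = classify_zones(human_morph)
        assert set(zones) == {s.id for s in human_morph.dendrites()}
        assert all(
            z.zone in {"spiny", "trunk", "main_trunk"} for z in zones.values()
        )


class TestPrimaryDendrites:
    def test_single_stem(self):
        assert count_primary_dendrites(y_tree()) == 1

    def test_three_stems(self):
        specs = []
        for k, ang in enumerate((60, 90, 120)):
            x = 50 * math.cos(math.radians(ang))
            y = 50 * math.sin(math.radians(ang))
            specs.append((0, "dendrite", straight_points((0, 0, 0), (x, y, 0), 2.0)))
        m = make_morphology(specs)
        assert count_primary_dendrites(m) == 3

    def test_stem_counts_once_even_if_it_branches_immediately(self):
        # short stem that branches right away: one primary, not two
        stem = straight_points((0, 0, 0), (0, 1.0, 0), 2.0)
        m = make_morphology(
            [
                (0, "dendrite", stem),
                (1, "dendrite", straight_points((0, 1, 0), (30, 30, 0), 1.0)),
                (1, "dendrite", straight_points((0, 1, 0), (-30, 30, 0), 1.0)),
            ]
        )
        assert count_primary_dendrites(m) == 1


class TestDci:
    def test_hand_enumerated_y_tree(self):
        # tips = 2 with orders {2, 2}; length 300; one primary
        assert dci(y_tree()) == pytest.approx(1800.0)

    def test_linear_in_total_length(self):
        big = y_tree(stem_len=200.0, child_len=200.0)
        assert dci(big) == pytest.approx(3600.0)

    def test_duplicated_stem_doubles_tips_but_halves_per_primary_length(self):
        # two identical Y-stems: tips 4, sum of orders 8, length 600, 2
        # primaries -> (8+4) * (600/2) = 3600
        h = 100 / math.sqrt(2)
        specs = []
        for sgn in (1, -1):
            base = len(specs)
            specs.append(
                (0, "dendrite",
                 straight_points((0, 0, 0), (sgn * 100, 0, 0), 2.0))
            )
            stem_id = base + 1
            specs.append(
                (stem_id, "dendrite",
                 straight_points((sgn * 100, 0, 0), (sgn * (100 + h), h, 0), 0.8))
            )
            specs.append(
                (stem_id, "dendrite",
                 straight_points((sgn * 100, 0, 0), (sgn * (100 + h), -h, 0), 0.8))
            )
        m = make_morphology(specs)
        assert dci(m) == pytest.approx(3600.0)

    def test_rigid_rotation_invariance(self, mouse_morph):
        theta = math.radians(37.0)
        c, s = math.cos(theta), math.sin(theta)
        secs = {}
        for sid, sec in mouse_morph.sections.items():
            pts = [
                MorphPoint(c * p.x - s * p.y + 5.0, s * p.x + c * p.y - 3.0,
                           p.z, p.diameter)
                for p in sec.points
            ]
            secs[sid] = Section(sec.id, sec.parent_id, sec.stype, pts)
        rotated = NeuronMorphology(secs, mouse_morph.root_id)
        assert dci(rotated) == pytest.approx(dci(mouse_morph), rel=1e-9)


class TestSpines:
    def test_simple_product(self):
        m = make_morphology(
            [(0, "dendrite", straight_points((0, 0, 0), (100, 0, 0), 0.8))]
        )
        total, table = estimate_spines(m, density=2.0)
        assert total == 200
        assert table.spine_count.sum() == 200

    def test_no_spiny_length_gives_zero(self):
        m = make_morphology(
            [(0, "dendrite", straight_points((0, 0, 0), (100, 0, 0), 2.5))]
        )
        total, table = estimate_spines(m, density=2.0)
        assert total == 0 and table.spine_count.sum() == 0

    def test_negative_density_rejected(self, mouse_morph):
        with pytest.raises(ValueError):
            estimate_spines(mouse_morph, density=-1.0)

    def test_bin_table_conserves_total_on_synthetic_tree(self, mouse_morph):
        total, table = estimate_spines(mouse_morph, density=2.0)
        assert table.spine_count.sum() == total

    def test_total_matches_per_section_allocation_within_rounding(
        self, mouse_morph
    ):
        # oracle: allocate per section with independent rounding; the whole-
        # tree total can differ by at most one count per section
        from pcarbor.morphometrics import classify_zones

        zones = classify_zones(mouse_morph)
        spiny = [s for s in mouse_morph.dendrites()
                 if zones[s.id].zone == "spiny"]
        per_section = sum(int(math.floor(2.0 * s.length + 0.5)) for s in spiny)
        total, _ = estimate_spines(mouse_morph, density=2.0)
        assert abs(total - per_section) <= len(spiny)


class TestSurfaceArea:
    def test_cylinder_closed_form(self):
        m = make_morphology(
            [(0, "dendrite", straight_points((0, 0, 0), (10, 0, 0), 2.0))]
        )
        assert surface_area(m) == pytest.approx(20 * math.pi)

    def test_frustum_closed_form(self):
        pts = [MorphPoint(0, 0, 0, 2.0), MorphPoint(10, 0, 0, 1.0)]
        m = make_morphology([(0, "dendrite", pts)])
        expected = math.pi * 1.5 * math.sqrt(10**2 + 0.5**2)
        assert surface_area(m) == pytest.approx(expected)

    def test_zone_scopes_are_additive(self, human_morph):
        whole = surface_area(human_morph)
        parts = sum(
            surface_area(human_morph, scope)
            for scope in ("spiny", "trunk", "main_trunk")
        )
        assert parts == pytest.approx(whole, rel=1e-9)


def test_report_counts_are_consistent(mouse_morph):
    rep = morphometric_report(mouse_morph)
    assert rep.n_spiny + rep.n_aspiny == rep.n_sections
    assert rep.dci > 0
    assert rep.spine_count_estimate == pytest.approx(
        2.0 * surface_spiny_length(mouse_morph), abs=1.0
    )


def surface_spiny_length(morph):
    from pcarbor.morphometrics import classify_zones

    zones = classify_zones(morph)
    return sum(
        s.length for s in morph.dendrites() if zones[s.id].zone == "spiny"
    )
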