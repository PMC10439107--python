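import math

import numpy as np
import pytest

from sweetdot import patterns
from sweetdot.patterns import (
    CompositionError,
    DotPattern,
    DotSpec,
    GeometryError,
    SampleGeometry,
    classify_scale,
    cluster_gap,
    dot_distances,
    generate_pattern,
    make_ink,
    pattern_from_json,
    pattern_to_json,
    render_bitmap,
    table_inks,
    tastant_load,
)

from conftest import DOTTED_DESIGNS, MICRO_DESIGNS


def _brute_force_nn(centers):
    """Independent nearest-neighbour oracle via explicit pairwise loops."""
    out = []
    for i, (xi, yi) in enumerate(centers):
        best = math.inf
        for j, (xj, yj) in enumerate(centers):
            if i != j:
                best = min(best, math.hypot(xi - xj, yi - yj))
        out.append(best)
    return out


class TestInks:
    def test_ink_a_effective_thaumatin(self):
        ink = make_ink("A", 0.009, 0.1)
        assert ink.effective_thaumatin == pytest.approx(0.0009, abs=1e-12)  # 0.09 %w/w

    def test_ink_c_effective_thaumatin(self):
        ink = make_ink("C", 0.036, 0.1)
        assert ink.effective_thaumatin == pytest.approx(0.0036, abs=1e-12)  # 0.36 %w/w

    def test_ink_d_zero(self):
        assert make_ink("D", 0.0).effective_thaumatin == 0.0

    @pytest.mark.parametrize(
        "label,expected", [("A", 0.0009), ("B", 0.0018), ("C", 0.0036), ("D", 0.0)]
    )
    def test_table_inks(self, inks, label, expected):
        assert inks[label].effective_thaumatin == pytest.approx(expected, abs=1e-12)

    def test_table_ink_invariants(self, inks):
        for ink in inks.values():
            assert sum(ink.emulsion_composition.values()) == pytest.approx(1.0, abs=1e-9)
            assert ink.seeded_cocoa_butter_frac + ink.emulsion_frac == pytest.approx(1.0, abs=1e-9)
            assert all(0 <= v <= 1 for v in ink.emulsion_composition.values())

    def test_bad_fraction_names_component(self):
        with pytest.raises(CompositionError, match="thaumatin"):
            make_ink("X", 1.5)

    def test_nonclosing_composition_rejected(self):
        with pytest.raises(CompositionError):
            make_ink("X", 0.01, components={"water": 0.2, "PGPR": 0.03, "CCT_oil": 0.52})


class TestGeneratePattern:
    @pytest.mark.parametrize(
        "name,count",
        [
            ("Bulk", 184),
            ("Homogeneous", 184),
            ("SpacedFull", 184),
            ("SpacedHalf", 92),
            ("SpacedQuarter", 46),
            ("Centered", 184),
            ("Periphery", 184),
            ("Layer", 0),
        ],
    )
    def test_canonical_counts(self, canonical_patterns, name, count):
        assert len(canonical_patterns[name]) == count

    def test_ink_assignment(self, canonical_patterns):
        assert {d.ink.name for d in canonical_patterns["SpacedFull"].dots} == {"A"}
        assert {d.ink.name for d in canonical_patterns["SpacedHalf"].dots} == {"B"}
        assert {d.ink.name for d in canonical_patterns["SpacedQuarter"].dots} == {"C"}
        assert {d.ink.name for d in canonical_patterns["Bulk"].dots} == {"D"}
        assert canonical_patterns["Bulk"].bulk_thaumatin_frac > 0

    def test_halving_subsets(self, canonical_patterns):
        full = {(d.center_x, d.center_y) for d in canonical_patterns["SpacedFull"].dots}
        half = {(d.center_x, d.center_y) for d in canonical_patterns["SpacedHalf"].dots}
        quarter = {(d.center_x, d.center_y) for d in canonical_patterns["SpacedQuarter"].dots}
        assert quarter < half < full
        assert len(half) * 2 == len(full)
        assert len(quarter) * 2 == len(half)

    def test_dots_inside_printable_region(self, canonical_patterns):
        for pattern in canonical_patterns.values():
            for d in pattern.dots:
                assert pattern.geometry.contains(d.center_x, d.center_y)

    def test_no_overlap(self, canonical_patterns):
        for pattern in canonical_patterns.values():
            dists = dot_distances(pattern, metric="center")
            if dists.size:
                diam = max(d.nominal_diameter for d in pattern.dots)
                assert dists.min() >= diam - 1e-9

    def test_no_coincident_centers(self, canonical_patterns):
        for pattern in canonical_patterns.values():
            pts = {(d.center_x, d.center_y) for d in pattern.dots}
            assert len(pts) == len(pattern.dots)

    def test_deterministic(self):
        a = generate_pattern("SpacedQuarter")
        b = generate_pattern("SpacedQuarter", seed=123)
        assert a.centers().tolist() == b.centers().tolist()

    def test_unknown_design(self):
        with pytest.raises(ValueError, match="unknown design"):
            generate_pattern("Diagonal")

    def test_aliases(self):
        assert generate_pattern("sp_quarter").design_name == "SpacedQuarter"
        assert generate_pattern("SP. Half").design_name == "SpacedHalf"

    def test_grid_must_fit(self):
        tiny = SampleGeometry(length=10.0, width=8.0, height=3.0, printable_margin=0.5)
        with pytest.raises(GeometryError):
            generate_pattern("Homogeneous", geometry=tiny)

    def test_layer_descriptor(self, canonical_patterns):
        layer = canonical_patterns["Layer"]
        assert len(layer) == 0
        assert layer.layer_coat_mass_ug > 0
        assert layer.layer_ink.name == "A"

    def test_geometry_ordering_enforced(self):
        with pytest.raises(GeometryError):
            SampleGeometry(length=24.0, width=36.0, height=3.0)


class TestDotDistances:
    def test_two_dot_edge_metric(self, inks):
        geo = SampleGeometry()
        dots = (
            DotSpec(10.0, 12.0, inks["A"], 1.5),
            DotSpec(14.0, 12.0, inks["A"], 1.5),
        )
        pattern = DotPattern("SpacedFull", dots, "micro", geo)
        assert dot_distances(pattern, "edge").tolist() == [2.5, 2.5]

    def test_single_dot_empty(self, inks):
        pattern = DotPattern(
            "SpacedFull", (DotSpec(10.0, 12.0, inks["A"]),), "micro", SampleGeometry()
        )
        assert dot_distances(pattern).size == 0

    def test_matches_brute_force(self, canonical_patterns):
        for name in DOTTED_DESIGNS:
            pattern = canonical_patterns[name]
            expected = _brute_force_nn([(d.center_x, d.center_y) for d in pattern.dots])
            np.testing.assert_allclose(dot_distances(pattern, "center"), expected)

    def test_spaced_quarter_max_gap(self, canonical_patterns):
        gaps = dot_distances(canonical_patterns["SpacedQuarter"], "edge")
        assert gaps.max() == pytest.approx(2.5, abs=1e-9)

    def test_edge_floor_at_zero(self, inks):
        dots = (
            DotSpec(10.0, 12.0, inks["A"], 3.0),
            DotSpec(12.0, 12.0, inks["A"], 3.0),
        )
        pattern = DotPattern("SpacedFull", dots, "micro", SampleGeometry())
        assert dot_distances(pattern, "edge").tolist() == [0.0, 0.0]

    def test_unknown_metric(self, canonical_patterns):
        with pytest.raises(ValueError):
            dot_distances(canonical_patterns["SpacedFull"], "manhattan")


class TestClassifyScale:
    @pytest.mark.parametrize("name", MICRO_DESIGNS)
    def test_micro(self, canonical_patterns, name):
        assert classify_scale(canonical_patterns[name]) == "micro"

    @pytest.mark.parametrize("name", ["Centered", "Periphery"])
    def test_meso(self, canonical_patterns, name):
        assert classify_scale(canonical_patterns[name]) == "meso"

    def test_layer_none(self, canonical_patterns):
        assert classify_scale(canonical_patterns["Layer"]) == "none"

    def test_bulk_none(self, canonical_patterns):
        # ink-D dots carry no thaumatin
        assert classify_scale(canonical_patterns["Bulk"]) == "none"

    def test_cluster_gap_exceeds_8mm(self, canonical_patterns):
        for name in ("Centered", "Periphery"):
            assert cluster_gap(canonical_patterns[name]) > 8.0


class TestTastantLoad:
    def test_homogeneous_load(self, canonical_patterns):
        load = tastant_load(canonical_patterns["Homogeneous"], drop_mass_ug=390.0)
        assert load.total_ug == pytest.approx(184 * 390 * 0.0009, rel=1e-12)
        assert load.total_ug == pytest.approx(64.584, abs=1e-9)

    def test_bulk_dot_contribution_zero(self, canonical_patterns):
        load = tastant_load(canonical_patterns["Bulk"])
        assert load.per_ink_ug.get("D", 0.0) == 0.0
        assert load.bulk_ug > 0

    def test_conservation_across_dotted_designs(self, canonical_patterns):
        ref = tastant_load(canonical_patterns["Homogeneous"]).total_ug
        for name in DOTTED_DESIGNS:
            total = tastant_load(canonical_patterns[name]).total_ug
            assert total / ref == pytest.approx(1.0, abs=1e-9)

    def test_bulk_and_layer_match_dotted_load(self, canonical_patterns):
        ref = tastant_load(canonical_patterns["Homogeneous"]).total_ug
        for name in ("Bulk", "Layer"):
            assert tastant_load(canonical_patterns[name]).total_ug == pytest.approx(ref, rel=1e-9)

    def test_drop_mass_must_be_positive(self, canonical_patterns):
        with pytest.raises(ValueError):
            tastant_load(canonical_patterns["Homogeneous"], drop_mass_ug=0.0)

    def test_ledger_itemized_by_ink(self, canonical_patterns):
        load = tastant_load(canonical_patterns["Centered"])
        assert set(load.per_ink_ug) == {"B", "D"}
        assert load.per_ink_ug["D"] == 0.0


class TestBitmapAndJson:
    def test_bitmap_white_count(self, canonical_patterns):
        for name in MICRO_DESIGNS:
            pattern = canonical_patterns[name]
            assert render_bitmap(pattern, 2.0).sum() == len(pattern)

    def test_bitmap_collision_raises(self, canonical_patterns):
        with pytest.raises(GeometryError):
            render_bitmap(canonical_patterns["Centered"], 2.0)

    def test_meso_bitmap_fine_pitch(self, canonical_patterns):
        bm = render_bitmap(canonical_patterns["Centered"], 0.5)
        assert bm.sum() == 184

    def test_json_round_trip(self, canonical_patterns):
        for name in ("SpacedQuarter", "Centered", "Layer", "Bulk"):
            pattern = canonical_patterns[name]
            restored = pattern_from_json(pattern_to_json(pattern))
            assert restored.design_name == pattern.design_name
            assert len(restored) == len(pattern)
            assert restored.centers().tolist() == pattern.centers().tolist()
            assert restored.bulk_thaumatin_frac == pattern.bulk_thaumatin_frac
            for a, b in zip(restored.dots, pattern.dots):
                assert a.ink.effective_thaumatin == b.ink.effective_thaumatin
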