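import math

import numpy as np
import networkx as nx
import pytest

from nmlineage.track_lineage import (
    Box,
    CellNode,
    ClonalSelection,
    FateRules,
    HalfSpace,
    LineageForest,
    Sphere,
    ap_contribution,
    classify_cell_fate,
    classify_label,
    classify_selection_fates,
    clone_fold_change,
    label_polar_position,
    read_tgmm,
    select_clone,
    terminal_division_fates,
    write_tgmm,
    zone_assign,
)

RULES = FateRules(mezzo_threshold=500, sox17_threshold=500, k_frames=3)


def _node(nid, parent, t, pos, mezzo=0.0, sox17=0.0):
    return CellNode(nid, parent, t, pos, {"mezzo": mezzo, "sox17": sox17})


class TestTGMMIO:
    def _write_toy(self, directory):
        directory.mkdir(exist_ok=True)
        (directory / "GMEMfinalResult_frame0000.xml").write_text(
            '<document>\n'
            '<GaussianMixtureModel id="0" lineage="0" parent="-1" '
            'm="10 20 30" mezzo="100"/>\n'
            '</document>\n'
        )
        (directory / "GMEMfinalResult_frame0001.xml").write_text(
            '<document>\n'
            '<GaussianMixtureModel id="1" lineage="0" parent="0" '
            'm="11 20 30" mezzo="110"/>\n'
            '<GaussianMixtureModel id="2" lineage="0" parent="0" '
            'm="9 20 30" mezzo="120"/>\n'
            '</document>\n'
        )

    def test_toy_xml_yields_one_division(self, tmp_path):
        self._write_toy(tmp_path / "tgmm")
        forest = read_tgmm(tmp_path / "tgmm")
        assert len(forest.roots()) == 1
        root = forest.roots()[0]
        assert len(forest.children(root)) == 2
        assert forest.nodes[root].channels["mezzo"] == 100.0
        np.testing.assert_allclose(forest.nodes[root].position, [10, 20, 30])

    def test_voxel_scale_applied(self, tmp_path):
        self._write_toy(tmp_path / "tgmm")
        forest = read_tgmm(tmp_path / "tgmm", voxel_size=(2.0, 2.0, 0.5))
        root = forest.roots()[0]
        np.testing.assert_allclose(forest.nodes[root].position, [20, 40, 15])

    def test_orphan_parent_becomes_new_root(self, tmp_path, caplog):
        d = tmp_path / "tgmm"
        d.mkdir()
        (d / "f0.xml").write_text(
            '<document><GaussianMixtureModel id="0" parent="-1" m="0 0 0"/>'
            '</document>'
        )
        (d / "f1.xml").write_text(
            '<document><GaussianMixtureModel id="1" parent="99" m="1 1 1"/>'
            '</document>'
        )
        with caplog.at_level("WARNING"):
            forest = read_tgmm(d)
        assert len(forest.roots()) == 2
        assert "new root" in caplog.text

    def test_duplicate_id_within_timepoint_is_error(self, tmp_path):
        d = tmp_path / "tgmm"
        d.mkdir()
        (d / "f0.xml").write_text(
            '<document>'
            '<GaussianMixtureModel id="0" parent="-1" m="0 0 0"/>'
            '<GaussianMixtureModel id="0" parent="-1" m="1 1 1"/>'
            '</document>'
        )
        with pytest.raises(ValueError, match="duplicate id"):
            read_tgmm(d)

    def test_csv_xml_round_trip(self, tmp_path):
        self._write_toy(tmp_path / "tgmm")
        forest = read_tgmm(tmp_path / "tgmm")
        forest.write_csv(tmp_path / "tracks.csv")
        back = LineageForest.read_csv(tmp_path / "tracks.csv")
        assert set(back.nodes) == set(forest.nodes)
        write_tgmm(back, tmp_path / "tgmm2")
        again = read_tgmm(tmp_path / "tgmm2")
        assert len(again.roots()) == 1
        orig = sorted(
            tuple(np.round(n.position, 6)) for n in forest.nodes.values()
        )
        rt = sorted(
            tuple(np.round(n.position, 6)) for n in again.nodes.values()
        )
        assert orig == rt


class TestForestInvariants:
    def test_parent_must_precede_child(self):
        nodes = {
            0: _node(0, None, 5, [0, 0, 0]),
            1: _node(1, 0, 5, [0, 0, 0]),
        }
        with pytest.raises(ValueError, match="not before"):
            LineageForest(nodes)

    def test_more_than_two_children_rejected(self):
        nodes = {0: _node(0, None, 0, [0, 0, 0])}
        for i in (1, 2, 3):
            nodes[i] = _node(i, 0, 1, [0, 0, 0])
        with pytest.raises(ValueError, match="children"):
            LineageForest(nodes)


class TestSelectClone:
    def _forest_five_cells(self):
        nodes = {}
        for i in range(5):
            nodes[i] = _node(i, None, 0, [float(i), 0, 0])
            nodes[i + 10] = _node(i + 10, i, 1, [float(i), 0, 0])
        # cell 2 divides at t=2
        nodes[20] = _node(20, 12, 2, [2, 1, 0])
        nodes[21] = _node(21, 12, 2, [2, -1, 0])
        return LineageForest(nodes)

    def test_sphere_selection_includes_descendants(self):
        forest = self._forest_five_cells()
        sel = select_clone(forest, Sphere([1, 0, 0], 1.2), t0=0)
        assert sel.roots == [0, 1, 2]
        assert {20, 21} <= sel.node_ids  # daughters of the dividing cell

    def test_viewpoint_half_space_removes_far_side(self):
        forest = self._forest_five_cells()
        view = HalfSpace(point=[2, 0, 0], normal=[1, 0, 0])  # keep x >= 2
        sel = select_clone(forest, Box([0, -1, -1], [4, 1, 1]), 0, view)
        assert sel.roots == [2, 3, 4]

    def test_empty_selection_warns(self, caplog):
        forest = self._forest_five_cells()
        with caplog.at_level("WARNING"):
            sel = select_clone(forest, Sphere([100, 0, 0], 1), 0)
        assert sel.roots == [] and sel.node_ids == set()
        assert "empty" in caplog.text

    def test_t0_outside_span_is_error(self):
        with pytest.raises(ValueError, match="outside forest span"):
            select_clone(self._forest_five_cells(), Sphere([0, 0, 0], 1), 99)

    def test_descendant_closure_matches_bfs_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 60))
            nodes = {0: _node(0, None, 0, rng.normal(size=3))}
            g = nx.DiGraph()
            g.add_node(0)
            for i in range(1, n):
                candidates = [
                    c for c in nodes
                    if len([k for k in g.successors(c)]) < 2
                ]
                parent = int(rng.choice(candidates))
                nodes[i] = _node(i, parent, nodes[parent].t + 1,
                                 rng.normal(size=3))
                g.add_edge(parent, i)
            forest = LineageForest(nodes)
            sel = select_clone(forest, Sphere([0, 0, 0], 100), t0=0)
            expected = {0} | nx.descendants(g, 0)
            assert sel.node_ids == expected


class TestFateClassification:
    def _linear(self, mezzo_trace, sox17_trace=None, t_max_pad=0):
        sox17_trace = sox17_trace or [0.0] * len(mezzo_trace)
        nodes = {}
        for t, (m, s) in enumerate(zip(mezzo_trace, sox17_trace)):
            nodes[t] = _node(t, t - 1 if t else None, t, [0, 0, 0], m, s)
        # optionally extend the observation window with an unrelated track
        for k in range(t_max_pad):
            nid = 100 + k
            nodes[nid] = _node(nid, 100 + k - 1 if k else None,
                               k, [5, 5, 5], 0, 0)
        return LineageForest(nodes)

    def test_sustained_mezzo_is_mesoderm(self):
        forest = self._linear([100, 100, 800, 900, 850])
        call = classify_cell_fate(forest, 4, RULES)
        assert call.fate == "mesoderm"
        assert call.evidence["consecutive_frames"] >= 3

    def test_flat_reporters_surviving_to_end_is_neural(self):
        forest = self._linear([100] * 5)
        assert classify_cell_fate(forest, 4, RULES).fate == "neural"

    def test_single_frame_spike_rejected(self):
        forest = self._linear([100, 100, 900, 100, 100])
        assert classify_cell_fate(forest, 4, RULES).fate == "neural"

    def test_sustained_sox17_excluded_as_endoderm(self):
        forest = self._linear([100] * 5, [600, 700, 800, 100, 100])
        assert classify_cell_fate(forest, 4, RULES).fate == "endoderm_excluded"

    def test_lost_track_is_unassigned(self):
        forest = self._linear([100, 100, 100], t_max_pad=6)
        assert classify_cell_fate(forest, 2, RULES).fate == "unassigned"

    def test_missing_channel_is_error(self):
        nodes = {0: CellNode(0, None, 0, [0, 0, 0], {"mezzo": 1.0})}
        forest = LineageForest(nodes)
        with pytest.raises(ValueError, match="sox17"):
            classify_cell_fate(forest, 0, RULES)


class TestTerminalDivisions:
    def _division_forest(self):
        # root chain -> division at t=2 -> mesoderm child + neural child
        nodes = {
            0: _node(0, None, 0, [0, 0, 0]),
            1: _node(1, 0, 1, [0, 0, 0]),
        }
        for t, nid, mez in ((2, 2, 800), (3, 4, 900), (4, 6, 850)):
            nodes[nid] = _node(nid, nid - 2 if nid > 2 else 1, t, [1, 0, 0], mez)
        for t, nid in ((2, 3), (3, 5), (4, 7)):
            nodes[nid] = _node(nid, nid - 2 if nid > 3 else 1, t, [-1, 0, 0])
        return LineageForest(nodes)

    def test_mixed_division_scored_nm(self):
        forest = self._division_forest()
        sel = ClonalSelection([0], set(forest.nodes), 0, None)
        calls = classify_selection_fates(forest, sel, RULES)
        summary = terminal_division_fates(forest, sel, calls)
        assert summary.class_counts["N/M"] == 1
        assert summary.divisions_per_track[1] == 1
        assert summary.bifated_fraction == 1.0

    def test_only_last_division_of_chain_is_terminal(self):
        nodes = {
            0: _node(0, None, 0, [0, 0, 0]),
        }
        # first division at t=1
        nodes[1] = _node(1, 0, 1, [1, 0, 0])
        nodes[2] = _node(2, 0, 1, [-1, 0, 0])
        # second division (on child 1) at t=2
        nodes[3] = _node(3, 1, 2, [1, 1, 0], 800)
        nodes[4] = _node(4, 1, 2, [1, -1, 0], 900)
        nodes[5] = _node(5, 2, 2, [-1, 0, 0])
        # extend tracks to t=3 so fates resolve
        nodes[6] = _node(6, 3, 3, [1, 1, 0], 800)
        nodes[7] = _node(7, 4, 3, [1, -1, 0], 900)
        nodes[8] = _node(8, 5, 3, [-1, 0, 0])
        forest = LineageForest(nodes)
        sel = ClonalSelection([0], set(forest.nodes), 0, None)
        rules = FateRules(500, 500, k_frames=2)
        calls = classify_selection_fates(forest, sel, rules)
        summary = terminal_division_fates(forest, sel, calls)
        assert summary.n_terminal_divisions == 1  # only the second division
        assert summary.class_counts["M/M"] == 1
        assert summary.divisions_per_track[2] == 1


class TestLabelRules:
    @pytest.mark.parametrize(
        "n, m, expected",
        [(95, 5, "neural"), (9, 91, "mesoderm"), (50, 50, "both"),
         (90, 10, "both"), (950, 50, "neural"), (10, 990, "mesoderm")],
    )
    def test_ninety_percent_rule(self, n, m, expected):
        assert classify_label(n, m) == expected

    def test_scale_invariance(self):
        for n, m in [(3, 97), (45, 55), (91, 9)]:
            assert classify_label(n, m) == classify_label(10 * n, 10 * m)

    def test_empty_label_is_error(self):
        with pytest.raises(ValueError):
            classify_label(0, 0)


class TestPolarPlacement:
    CENTER = np.zeros(3)
    AP = np.array([0, 0, 1.0])
    SHIELD = np.array([1.0, 0, 0])

    def test_label_at_animal_pole(self):
        arc, azim = label_polar_position(self.AP, self.AP, self.SHIELD,
                                         self.CENTER)
        assert arc == pytest.approx(0.0)
        assert math.isnan(azim)

    def test_label_on_shield_meridian(self):
        label = np.array([1.0, 0, 1.0])
        arc, azim = label_polar_position(label, self.AP, self.SHIELD,
                                         self.CENTER)
        assert azim == pytest.approx(0.0, abs=1e-9)
        assert arc == pytest.approx(45.0)

    def test_antipodal_meridian_at_equator(self):
        label = np.array([-1.0, 0, 0])
        arc, azim = label_polar_position(label, self.AP, self.SHIELD,
                                         self.CENTER)
        assert arc == pytest.approx(90.0)
        assert abs(azim) == pytest.approx(180.0)


class TestAPContribution:
    def test_spans_match_occupied_segments(self):
        cells = [(s, "somite") for s in range(25, 32)] + \
            [(s, "neural") for s in range(23, 32)]
        out = ap_contribution(cells, n_segments=32)
        assert out["spans"]["somite"] == (25, 31)
        assert out["spans"]["neural"] == (23, 31)
        assert out["somite"].sum() == 7 and out["neural"].sum() == 9

    def test_empty_input_gives_zero_vectors(self):
        out = ap_contribution([], n_segments=10)
        assert out["neural"].sum() == 0 and out["somite"].sum() == 0
        assert out["spans"]["neural"] is None

    def test_out_of_range_segment_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            ap_contribution([(33, "neural")], n_segments=32)


class TestFoldChange:
    def test_values(self):
        assert clone_fold_change(10, 20) == pytest.approx(2.0)
        assert clone_fold_change(10, 10) == pytest.approx(1.0)

    def test_zero_start_is_error(self):
        with pytest.raises(ValueError):
            clone_fold_change(0, 5)


class TestZoneAssignment:
    def _forest_sorted(self, n=10):
        # tracks start sorted along x; terminal position determines zone
        nodes = {}
        nid = 0
        for i in range(n):
            # two spatially separated blocks of starting positions
            x = float(i) if i < n // 2 else 1000.0 + i
            nodes[nid] = _node(nid, None, 0, [x, 0, 0])
            term = nid + 1
            # low-x cells end in the neural zone, high-x in the mesoderm zone
            zx = 0.0 if i < n // 2 else 100.0
            nodes[term] = _node(term, nid, 1, [zx, 0, 0])
            nid += 2
        return LineageForest(nodes)

    def _zones(self):
        return {
            "neural": Box([-10, -10, -10], [10, 10, 10]),
            "mesoderm": Box([90, -10, -10], [110, 10, 10]),
            "unassigned": Box([40, -10, -10], [60, 10, 10]),
        }

    def test_terminal_zone_determines_fate(self):
        forest = self._forest_sorted()
        sel = ClonalSelection(forest.roots(), set(forest.nodes), 0, None)
        out = zone_assign(forest, sel, self._zones())
        fates = [r["fate"] for r in out["assignments"]]
        assert fates[:5] == ["neural"] * 5
        assert fates[5:] == ["mesoderm"] * 5

    def test_sox2_tbxta_zone_maps_to_unassigned(self):
        nodes = {
            0: _node(0, None, 0, [0, 0, 0]),
            1: _node(1, 0, 1, [50, 0, 0]),
        }
        forest = LineageForest(nodes)
        sel = ClonalSelection([0], {0, 1}, 0, None)
        out = zone_assign(forest, sel, self._zones())
        assert out["assignments"][0]["fate"] == "unassigned"

    def test_outside_all_zones_is_other_with_warning(self, caplog):
        nodes = {
            0: _node(0, None, 0, [0, 0, 0]),
            1: _node(1, 0, 1, [999, 0, 0]),
        }
        forest = LineageForest(nodes)
        sel = ClonalSelection([0], {0, 1}, 0, None)
        with caplog.at_level("WARNING"):
            out = zone_assign(forest, sel, self._zones())
        assert out["assignments"][0]["fate"] == "other"
        assert "outside all zones" in caplog.text

    def test_fully_sorted_layout_has_unit_mixing(self):
        forest = self._forest_sorted(n=12)
        sel = ClonalSelection(forest.roots(), set(forest.nodes), 0, None)
        out = zone_assign(forest, sel, self._zones(), k_neighbors=3)
        assert out["mixing"]["neural"] == pytest.approx(1.0)
        assert out["mixing"]["mesoderm"] == pytest.approx(1.0)
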