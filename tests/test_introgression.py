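"""Marker harmonization, missingness filtering, parent-difference calls,
segment merging, and end-to-end recovery of planted introgression."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import brassipool as bp
from brassipool import introgression as intro

from conftest import toy_locus_info, toy_matrix


def marker_frame(rows):
    return pd.DataFrame(rows, columns=["marker", "source", "genome", "chrom",
                                       "pos"])


class TestHarmonize:
    def test_hand_tally(self):
        nap = marker_frame([(f"N{i}", "napus_AC", "A", "A01", 100 * i)
                            for i in range(1, 4)])
        alt = marker_frame([(f"R{i}", "rapa_A", "A", "A01", 100 * i)
                            for i in range(1, 6)])
        match = pd.DataFrame({"alt_marker": ["R1", "R2", "R3", "R4", "R5"],
                              "napus_marker": ["N1", "N2", "N3", None, None]})
        out = intro.harmonize_marker_sets(nap, alt, match)
        assert out.counts["alt_matched"] == 3
        assert out.counts["additional_specific"] == 2
        assert len(out.markers) == 5
        assert out.markers["species_specific"].sum() == 2

    def test_empty_alt_set(self):
        nap = marker_frame([("N1", "napus_AC", "A", "A01", 1)])
        alt = marker_frame([])
        match = pd.DataFrame({"alt_marker": [], "napus_marker": []})
        out = intro.harmonize_marker_sets(nap, alt, match)
        assert len(out.markers) == 1
        assert out.counts["additional_specific"] == 0

    def test_all_matched_leaves_no_additional(self):
        nap = marker_frame([("N1", "napus_AC", "A", "A01", 1)])
        alt = marker_frame([("R1", "rapa_A", "A", "A01", 1)])
        match = pd.DataFrame({"alt_marker": ["R1"], "napus_marker": ["N1"]})
        out = intro.harmonize_marker_sets(nap, alt, match)
        assert out.counts["additional_specific"] == 0

    def test_ambiguous_match_excluded(self):
        nap = marker_frame([("N1", "napus_AC", "A", "A01", 1),
                            ("N2", "napus_AC", "A", "A01", 2)])
        alt = marker_frame([("R1", "rapa_A", "A", "A01", 1)])
        match = pd.DataFrame({"alt_marker": ["R1", "R1"],
                              "napus_marker": ["N1", "N2"]})
        out = intro.harmonize_marker_sets(nap, alt, match)
        assert out.counts["alt_ambiguous"] == 1
        assert out.counts["additional_specific"] == 0
        assert list(out.markers["marker"]) == ["N1", "N2"]


def b_matrix(trad_calls, dh_calls):
    """Matrix with one B marker; calls are dicts sample -> allele or None."""
    info = toy_locus_info([("B04:100", "B", "B04", 100)])
    cells, taxa = [], {}
    for s, a in {**trad_calls, **dh_calls}.items():
        cells.append((s, "B04:100", "B04:100", a, a))
        taxa[s] = "T_napus" if s in trad_calls else "new_type"
    return toy_matrix(cells, locus_info=info, taxa=taxa)


class TestFlagBGenome:
    def test_all_traditional_missing_is_flagged(self):
        trad = {f"T{i}": None for i in range(11)}
        dh = {f"D{i}": "x" for i in range(3)}
        gm = b_matrix(trad, dh)
        assert intro.flag_b_genome_markers(gm, list(trad)) == {"B04:100"}

    def test_one_traditional_call_unflags(self):
        trad = {f"T{i}": (None if i else "x") for i in range(11)}
        gm = b_matrix(trad, {"D1": "x"})
        assert intro.flag_b_genome_markers(gm, list(trad)) == set()

    def test_empty_panel_rejected(self):
        gm = b_matrix({"T1": None}, {"D1": "x"})
        with pytest.raises(bp.SchemaError):
            intro.flag_b_genome_markers(gm, [])

    def test_planted_b_segments_are_flagged(self, genome_model):
        panel = bp.make_founders(genome_model, bp.DiversityConfig(), seed=81)
        pop, _ = bp.make_planted_dh_panel(panel, genome_model,
                                          [0.4, 0.5], seed=82,
                                          n_b_segments=3)
        markers = bp.make_marker_panel(genome_model, frac_dual_ac=0,
                                       frac_ab=0, seed=83)
        g = bp.genotype_markers(pop, markers, 0.0, 84)
        flagged = intro.flag_b_genome_markers(g, ["HS3"])
        inside = set()
        for ind in pop.individuals:
            for chrom, segs in ind.b_segments.items():
                for m in markers:
                    l = m.loci[0]
                    if l.chrom == chrom and any(s <= l.pos <= e
                                                for s, e, _ in segs):
                        inside.add(l.locus_id)
        assert inside <= flagged


class TestFilterMissing:
    def _matrix(self, missing_per_marker):
        """10 samples; marker Mi missing in the first k_i samples."""
        cells = []
        info_rows = []
        for i, k in enumerate(missing_per_marker):
            locus = f"A01:{100 + i}"
            info_rows.append((locus, "A", "A01", 100 + i))
            for s in range(10):
                a = None if s < k else "x"
                cells.append((f"s{s}", locus, locus, a, a))
        return toy_matrix(cells, locus_info=toy_locus_info(info_rows))

    def test_exact_half_removed_strict_boundary(self):
        gm = self._matrix([5])
        assert intro.filter_missing(gm, 0.5).loci == []

    def test_threshold_one_keeps_everything(self):
        gm = self._matrix([10, 5, 0])
        assert len(intro.filter_missing(gm, 1.0).loci) == 3

    def test_hand_count(self):
        ks = [0, 1, 2, 3, 4, 4, 4, 3, 2, 1, 0, 2, 4,
              5, 6, 7, 8, 9, 10, 10]
        gm = self._matrix(ks)
        kept = intro.filter_missing(gm, 0.5)
        assert len(kept.loci) == sum(1 for k in ks if k < 5) == 13

    def test_idempotent_and_monotone(self):
        gm = self._matrix([0, 2, 4, 6, 8])
        once = intro.filter_missing(gm, 0.5)
        twice = intro.filter_missing(once, 0.5)
        assert once.loci == twice.loci
        sizes = [len(intro.filter_missing(gm, t).loci)
                 for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes)

    def test_invalid_threshold(self):
        gm = self._matrix([0])
        with pytest.raises(bp.ConfigurationError):
            intro.filter_missing(gm, 0.0)


def track_matrix(parent_gt, line_gts, positions=None):
    """One-chromosome matrix: parent 'HS3' plus lines with given genotypes."""
    loci = sorted(parent_gt)
    positions = positions or {l: 100 + i for i, l in enumerate(loci)}
    info = toy_locus_info([(l, "A", "A01", positions[l]) for l in loci])
    cells = []
    taxa = {"HS3": "T_napus"}
    for l in loci:
        a = parent_gt[l]
        cells.append(("HS3", l, l, a, a))
    for line, gts in line_gts.items():
        taxa[line] = "new_type"
        for l in loci:
            a = gts.get(l)
            cells.append((line, l, l, a, a))
    return toy_matrix(cells, locus_info=info, taxa=taxa)


class TestCallVsParent:
    def test_identical_line_has_zero_fraction(self):
        gm = track_matrix({"L1": "a", "L2": "b"},
                          {"D1": {"L1": "a", "L2": "b"}})
        track = intro.call_vs_parent(gm, "HS3")
        assert track.per_line_fraction["D1"] == 0.0
        assert track.union_fraction == 0.0

    def test_fraction_excludes_missing(self):
        gm = track_matrix({"L1": "a", "L2": "a", "L3": "a", "L4": "a"},
                          {"D1": {"L1": "x", "L2": "a", "L3": None,
                                  "L4": "x"}})
        track = intro.call_vs_parent(gm, "HS3")
        assert track.per_line_fraction["D1"] == pytest.approx(2 / 3)

    def test_heterozygous_call_differs_from_homozygous_parent(self):
        info = toy_locus_info([("L1", "A", "A01", 100)])
        gm = toy_matrix([("HS3", "L1", "L1", "a", "a"),
                         ("D1", "L1", "L1", "a", "b")], locus_info=info,
                        taxa={"HS3": "T_napus", "D1": "new_type"})
        track = intro.call_vs_parent(gm, "HS3")
        assert track.per_line_fraction["D1"] == 1.0

    def test_union_bounds_per_line(self):
        gm = track_matrix(
            {"L1": "a", "L2": "a", "L3": "a"},
            {"D1": {"L1": "x", "L2": "a", "L3": "a"},
             "D2": {"L1": "a", "L2": "x", "L3": "a"}})
        track = intro.call_vs_parent(gm, "HS3")
        frac = track.per_line_fraction
        assert track.union_fraction == pytest.approx(2 / 3)
        assert (track.union_fraction >= frac - 1e-12).all()

    def test_single_line_union_equals_fraction(self):
        gm = track_matrix({"L1": "a", "L2": "a"},
                          {"D1": {"L1": "x", "L2": "a"}})
        track = intro.call_vs_parent(gm, "HS3")
        assert track.union_fraction == pytest.approx(
            track.per_line_fraction["D1"])

    def test_unknown_or_blank_parent_rejected(self):
        gm = track_matrix({"L1": "a"}, {"D1": {"L1": "a"}})
        with pytest.raises(bp.SchemaError):
            intro.call_vs_parent(gm, "nope")
        blank = track_matrix({"L1": None}, {"D1": {"L1": "a"}})
        with pytest.raises(bp.SchemaError):
            intro.call_vs_parent(blank, "HS3")


class TestMergeSegments:
    def test_printed_b04_interval_length(self):
        """Markers spanning 3,563,715-3,723,750 on B04 merge to ~160 kb."""
        positions = [3_563_715, 3_600_000, 3_650_000, 3_723_750]
        info = toy_locus_info([(f"B04:{p}", "B", "B04", p) for p in positions])
        cells = [("HS3", f"B04:{p}", f"B04:{p}", "r", "r") for p in positions]
        cells += [("D1", f"B04:{p}", f"B04:{p}", "x", "x") for p in positions]
        gm = toy_matrix(cells, locus_info=info,
                        taxa={"HS3": "T_napus", "D1": "new_type"})
        track = intro.call_vs_parent(gm, "HS3")
        (seg,) = intro.merge_segments(track)
        assert (seg.start, seg.end) == (3_563_715, 3_723_750)
        assert seg.length_bp == 160_035
        assert seg.length_kb == pytest.approx(160.0, abs=0.5)
        assert seg.n_markers == 4

    def test_isolated_marker_makes_single_marker_segment(self):
        gm = track_matrix({"L1": "a", "L2": "a", "L3": "a"},
                          {"D1": {"L1": "a", "L2": "x", "L3": "a"}})
        segs = intro.merge_segments(intro.call_vs_parent(gm, "HS3"))
        assert len(segs) == 1 and segs[0].n_markers == 1
        assert segs[0].start == segs[0].end

    def test_gap_splits_clusters(self):
        parent = {f"L{i}": "a" for i in range(1, 8)}
        line = {f"L{i}": "x" for i in (1, 2, 6, 7)}
        line.update({f"L{i}": "a" for i in (3, 4, 5)})
        gm = track_matrix(parent, {"D1": line})
        track = intro.call_vs_parent(gm, "HS3")
        assert len(intro.merge_segments(track, max_gap_markers=0)) == 2
        assert len(intro.merge_segments(track, max_gap_markers=2)) == 2
        assert len(intro.merge_segments(track, max_gap_markers=3)) == 1

    def test_every_differs_call_covered_once_at_zero_gap(self, genome_model):
        panel = bp.make_founders(genome_model,
                                 bp.DiversityConfig(private_proportion=1.0,
                                                    novel_rate=0.0), seed=91)
        pop, _ = bp.make_planted_dh_panel(panel, genome_model, [0.4], seed=92)
        markers = bp.make_marker_panel(genome_model, frac_dual_ac=0,
                                       frac_ab=0, seed=93)
        g = bp.genotype_markers(pop, markers, 0.0, 94)
        track = intro.call_vs_parent(g, "HS3")
        segs = intro.merge_segments(track, max_gap_markers=0)
        covered = {}
        pos = track.positions
        for s in segs:
            for l in track.states.columns:
                if (pos.loc[l, "chrom"] == s.chrom
                        and s.start <= pos.loc[l, "pos"] <= s.end):
                    covered[l] = covered.get(l, 0) + 1
        differs = track.states.loc["DH001"]
        for l in track.states.columns:
            if differs[l] == intro.DIFFERS:
                assert covered.get(l, 0) == 1

    def test_unsorted_positions_rejected(self):
        gm = track_matrix({"L1": "a", "L2": "a"}, {"D1": {"L1": "x",
                                                          "L2": "x"}})
        track = intro.call_vs_parent(gm, "HS3")
        track.positions = track.positions.iloc[::-1]
        with pytest.raises(bp.SchemaError):
            intro.merge_segments(track)


class TestEndToEndRecovery:
    def test_planted_fractions_recovered(self, genome_model):
        """Per-line estimates within 0.05 of truth; union dominates."""
        panel = bp.make_founders(genome_model,
                                 bp.DiversityConfig(private_proportion=1.0,
                                                    novel_rate=0.0), seed=95)
        fractions = [0.30, 0.40, 0.50, 0.65]
        pop, truth = bp.make_planted_dh_panel(panel, genome_model, fractions,
                                              seed=96)
        markers = bp.make_marker_panel(genome_model, frac_dual_ac=0,
                                       frac_ab=0, seed=97)
        g = bp.genotype_markers(pop, markers, 0.0, 98)
        track = intro.call_vs_parent(intro.filter_missing(g), "HS3")
        est = track.per_line_fraction
        for line in truth.index:
            assert abs(est[line] - truth[line]) < 0.05, line
        assert track.union_fraction > est.max()

    def test_planted_b_boundaries_recovered(self, genome_model):
        panel = bp.make_founders(genome_model,
                                 bp.DiversityConfig(private_proportion=1.0,
                                                    novel_rate=0.0), seed=99)
        pop, _ = bp.make_planted_dh_panel(panel, genome_model, [0.5], seed=100,
                                          n_b_segments=4)
        markers = bp.make_marker_panel(genome_model, frac_dual_ac=0,
                                       frac_ab=0, seed=101)
        g = bp.genotype_markers(pop, markers, 0.0, 102)
        flagged = intro.flag_b_genome_markers(g, ["HS3"])
        track = intro.call_vs_parent(g, "HS3")
        segs = [s for s in intro.merge_segments(track, b_flags=flagged)
                if s.chrom.startswith("B") and s.line == "DH001"]
        line = pop.by_id("DH001")
        info = g.locus_info
        for chrom, planted in line.b_segments.items():
            b_pos = sorted(info[info["chrom"] == chrom]["pos"])
            for start, end, _ in planted:
                inside = [p for p in b_pos if start <= p <= end]
                if not inside:
                    continue    # segment falls between markers, undetectable
                hits = [s for s in segs if s.chrom == chrom
                        and s.start <= inside[0] and s.end >= inside[-1]]
                assert hits, (chrom, start, end)
                # recovered endpoints within one marker interval of truth
                seg = hits[0]
                lower = max([p for p in b_pos if p < seg.start], default=0)
                upper = min([p for p in b_pos if p > seg.end],
                            default=10**12)
                assert lower < start <= seg.start or seg.start == inside[0]
                assert seg.end <= end < upper or seg.end == inside[-1]


class TestSummaryFrame:
    def test_summary_contains_union_row(self):
        gm = track_matrix({"L1": "a", "L2": "a"},
                          {"D1": {"L1": "x", "L2": "a"},
                           "D2": {"L1": "a", "L2": "x"}})
        track = intro.call_vs_parent(gm, "HS3")
        summary = intro.introgression_summary(track)
        assert summary.loc["UNION", "fraction_differing"] == pytest.approx(1.0)
        assert set(summary.index) == {"D1", "D2", "UNION"}
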