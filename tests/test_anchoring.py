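"""Probe placement, misassembly detection against the map, scaffold
ordering/orientation, gap estimation and AGP/FASTA round-trip."""

import re

import numpy as np
import pytest

from vigmap import agp as agp_mod
from vigmap import anchoring as anch
from vigmap.linkage import GeneticMap
from vigmap.seqs import SequenceSet, revcomp
from tests.conftest import random_seq


def probe_at(seq, pos, marker_id="M1", alt="T"):
    window = seq[pos - 60 : pos + 61]
    ref = seq[pos]
    alt = "ACGT".replace(ref, "")[0]
    return anch.Probe(marker_id, window, ref, alt)


class TestPlaceProbes:
    def test_planted_probe_found_once(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 5000)
        p = probe_at(seq, 1234)
        (pl,) = anch.place_probes([p], SequenceSet([("s1", seq)]))
        assert (pl.scaffold_id, pl.position, pl.n_hits, pl.usable) == ("s1", 1234, 1, True)

    def test_reverse_strand_position(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 5000)
        p = probe_at(seq, 2000)
        (pl,) = anch.place_probes([p], SequenceSet([("s1", revcomp(seq))]))
        assert pl.position == len(seq) - 1 - 2000
        assert pl.usable

    def test_alternate_allele_variant_matches(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 3000)
        p = probe_at(seq, 1500)
        mutated = seq[:1500] + p.allele_b + seq[1501:]
        (pl,) = anch.place_probes([p], SequenceSet([("s1", mutated)]))
        assert pl.n_hits == 1 and pl.position == 1500

    def test_duplicated_probe_unusable(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 4000)
        p = probe_at(seq, 700)
        dup = seq + seq[700 - 60 : 700 + 61]
        (pl,) = anch.place_probes([p], SequenceSet([("s1", dup)]))
        assert pl.n_hits == 2 and not pl.usable

    def test_absent_probe_zero_hits(self):
        rng = np.random.default_rng(4)
        p = probe_at(random_seq(rng, 2000), 1000)
        (pl,) = anch.place_probes([p], SequenceSet([("s1", random_seq(rng, 2000))]))
        assert pl.n_hits == 0 and not pl.usable

    def test_planted_recovery_full_set(self, default_truth, default_placements):
        by_id = {p.marker_id: p for p in default_placements}
        assert all(p.usable for p in default_placements)
        # positions must agree with the scaffold truth mapping
        for s in default_truth.scaffold_truth:
            if s.defect is not None:
                continue
            (lg, start, end, _strand) = s.parts[0]
            length = end - start
            for m in default_truth.markers:
                if m.lg != lg or not (start <= m.pos < end):
                    continue
                pl = by_id[m.marker_id]
                assert pl.scaffold_id == s.scaffold_id
                expect = m.pos - start
                if s.flipped:
                    expect = length - 1 - expect
                assert pl.position == expect


def simple_map():
    return GeneticMap([
        ("LG1", [("a", 0.0), ("b", 2.0), ("c", 4.0), ("d", 6.0)]),
        ("LG2", [("x", 0.0), ("y", 3.0)]),
    ])


def placement(marker, scaffold, pos):
    return anch.MarkerPlacement(marker, scaffold, pos, 1, True)


class TestDetectContradictions:
    def test_monotone_is_clean(self):
        pls = [placement("a", "s", 100), placement("b", "s", 500),
               placement("c", "s", 900)]
        assert anch.detect_contradictions(pls, simple_map()) == []

    def test_descending_is_clean(self):
        pls = [placement("c", "s", 100), placement("b", "s", 500),
               placement("a", "s", 900)]
        assert anch.detect_contradictions(pls, simple_map()) == []

    def test_shuffled_order_conflict(self):
        # cM sequence 2, 0, 4 in physical order
        pls = [placement("b", "s", 100), placement("a", "s", 500),
               placement("c", "s", 900)]
        (rec,) = anch.detect_contradictions(pls, simple_map())
        assert rec.kind == "order_conflict" and rec.scaffold_id == "s"

    def test_two_lgs_is_chimera(self):
        pls = [placement("a", "s", 100), placement("x", "s", 900)]
        (rec,) = anch.detect_contradictions(pls, simple_map())
        assert rec.kind == "inter_lg_chimera"
        assert {e[2] for e in rec.evidence} == {"LG1", "LG2"}

    def test_unusable_placements_ignored(self):
        pls = [placement("a", "s", 100),
               anch.MarkerPlacement("x", "s", 900, 2, True)]
        assert anch.detect_contradictions(pls, simple_map()) == []

    def test_planted_defects_full_recall_no_false_positives(
        self, defect_truth, defect_placements
    ):
        recs = anch.detect_contradictions(
            defect_placements, defect_truth.truth_map()
        )
        expected_chim = {s for s, k in defect_truth.defect_log()
                        if k == "inter_lg_chimera"}
        expected_inv = {s for s, k in defect_truth.defect_log() if k == "inversion"}
        got_chim = {r.scaffold_id for r in recs if r.kind == "inter_lg_chimera"}
        got_conf = {r.scaffold_id for r in recs if r.kind == "order_conflict"}
        assert got_chim == expected_chim  # 12 planted
        assert got_conf == expected_inv  # 8 planted
        assert len(expected_chim) == 12 and len(expected_inv) == 8

    def test_clean_fragmentation_no_records(self, default_truth, default_placements):
        recs = anch.detect_contradictions(
            default_placements, default_truth.truth_map()
        )
        assert recs == []


class TestAnchor:
    def test_single_marker_orientation_unknown(self):
        seqs = SequenceSet([("s", "ACGT" * 2500)])
        plan = anch.anchor([placement("a", "s", 100)], simple_map(), seqs)
        (entry,) = plan.lgs["LG1"]
        assert entry.orientation == "?"

    def test_single_marker_uses_synteny_hint(self):
        seqs = SequenceSet([("s", "ACGT" * 2500)])
        plan = anch.anchor(
            [placement("a", "s", 100)], simple_map(), seqs, {"s": "-"}
        )
        assert plan.lgs["LG1"][0].orientation == "-"

    def test_reversed_correlation_minus(self):
        seqs = SequenceSet([("s", "A" * 1_000_000)])
        pls = [placement("c", "s", 10_000), placement("b", "s", 900_000)]
        plan = anch.anchor(pls, simple_map(), seqs)
        assert plan.lgs["LG1"][0].orientation == "-"

    def test_chimera_reaching_anchor_errors(self):
        seqs = SequenceSet([("s", "A" * 1000)])
        pls = [placement("a", "s", 10), placement("x", "s", 900)]
        with pytest.raises(ValueError, match="unresolved chimera"):
            anch.anchor(pls, simple_map(), seqs)

    def test_order_and_orientation_recovery(self, default_truth, default_placements):
        """Multi-marker scaffolds get their true orientation; the scaffold
        order along each LG matches the source coordinates exactly."""
        truth = default_truth
        plan = anch.anchor(
            default_placements, truth.truth_map(), truth.scaffolds
        )
        truth_by_id = {s.scaffold_id: s for s in truth.scaffold_truth}
        n_multi = n_correct = 0
        for lg, entries in plan.lgs.items():
            starts = []
            for e in entries:
                st = truth_by_id[e.scaffold_id]
                assert st.parts[0][0] == lg
                starts.append(st.parts[0][1])
                if len({round(cm, 2) for _, _, cm in e.markers}) >= 2:
                    n_multi += 1
                    n_correct += e.orientation == ("-" if st.flipped else "+")
            assert starts == sorted(starts)  # Kendall tau = 1.0
        assert n_multi > 0
        assert n_correct / n_multi >= 0.95


def entry(sid, lg, markers, length, orientation="+"):
    return anch.AnchoredScaffold(
        scaffold_id=sid, lg=lg, orientation=orientation, markers=markers,
        length=length, median_cm=float(np.median([c for *_, c in markers])),
    )


class TestEstimateGap:
    def test_stated_arithmetic(self):
        # 0.5 cM interval at 900 kb/cM, 150 kb of overhang in total
        left = entry("L", "LG1", [("a", 50_000, 1.0)], 150_000)
        right = entry("R", "LG1", [("b", 50_000, 1.5)], 300_000)
        # left overhang = 150000-1-50000 = 99999; right overhang = 50000
        expect = round(0.5 * 900_000 - 99_999 - 50_000)
        assert anch.estimate_gap(left, right, 900_000) == expect

    def test_tied_markers_sentinel(self):
        left = entry("L", "LG1", [("a", 900, 2.0)], 1000)
        right = entry("R", "LG1", [("b", 100, 2.0)], 1000)
        assert anch.estimate_gap(left, right, 900_000) == 1000

    def test_negative_result_sentinel(self):
        left = entry("L", "LG1", [("a", 0, 1.0)], 500_000)
        right = entry("R", "LG1", [("b", 400_000, 1.1)], 500_000)
        assert anch.estimate_gap(left, right, 900_000) == 1000

    def test_minimum_gap_clamp(self):
        left = entry("L", "LG1", [("a", 989, 1.0)], 1000)
        right = entry("R", "LG1", [("b", 10, 1.01)], 1000)
        # 0.01 cM * 900k = 9000 - 10 - 10 = 8980 -> fine; shrink interval
        assert anch.estimate_gap(left, right, 2000) >= 100

    def test_orientation_affects_overhang(self):
        # '-' scaffold: marker near position 0 sits near the emitted end
        left = entry("L", "LG1", [("a", 100, 1.0)], 100_000, orientation="-")
        right = entry("R", "LG1", [("b", 50, 1.5)], 100_000)
        gap = anch.estimate_gap(left, right, 900_000)
        assert gap == round(0.5 * 900_000 - 100 - 50)

    def test_dropped_scaffold_gap_approximates_truth(self, default_truth,
                                                     default_placements):
        """Removing an interior scaffold from the plan leaves a gap whose
        estimate approximates the dropped length."""
        truth = default_truth
        plan = anch.anchor(default_placements, truth.truth_map(),
                           truth.scaffolds, truth.synteny_hints())
        bp_per_cm = 1e6 / truth.config.cm_per_mb
        rel_errors = []
        for lg, entries in plan.lgs.items():
            if len(entries) < 3:
                continue
            for k in range(1, len(entries) - 1):
                dropped = truth.scaffolds[entries[k].scaffold_id]
                est = anch.estimate_gap(entries[k - 1], entries[k + 1], bp_per_cm)
                if est in (1000,):
                    continue
                rel_errors.append(abs(est - len(dropped)) / len(dropped))
        assert rel_errors, "no estimable dropped-scaffold gaps"
        assert float(np.median(rel_errors)) < 0.5


class TestBuildPseudomolecules:
    def test_two_scaffolds_with_sentinel_gap(self):
        rng = np.random.default_rng(9)
        seqs = SequenceSet([("s1", random_seq(rng, 100)), ("s2", random_seq(rng, 200))])
        plan = anch.AnchorPlan(lgs={"LG1": [
            entry("s1", "LG1", [("a", 50, 1.0)], 100),
            entry("s2", "LG1", [("b", 50, 1.0)], 200),
        ]})
        psmol, rows = anch.build_pseudomolecules(plan, seqs, 900_000)
        assert len(psmol["LG1"]) == 100 + 1000 + 200
        assert psmol["LG1"][100:1100] == "N" * 1000
        gap_rows = [r for r in rows if r.component_type in "NU"]
        assert gap_rows[0].component_type == "U"

    def test_reverse_oriented_component(self):
        rng = np.random.default_rng(10)
        s1, s2 = random_seq(rng, 300), random_seq(rng, 400)
        seqs = SequenceSet([("s1", s1), ("s2", s2)])
        plan = anch.AnchorPlan(lgs={"LG1": [
            entry("s1", "LG1", [("a", 150, 1.0)], 300, orientation="-"),
            entry("s2", "LG1", [("b", 200, 1.0)], 400),
        ]})
        psmol, rows = anch.build_pseudomolecules(plan, seqs, 900_000)
        assert psmol["LG1"].startswith(revcomp(s1))
        assert rows[0].orientation == "-"

    def test_agp_round_trip_byte_identity(self, tmp_path, default_truth,
                                          default_placements):
        truth = default_truth
        plan = anch.anchor(default_placements, truth.truth_map(),
                           truth.scaffolds, truth.synteny_hints())
        bp_per_cm = 1e6 / truth.config.cm_per_mb
        psmol, rows = anch.build_pseudomolecules(plan, truth.scaffolds, bp_per_cm)
        path = tmp_path / "out.agp"
        agp_mod.write_agp(rows, path)
        rebuilt = agp_mod.rebuild_fasta(agp_mod.read_agp(path), truth.scaffolds)
        assert rebuilt.ids == psmol.ids
        for sid in psmol.ids:
            assert rebuilt[sid] == psmol[sid]

    def test_round_trip_to_source_genome(self, default_truth, default_placements):
        """A clean fragmentation re-anchors into the source chromosomes,
        up to the estimated-N gap runs."""
        truth = default_truth
        plan = anch.anchor(default_placements, truth.truth_map(),
                           truth.scaffolds, truth.synteny_hints())
        psmol, _ = anch.build_pseudomolecules(
            plan, truth.scaffolds, 1e6 / truth.config.cm_per_mb
        )
        for lg in truth.genome.ids:
            assert re.sub("N+", "", psmol[lg]) == truth.genome[lg]

    def test_reanchoring_pseudomolecules_is_clean(self, default_truth,
                                                  default_placements):
        truth = default_truth
        plan = anch.anchor(default_placements, truth.truth_map(),
                           truth.scaffolds, truth.synteny_hints())
        psmol, _ = anch.build_pseudomolecules(
            plan, truth.scaffolds, 1e6 / truth.config.cm_per_mb
        )
        pls2 = anch.place_probes(truth.probes(), psmol)
        assert anch.detect_contradictions(pls2, truth.truth_map()) == []
        plan2 = anch.anchor(pls2, truth.truth_map(), psmol)
        for lg, entries in plan2.lgs.items():
            assert [e.scaffold_id for e in entries] == [lg]

    def test_anchored_total_within_assembly(self, default_truth, default_placements):
        truth = default_truth
        plan = anch.anchor(default_placements, truth.truth_map(), truth.scaffolds)
        anchored_bp = sum(
            len(truth.scaffolds[s]) for s in plan.all_anchored_ids()
        )
        assert anchored_bp <= truth.scaffolds.total_bp
        ids = plan.all_anchored_ids()
        assert len(ids) == len(set(ids))


class TestRelabelGroups:
    def test_majority_vote(self):
        plan = anch.AnchorPlan(lgs={"LG1": [
            entry("s", "LG1", [(f"m{i}", i * 100, float(i)) for i in range(5)], 1000)
        ]})
        ref = {f"m{i}": "chr2" for i in range(4)}
        ref["m4"] = "chr7"
        out, warnings = anch.relabel_groups(plan, ref)
        assert list(out.lgs) == ["chr2"]
        assert any("minority" in w for w in warnings)

    def test_no_overlap_keeps_name(self):
        plan = anch.AnchorPlan(lgs={"LG1": [
            entry("s", "LG1", [("m1", 100, 1.0)], 1000)
        ]})
        out, warnings = anch.relabel_groups(plan, {"other": "chr1"})
        assert list(out.lgs) == ["LG1"]
        assert warnings

    def test_synthetic_relabeling_all_correct(self, default_truth,
                                              default_placements):
        truth = default_truth
        plan = anch.anchor(default_placements, truth.truth_map(), truth.scaffolds)
        ref = {m.marker_id: m.lg.replace("LG", "chr") for m in truth.markers}
        out, _ = anch.relabel_groups(plan, ref)
        assert sorted(out.lgs) == sorted(
            lg.replace("LG", "chr") for lg in truth.genome.ids
        )
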