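"""Variant filtering: Fisher strand-bias against scipy and enumeration,
threshold gates at their boundaries, planted-truth marker selection, spacing
invariants, homopolymer classification, and edit application round-trips."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from vigmap import variants as var
from vigmap.seqs import SequenceSet
from tests.conftest import random_seq


def record(depth=30, freq=0.97, strand=None, genotype="hom_alt",
           scaffold="s1", pos=1000, ref="A", alt="G"):
    if strand is None:
        alt_n = round(depth * freq)
        ref_n = depth - alt_n
        strand = (ref_n - ref_n // 2, ref_n // 2, alt_n - alt_n // 2, alt_n // 2)
    return var.VariantRecord(scaffold, pos, ref, alt, depth, freq, strand, genotype)


class TestStrandBias:
    def test_balanced_table_is_one(self):
        assert var.strand_bias_p(5, 5, 5, 5) == pytest.approx(1.0)

    def test_fully_biased_table(self):
        from math import comb
        assert var.strand_bias_p(10, 0, 0, 10) == pytest.approx(2 / comb(20, 10))

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            var.strand_bias_p(0, 0, 0, 0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            t = tuple(int(x) for x in rng.integers(0, 25, 4))
            if sum(t) == 0:
                continue
            ours = var.strand_bias_p(*t)
            oracle = fisher_exact([[t[0], t[1]], [t[2], t[3]]])[1]
            assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_symmetry_invariances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, 4))
            if a + b + c + d == 0:
                continue
            p = var.strand_bias_p(a, b, c, d)
            assert p == pytest.approx(var.strand_bias_p(c, d, a, b))  # row swap
            assert p == pytest.approx(var.strand_bias_p(b, a, d, c))  # col swap
            assert p == pytest.approx(var.strand_bias_p(a, c, b, d))  # transpose


class TestSelectErrorSites:
    def test_depth_boundary(self):
        assert var.select_error_sites([record(depth=9, freq=1.0)]) == []
        kept = var.select_error_sites([record(depth=10, freq=0.70)])
        assert len(kept) == 1  # boundaries inclusive

    def test_strand_bias_rejected(self):
        assert var.select_error_sites([record(strand=(10, 0, 0, 10), freq=0.5,
                                              depth=20)]) == []

    def test_degenerate_thresholds_keep_all(self):
        cfg = var.FilterConfig(min_depth=0, min_freq_error=0.0, strand_p=0.0)
        records = [record(depth=3, freq=0.1), record(strand=(10, 0, 0, 10))]
        assert var.select_error_sites(records, cfg) == records

    def test_planted_labels_recovered_exactly(self, variant_fixture):
        parent_b, _, labels = variant_fixture
        kept = {(v.scaffold_id, v.position)
                for v in var.select_error_sites(parent_b)}
        expected = {(r.scaffold, r.position)
                    for _, r in labels.iterrows() if r.expected_error_site}
        assert kept == expected

    def test_monotone_in_thresholds(self, variant_fixture):
        parent_b, _, _ = variant_fixture
        base = var.select_error_sites(parent_b, var.FilterConfig())
        for cfg in (var.FilterConfig(min_depth=25),
                    var.FilterConfig(min_freq_error=0.9),
                    var.FilterConfig(strand_p=0.2)):
            tighter = var.select_error_sites(parent_b, cfg)
            assert set((v.scaffold_id, v.position) for v in tighter) <= set(
                (v.scaffold_id, v.position) for v in base
            )


class TestSelectMarkerSnps:
    def test_neighbor_snp_rejected(self):
        rng = np.random.default_rng(2)
        seqs = SequenceSet([("s1", random_seq(rng, 3000))])
        a = record(pos=1000, scaffold="s1")
        b = record(pos=1040, scaffold="s1")
        probes, audit = var.select_marker_snps([a, b], seqs, [])
        assert probes == [] and audit["flank_clean"] == 0

    def test_duplicate_flank_rejected(self):
        rng = np.random.default_rng(3)
        core = random_seq(rng, 2000)
        seqs = SequenceSet([("s1", core + core)])  # every 121-mer occurs twice
        probes, audit = var.select_marker_snps([record(pos=500)], seqs, [])
        assert probes == [] and audit["unique_flank"] == 0

    def test_planted_fixture_exact_recovery(self, default_truth, variant_fixture):
        parent_b, parent_a, labels = variant_fixture
        probes, audit = var.select_marker_snps(
            parent_b, default_truth.genome, parent_a
        )
        got = {p.marker_id for p in probes}
        expected = {f"{r.scaffold}:{r.position}"
                    for _, r in labels.iterrows() if r.expected_marker}
        assert got == expected
        assert audit["cross_parent_fixed"] == len(expected)
        # audit counts shrink monotonically along the pipeline
        order = ["input", "stat_filters", "flank_clean", "unique_flank",
                 "cross_parent_fixed"]
        vals = [audit[k] for k in order]
        assert vals == sorted(vals, reverse=True)


class TestSpaceMarkers:
    def test_dense_candidates_pigeonhole(self):
        cands = [("s", p) for p in range(0, 1_000_000, 10_000)]
        out = var.space_markers(cands)
        assert len(out) <= 10
        gaps = np.diff([p for _, p in out])
        assert (gaps >= 100_000).all()

    def test_single_candidate_selected(self):
        assert var.space_markers([("s", 5)]) == [("s", 5)]

    def test_invariant_and_first_fit_count(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            cands = [("s", int(p)) for p in
                     np.sort(rng.integers(0, 2_000_000, 80))]
            out = var.space_markers(cands)
            ps = [p for _, p in out]
            assert (np.diff(ps) >= 100_000).all()
            # naive first-fit oracle
            last, n = -10**9, 0
            for _, p in sorted(cands, key=lambda t: t[1]):
                if p - last >= 100_000:
                    n += 1
                    last = p
            assert len(out) >= n


class TestHomopolymer:
    def test_run_inside_g_tract(self):
        for i in range(2, 6):
            assert var.homopolymer_run("ACGGGGT", i) == 4

    def test_no_run(self):
        assert var.homopolymer_run("ACGT", 2) == 1

    def test_matches_regex_scan_oracle(self):
        import re
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = random_seq(rng, 200)
            pos = int(rng.integers(0, 200))
            runs = [(m.start(), m.end()) for m in re.finditer(r"(.)\1*", seq)]
            (start, end) = next((s, e) for s, e in runs if s <= pos < e)
            assert var.homopolymer_run(seq, pos) == end - start


class TestApplyEdits:
    def test_single_deletion_shifts_downstream(self):
        seqs = SequenceSet([("s", "ACGTACGT")])
        edits = var.EditSet([("s", 2, "GT", "G")])
        out, cmap = var.apply_edits(seqs, edits)
        assert out["s"] == "ACGACGT"
        assert cmap.map_position("s", 1) == 1
        assert cmap.map_position("s", 5) == 4
        assert cmap.map_position("s", 3) is None  # inside the deleted span

    def test_empty_edit_set_identity(self):
        seqs = SequenceSet([("s", "ACGTACGT")])
        out, cmap = var.apply_edits(seqs, var.EditSet([]))
        assert out["s"] == seqs["s"]
        assert cmap.map_position("s", 7) == 7

    def test_ref_mismatch_names_site(self):
        seqs = SequenceSet([("s", "ACGTACGT")])
        with pytest.raises(ValueError, match="s:2"):
            var.apply_edits(seqs, var.EditSet([("s", 2, "TT", "T")]))

    def test_landmarks_recoverable_through_coordinate_map(self):
        rng = np.random.default_rng(6)
        seq = random_seq(rng, 50_000)
        positions = np.sort(rng.choice(np.arange(100, 49_000, 60), 100,
                                       replace=False))
        edits = []
        for p in positions:
            p = int(p)
            kind = rng.integers(0, 3)
            ref = seq[p : p + 2] if kind == 2 else seq[p]
            if kind == 0:  # substitution
                alt = "ACGT".replace(ref, "")[0]
            elif kind == 1:  # insertion
                alt = ref + "ACGT"[rng.integers(0, 4)]
            else:  # deletion
                alt = ref[0]
            edits.append(("s", p, ref, alt))
        eset = var.EditSet(edits)
        seqs = SequenceSet([("s", seq)])
        out, cmap = var.apply_edits(seqs, eset)
        # landmarks: 20-mers placed between edits
        landmarks = [int(p) + 20 for p in positions[:-1]
                     if positions[np.searchsorted(positions, p) + 1] - p > 45]
        assert landmarks
        for lm in landmarks:
            new = cmap.map_position("s", lm)
            assert out["s"][new : new + 20] == seq[lm : lm + 20]

    def test_reverse_edits_round_trip(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 20_000)
        edits = []
        for p in range(500, 19_000, 500):
            kind = p // 500 % 3
            if kind == 0:
                edits.append(("s", p, seq[p], "ACGT".replace(seq[p], "")[0]))
            elif kind == 1:
                edits.append(("s", p, seq[p], seq[p] + "GATTACA"))
            else:
                edits.append(("s", p, seq[p : p + 5], seq[p]))
        eset = var.EditSet(edits)
        seqs = SequenceSet([("s", seq)])
        edited, cmap = var.apply_edits(seqs, eset)
        delta = sum(len(a) - len(r) for _, _, r, a in eset.edits)
        assert len(edited["s"]) == len(seq) + delta
        restored, _ = var.apply_edits(edited, var.invert_edits(eset, cmap))
        assert restored["s"] == seq


class TestClassifyDiscrepancies:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "G", "substitutions"), ("A", "AT", "insertions"),
         ("AT", "A", "deletions")],
    )
    def test_kinds(self, ref, alt, expected):
        seq = "ACGTATATACGT"
        seqs = SequenceSet([("s", seq.replace("A", ref[0], 1))])
        seqs = SequenceSet([("s", "A" + "CGTT" * 3)])
        eset = var.EditSet([("s", 0, ref, alt)])
        tallies = var.classify_discrepancies(eset, seqs)
        assert getattr(tallies, expected) == 1

    def test_planted_composition(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 30_000)
        # plant a homopolymer tract and edit inside it
        seq = seq[:1000] + "G" * 8 + seq[1008:]
        edits = [
            ("s", 999, seq[999], seq[999] + "G"),  # insertion at G-tract
            ("s", 5000, seq[5000], "ACGT".replace(seq[5000], "")[0]),
            ("s", 7000, seq[7000 : 7002], seq[7000]),  # deletion, random context
        ]
        tallies = var.classify_discrepancies(
            var.EditSet(edits), SequenceSet([("s", seq)])
        )
        assert tallies.substitutions == 1
        assert tallies.insertions == 1
        assert tallies.deletions == 1
        assert tallies.homopolymer_insertions == 1


class TestIO:
    def test_tsv_round_trip(self, tmp_path, variant_fixture):
        parent_b, _, _ = variant_fixture
        path = tmp_path / "v.tsv"
        var.write_variants_tsv(parent_b, path)
        back = var.read_variants_tsv(path)
        assert len(back) == len(parent_b)
        for a, b in zip(back, parent_b):
            assert a.alt_frequency == pytest.approx(b.alt_frequency)
            assert (a.scaffold_id, a.position, a.ref, a.alt, a.depth_hq,
                    a.strand_counts, a.genotype) == (
                b.scaffold_id, b.position, b.ref, b.alt, b.depth_hq,
                b.strand_counts, b.genotype)

    def test_vcf_reader(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP4,Number=4,Type=Integer,Description="strand counts">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "s1\t101\t.\tA\tG\t60\tPASS\tDP4=7,8,7,8\tGT\t1/1\n"
            "s1\t201\t.\tC\tCT\t60\tPASS\tDP4=10,10,5,5\tGT\t0/1\n"
        )
        records = var.read_variants_vcf(vcf)
        assert len(records) == 2
        assert records[0].position == 100  # 0-based
        assert records[0].genotype == "hom_alt"
        assert records[0].depth_hq == 30
        assert records[1].is_indel and records[1].genotype == "het"
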