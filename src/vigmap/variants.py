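"""Variant-level filtering rules for assembly correction and marker design.

The rules implemented here are the quality gates a genome project applies to
short-read pileup calls: a high-quality-depth / allele-frequency / strand-
bias gate for selecting assembly error sites (depth >= 10 at base quality
>= 30, frequency >= 70%, Fisher strand-bias p > 0.01), a stricter pipeline
for SNP-array marker design (homozygous calls at >= 90% frequency with
SNP-free, assembly-unique, cross-parent-fixed 60 bp flanks, spaced >= 100 kb
apart), homopolymer classification of indel discrepancies (run length >= 4,
i.e. "more than three consecutive nucleotides"), and application of the
accepted edits to the assembly with coordinate remapping.

``depth_hq`` on a record must count only reads meeting the base-quality
floor; the upstream pileup is out of scope here. Allele frequency is
computed over those high-quality reads.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from vigmap.anchoring import Probe, _find_all
from vigmap.seqs import SequenceSet, revcomp


@dataclass(frozen=True)
class VariantRecord:
    scaffold_id: str
    position: int  # 0-based
    ref: str
    alt: str
    depth_hq: int
    alt_frequency: float
    strand_counts: tuple[int, int, int, int]  # ref_fwd, ref_rev, alt_fwd, alt_rev
    genotype: str  # hom_ref | het | hom_alt

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 10
    min_baseq: int = 30  # documented floor for depth_hq; not applied here
    min_freq_error: float = 0.70
    min_freq_marker: float = 0.90
    strand_p: float = 0.01
    flank: int = 60
    min_spacing: int = 100_000
    homopolymer_min_run: int = 4


@dataclass
class EditSet:
    """Non-overlapping sequence edits, sorted by (scaffold, position)."""

    edits: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edits = sorted(self.edits)
        prev: dict[str, int] = {}
        for sid, pos, ref, alt in self.edits:
            if not ref or not alt:
                raise ValueError("edits must use anchored ref/alt strings")
            if sid in prev and pos < prev[sid]:
                raise ValueError(f"overlapping edits on {sid} at {pos}")
            prev[sid] = pos + len(ref)

    def __len__(self) -> int:
        return len(self.edits)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EditSet":
        df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "ref": str, "alt": str})
        return cls([tuple(r) for r in df[["scaffold", "position", "ref", "alt"]].itertuples(index=False)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.edits, columns=["scaffold", "position", "ref", "alt"]
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# strand bias
# ---------------------------------------------------------------------------


def strand_bias_p(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> float:
    """Two-sided Fisher exact p-value on the allele x strand 2x2 table.

    Computed as the hypergeometric tail sum: all tables with the observed
    margins whose probability does not exceed that of the observed table
    (with the standard 1+1e-7 relative guard against floating-point ties).
    """
    counts = (ref_fwd, ref_rev, alt_fwd, alt_rev)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all-zero table")
    n_ref = ref_fwd + ref_rev
    n_fwd = ref_fwd + alt_fwd
    support = np.arange(max(0, n_ref + n_fwd - n), min(n_ref, n_fwd) + 1)
    pmf = hypergeom.pmf(support, n, n_ref, n_fwd)
    p_obs = pmf[int(ref_fwd - support[0])]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


# ---------------------------------------------------------------------------
# error-site and marker selection
# ---------------------------------------------------------------------------


def select_error_sites(
    variants: list[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Variant sites accepted as assembly errors: high-quality depth >=
    ``min_depth``, alternate frequency >= ``min_freq_error``, and no strand
    bias (Fisher p > ``strand_p``). Boundaries are inclusive.
    """
    out = []
    for v in variants:
        if v.depth_hq < cfg.min_depth:
            continue
        if v.alt_frequency < cfg.min_freq_error:
            continue
        if strand_bias_p(*v.strand_counts) <= cfg.strand_p:
            continue
        out.append(v)
    return out


def _positions_by_scaffold(records: list[VariantRecord]) -> dict[str, list[int]]:
    by: dict[str, list[int]] = {}
    for v in records:
        by.setdefault(v.scaffold_id, []).append(v.position)
    return {sid: sorted(ps) for sid, ps in by.items()}


def _has_neighbor(positions: dict[str, list[int]], sid: str, pos: int, flank: int) -> bool:
    ps = positions.get(sid, [])
    lo = bisect.bisect_left(ps, pos - flank)
    hi = bisect.bisect_right(ps, pos + flank)
    for p in ps[lo:hi]:
        if p != pos:
            return True
    return False


def _count_genomewide(assembly: SequenceSet, kmer: str) -> int:
    rc = revcomp(kmer)
    n = 0
    for _, seq in assembly:
        n += len(_find_all(seq, kmer))
        if rc != kmer:
            n += len(_find_all(seq, rc))
    return n


def select_marker_snps(
    variants: list[VariantRecord],
    assembly: SequenceSet,
    other_parent_variants: list[VariantRecord],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[Probe], dict[str, int]]:
    """Marker-grade SNP selection between two parents on one assembly.

    Filter pipeline (each step logged in the audit dict):

    1. ``stat_filters`` — homozygous-alternate calls with depth_hq >= 10,
       frequency >= 0.90 and no strand bias (p > 0.01);
    2. ``flank_clean`` — no other variant within +-``flank`` bp in either
       parent's call set;
    3. ``unique_flank`` — the 121-mer centred on the SNP occurs exactly once
       in the assembly (both strands), a deterministic uniqueness screen;
    4. ``cross_parent_fixed`` — the other parent carries no call at the SNP
       site itself, so the site is a fixed inter-parent difference.

    Survivors become array probes (ref allele = assembly base).
    """
    audit: dict[str, int] = {"input": len(variants)}
    step1 = [
        v
        for v in variants
        if v.genotype == "hom_alt"
        and v.depth_hq >= cfg.min_depth
        and v.alt_frequency >= cfg.min_freq_marker
        and strand_bias_p(*v.strand_counts) > cfg.strand_p
    ]
    audit["stat_filters"] = len(step1)

    own_pos = _positions_by_scaffold(variants)
    other_pos = _positions_by_scaffold(other_parent_variants)
    step2 = [
        v
        for v in step1
        if not _has_neighbor(own_pos, v.scaffold_id, v.position, cfg.flank)
        and not _has_neighbor(other_pos, v.scaffold_id, v.position, cfg.flank)
    ]
    audit["flank_clean"] = len(step2)

    step3 = []
    for v in step2:
        seq = assembly[v.scaffold_id]
        start = v.position - cfg.flank
        end = v.position + cfg.flank + 1
        if start < 0 or end > len(seq):
            continue
        kmer = seq[start:end]
        if _count_genomewide(assembly, kmer) == 1:
            step3.append((v, kmer))
    audit["unique_flank"] = len(step3)

    other_sites = {(v.scaffold_id, v.position) for v in other_parent_variants}
    step4 = [(v, k) for v, k in step3 if (v.scaffold_id, v.position) not in other_sites]
    audit["cross_parent_fixed"] = len(step4)

    probes = [
        Probe(
            marker_id=f"{v.scaffold_id}:{v.position}",
            sequence=kmer,
            allele_a=v.ref,
            allele_b=v.alt,
            snp_offset=cfg.flank,
        )
        for v, kmer in step4
    ]
    return probes, audit


def space_markers(
    candidates: list[tuple[str, int]],
    cfg: FilterConfig = FilterConfig(),
    per_scaffold_quota: dict[str, int] | None = None,
    scaffold_lengths: dict[str, int] | None = None,
) -> list[tuple[str, int]]:
    """Thin candidate markers so consecutive selections on a scaffold are at
    least ``min_spacing`` apart.

    Without a quota this is a first-fit greedy sweep (which maximises the
    number selected). With a per-scaffold quota, selections chase an even
    grid over the scaffold — the candidate nearest each grid point is
    preferred, still subject to the spacing floor.
    """
    by: dict[str, list[int]] = {}
    for sid, pos in candidates:
        by.setdefault(sid, []).append(pos)
    out: list[tuple[str, int]] = []
    for sid in sorted(by):
        ps = sorted(by[sid])
        quota = (per_scaffold_quota or {}).get(sid)
        if quota is None:
            last = -cfg.min_spacing
            for p in ps:
                if p - last >= cfg.min_spacing:
                    out.append((sid, p))
                    last = p
        else:
            length = (scaffold_lengths or {}).get(sid, ps[-1] + 1)
            grid = [
                int(round((i + 0.5) * length / quota)) for i in range(quota)
            ]
            last = -cfg.min_spacing
            chosen: list[int] = []
            for gpos in grid:
                eligible = [p for p in ps if p - last >= cfg.min_spacing and p not in chosen]
                if not eligible:
                    continue
                p = min(eligible, key=lambda q: (abs(q - gpos), q))
                if chosen and p < chosen[-1]:
                    continue
                chosen.append(p)
                last = p
            out.extend((sid, p) for p in chosen)
    return out


# ---------------------------------------------------------------------------
# homopolymer classification
# ---------------------------------------------------------------------------


def homopolymer_run(seq: str, position: int, base: str | None = None) -> int:
    """Length of the maximal single-base run touching ``position``.

    With an explicit ``base`` (the inserted/deleted base of an indel) the
    run of that base spanning the boundary at ``position`` is counted even
    when ``seq[position]`` differs.
    """
    if not 0 <= position <= len(seq) - 1:
        raise ValueError("position outside sequence")
    b = (base or seq[position]).upper()
    seq = seq.upper()
    n = 0
    i = position
    while i < len(seq) and seq[i] == b:
        n += 1
        i += 1
    i = position - 1
    while i >= 0 and seq[i] == b:
        n += 1
        i -= 1
    return n


def _indel_base_and_pos(position: int, ref: str, alt: str) -> tuple[int, str]:
    """VCF-style anchored indel: the varying base starts after the anchor."""
    if len(alt) > len(ref):
        return position + len(ref), alt[len(ref)]
    return position + len(alt), ref[len(alt)]


@dataclass(frozen=True)
class DiscrepancyTallies:
    substitutions: int
    insertions: int
    deletions: int
    homopolymer_insertions: int
    homopolymer_deletions: int

    @property
    def homopolymer_indels(self) -> int:
        return self.homopolymer_insertions + self.homopolymer_deletions


def classify_discrepancies(
    edits: EditSet, seqs: SequenceSet, min_run: int = 4
) -> DiscrepancyTallies:
    """Tally substitutions / insertions / deletions and flag indels at
    homopolymer sites (run >= ``min_run``)."""
    n_sub = n_ins = n_del = hp_ins = hp_del = 0
    for sid, pos, ref, alt in edits.edits:
        if len(ref) == len(alt):
            n_sub += 1
            continue
        seq = seqs[sid]
        bpos, base = _indel_base_and_pos(pos, ref, alt)
        bpos = min(bpos, len(seq) - 1)
        is_hp = homopolymer_run(seq, bpos, base) >= min_run
        if len(alt) > len(ref):
            n_ins += 1
            hp_ins += is_hp
        else:
            n_del += 1
            hp_del += is_hp
    return DiscrepancyTallies(n_sub, n_ins, n_del, hp_ins, hp_del)


# ---------------------------------------------------------------------------
# edit application with coordinate remapping
# ---------------------------------------------------------------------------


class CoordinateMap:
    """Old -> new coordinate translation produced by :func:`apply_edits`.

    Positions inside a replaced reference span map to ``None``.
    """

    def __init__(self, table: dict[str, list[tuple[int, int, int]]]):
        # per scaffold: sorted (ref_start, ref_end, cumulative_delta_after)
        self._table = table

    def map_position(self, scaffold_id: str, position: int) -> int | None:
        spans = self._table.get(scaffold_id, [])
        delta = 0
        for start, end, cum in spans:
            if position < start:
                break
            if position < end:
                return None
            delta = cum
        return position + delta


def apply_edits(
    seqs: SequenceSet, edits: EditSet
) -> tuple[SequenceSet, CoordinateMap]:
    """Apply validated edits (ref must match) and return the edited sequences
    plus an old->new coordinate map.

    Edits are applied from the right so earlier coordinates stay valid; the
    net length change per scaffold equals the summed ``len(alt)-len(ref)``.
    """
    by: dict[str, list[tuple[int, str, str]]] = {}
    for sid, pos, ref, alt in edits.edits:
        if sid not in seqs:
            raise ValueError(f"edit names unknown sequence {sid!r}")
        by.setdefault(sid, []).append((pos, ref, alt))
    out: list[tuple[str, str]] = []
    table: dict[str, list[tuple[int, int, int]]] = {}
    for sid, seq in seqs:
        todo = sorted(by.get(sid, []))
        spans: list[tuple[int, int, int]] = []
        cum = 0
        for pos, ref, alt in todo:
            if seq[pos : pos + len(ref)] != ref:
                raise ValueError(
                    f"ref mismatch at {sid}:{pos} (expected {ref!r}, "
                    f"found {seq[pos:pos + len(ref)]!r})"
                )
            cum += len(alt) - len(ref)
            spans.append((pos, pos + len(ref), cum))
        new_seq = seq
        for pos, ref, alt in reversed(todo):
            new_seq = new_seq[:pos] + alt + new_seq[pos + len(ref) :]
        out.append((sid, new_seq))
        table[sid] = spans
    return SequenceSet(out, kind=seqs.kind), CoordinateMap(table)


def invert_edits(edits: EditSet, coord_map: CoordinateMap) -> EditSet:
    """The edit set that undoes ``edits`` on the edited sequences."""
    inv = []
    for sid, pos, ref, alt in edits.edits:
        delta_before = 0
        for start, _end, cum in coord_map._table.get(sid, []):
            if start >= pos:
                break
            delta_before = cum
        inv.append((sid, pos + delta_before, alt, ref))
    return EditSet(inv)


# ---------------------------------------------------------------------------
# record I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "scaffold", "position", "ref", "alt", "depth_hq", "alt_frequency",
    "ref_fwd", "ref_rev", "alt_fwd", "alt_rev", "genotype",
]


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "ref": str, "alt": str})
    return [
        VariantRecord(
            r.scaffold, int(r.position), r.ref, r.alt, int(r.depth_hq),
            float(r.alt_frequency),
            (int(r.ref_fwd), int(r.ref_rev), int(r.alt_fwd), int(r.alt_rev)),
            r.genotype,
        )
        for r in df.itertuples(index=False)
    ]


def write_variants_tsv(records: list[VariantRecord], path: str | Path) -> None:
    rows = [
        (v.scaffold_id, v.position, v.ref, v.alt, v.depth_hq, v.alt_frequency,
         *v.strand_counts, v.genotype)
        for v in records
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Read site records from a VCF with samtools-style annotations.

    Expects ``DP4`` (ref_fwd, ref_rev, alt_fwd, alt_rev) in INFO; depth_hq
    is the DP4 sum (high-quality reads only, by samtools convention) and the
    genotype comes from the first sample's GT when present.
    """
    from cyvcf2 import VCF

    records = []
    for var in VCF(str(path)):
        dp4 = var.INFO.get("DP4")
        if dp4 is None:
            continue
        rf, rr, af, ar = (int(x) for x in dp4)
        depth = rf + rr + af + ar
        freq = (af + ar) / depth if depth else 0.0
        if var.gt_types is not None and len(var.gt_types) > 0:
            gt = {0: "hom_ref", 1: "het", 3: "hom_alt"}.get(int(var.gt_types[0]), "het")
        else:
            gt = "hom_alt" if freq >= 0.9 else "het"
        records.append(
            VariantRecord(
                var.CHROM, var.start, var.REF, var.ALT[0] if var.ALT else var.REF,
                depth, freq, (rf, rr, af, ar), gt,
            )
        )
    return records
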