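"""Synthetic diploid cross and assembly simulator with known truth.

Generates every input the pipeline consumes, at a scale a laptop can chew
through, while keeping the geometry of a real high-density-map genome
project: multiple linkage groups with interspersed repeats and telomeric
``TTTAGGG`` arrays at the termini, array markers planted at controlled
spacing with unique 121-mer probe contexts, an F2 cross simulated under the
Haldane (no-interference) crossover model with genotyping error and missing
data, a fragmented scaffold set carrying planted inter-LG chimeras and
internal inversions, and two-parent variant tables with decoy records that
violate each filter dimension.

Every generator is a deterministic function of the configuration (including
its seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vigmap.anchoring import Probe, _find_all
from vigmap.linkage import GeneticMap, GenotypeMatrix
from vigmap.seqs import SequenceSet, revcomp
from vigmap.variants import VariantRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
TELOMERE_MOTIF = "TTTAGGG"
PROBE_FLANK = 60


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one synthetic genome project.

    Defaults are the scaled-down analogue of a real legume project: two
    1 Mb linkage groups with markers every 100 kb (the real project spaced
    its array markers >= 100 kb apart), a 500-plant F2 population, ~1.1
    cM/Mb (a 540 Mb genome over a ~600 cM map), light genotyping error and
    missingness, and a scaffold set of 16 pieces with low planted-defect
    rates comparable to the per-scaffold misassembly rate of a long-read
    assembly.
    """

    seed: int = 0
    n_lgs: int = 2
    lg_size: int = 1_000_000
    repeat_fraction: float = 0.15
    marker_spacing: int = 100_000
    n_individuals: int = 500
    genotyping_error: float = 0.005
    missing_rate: float = 0.02
    n_scaffolds: int = 16
    chimera_rate: float = 0.02
    inversion_rate: float = 0.01
    cm_per_mb: float = 1.1
    telomere_copies: int = 30
    n_chimeras: int | None = None  # override the rate with an exact count
    n_inversions: int | None = None

    def __post_init__(self) -> None:
        for name in ("repeat_fraction", "genotyping_error", "missing_rate",
                     "chimera_rate", "inversion_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lg_size <= 0 or self.marker_spacing <= 0:
            raise ValueError("sizes must be positive")
        if self.marker_spacing > self.lg_size:
            raise ValueError("marker spacing exceeds linkage-group size")


@dataclass(frozen=True)
class MarkerTruth:
    marker_id: str
    lg: str
    pos: int  # 0-based position of the SNP base on its LG
    cm: float  # map position within the LG (first marker at 0)
    probe: str  # 121-mer context carrying the parent-A allele at the centre
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class ScaffoldTruth:
    scaffold_id: str
    # source intervals: (lg, start, end, strand) concatenated left to right
    parts: tuple[tuple[str, int, int, str], ...]
    defect: str | None  # None | inter_lg_chimera | inversion
    flipped: bool  # whole scaffold emitted reverse-complemented


@dataclass
class TruthSet:
    """Everything the tests need to score the pipeline against."""

    config: SimConfig
    genome: SequenceSet
    markers: list[MarkerTruth]
    repeat_intervals: dict[str, list[tuple[int, int, int]]]  # lg -> (s, e, elem)
    genotypes: GenotypeMatrix | None = None
    crossover_counts: np.ndarray | None = None  # individuals x 2 gametes
    scaffolds: SequenceSet | None = None
    scaffold_truth: list[ScaffoldTruth] = field(default_factory=list)

    # -- derived views ------------------------------------------------------
    def truth_map(self) -> GeneticMap:
        groups = []
        for lg in self.genome.ids:
            mk = sorted(
                (m for m in self.markers if m.lg == lg), key=lambda m: m.pos
            )
            if not mk:
                continue
            base = mk[0].cm
            groups.append((lg, [(m.marker_id, m.cm - base) for m in mk]))
        return GeneticMap(groups)

    def probes(self) -> list[Probe]:
        return [
            Probe(m.marker_id, m.probe, m.allele_a, m.allele_b, PROBE_FLANK)
            for m in self.markers
        ]

    def defect_log(self) -> list[tuple[str, str]]:
        return [
            (s.scaffold_id, s.defect) for s in self.scaffold_truth if s.defect
        ]

    def synteny_hints(self) -> dict[str, str]:
        """True emitted orientation of every defect-free scaffold."""
        return {
            s.scaffold_id: ("-" if s.flipped else "+")
            for s in self.scaffold_truth
            if s.defect is None
        }

    def marker_order(self, lg: str) -> list[str]:
        return [
            m.marker_id
            for m in sorted(
                (m for m in self.markers if m.lg == lg), key=lambda m: m.pos
            )
        ]


# ---------------------------------------------------------------------------
# genome + markers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _intersects(intervals: list[tuple[int, int, int]], lo: int, hi: int) -> bool:
    return any(s < hi and lo < e for s, e, _ in intervals)


def simulate_genome(cfg: SimConfig) -> TruthSet:
    """Simulate the diploid reference genome and its planted array markers."""
    rng = np.random.default_rng([cfg.seed, 1])
    left_tel = ("CCCTAAA" * cfg.telomere_copies).encode()
    right_tel = (TELOMERE_MOTIF * cfg.telomere_copies).encode()

    n_elems = 6
    library = [
        _random_seq(rng, int(length))
        for length in rng.integers(200, 5001, n_elems)
    ]

    arrays: dict[str, np.ndarray] = {}
    repeat_intervals: dict[str, list[tuple[int, int, int]]] = {}
    for i in range(1, cfg.n_lgs + 1):
        lg = f"LG{i}"
        arr = _random_seq(rng, cfg.lg_size)
        intervals: list[tuple[int, int, int]] = []
        target = cfg.repeat_fraction * cfg.lg_size
        placed = 0
        guard = 0
        while placed < target and guard < 10_000:
            guard += 1
            e = int(rng.integers(0, n_elems))
            elem = library[e]
            if len(elem) + len(left_tel) * 2 >= cfg.lg_size:
                continue
            pos = int(rng.integers(len(left_tel), cfg.lg_size - len(elem) - len(right_tel)))
            arr[pos : pos + len(elem)] = elem
            intervals.append((pos, pos + len(elem), e))
            placed += len(elem)
        arr[: len(left_tel)] = np.frombuffer(left_tel, dtype=np.uint8)
        arr[cfg.lg_size - len(right_tel) :] = np.frombuffer(right_tel, dtype=np.uint8)
        arrays[lg] = arr
        repeat_intervals[lg] = intervals

    seqs = {lg: _to_str(arr) for lg, arr in arrays.items()}
    genome = SequenceSet(list(seqs.items()), kind="pseudomolecule")

    markers: list[MarkerTruth] = []
    tel_len = len(left_tel)
    for i in range(1, cfg.n_lgs + 1):
        lg = f"LG{i}"
        seq = seqs[lg]
        nominal = list(range(cfg.marker_spacing, cfg.lg_size - cfg.marker_spacing // 2,
                             cfg.marker_spacing))
        for j, base_pos in enumerate(nominal):
            pos = _place_marker(
                seq, genome, base_pos, repeat_intervals[lg], tel_len, cfg.lg_size
            )
            if pos is None:
                continue
            probe = seq[pos - PROBE_FLANK : pos + PROBE_FLANK + 1]
            a = seq[pos]
            b = "ACGT".replace(a, "")[int(rng.integers(0, 3))]
            markers.append(
                MarkerTruth(
                    marker_id=f"{lg}_M{j + 1:03d}",
                    lg=lg,
                    pos=pos,
                    cm=pos * cfg.cm_per_mb / 1e6,
                    probe=probe,
                    allele_a=a,
                    allele_b=b,
                )
            )
    return TruthSet(cfg, genome, markers, repeat_intervals)


def _unique_in_genome(genome: SequenceSet, kmer: str) -> bool:
    n = 0
    rc = revcomp(kmer)
    for _, seq in genome:
        n += len(_find_all(seq, kmer))
        if rc != kmer:
            n += len(_find_all(seq, rc))
        if n > 1:
            return False
    return n == 1


def _place_marker(seq, genome, base_pos, intervals, tel_len, lg_size):
    """Jitter around the nominal position until the 121-mer context is clear
    of repeats/telomeres and unique genome-wide."""
    for step in range(0, 80):
        for sign in (1, -1) if step else (1,):
            pos = base_pos + sign * step * 137
            lo, hi = pos - PROBE_FLANK, pos + PROBE_FLANK + 1
            if lo < tel_len + 10 or hi > lg_size - tel_len - 10:
                continue
            if _intersects(intervals, lo, hi):
                continue
            if _unique_in_genome(genome, seq[lo:hi]):
                return pos
    return None


# ---------------------------------------------------------------------------
# F2 cross
# ---------------------------------------------------------------------------


def simulate_f2_genotypes(
    marker_cm: dict[str, np.ndarray],
    n_individuals: int,
    genotyping_error: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    chrom_cm: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate F2 genotypes for markers at given cM positions per group.

    Crossovers per gamete follow a Poisson process along the map (Haldane:
    count ~ Poisson(length_cM / 100), positions uniform, no interference).
    Returns ``(calls, crossover_counts)`` where calls is individuals x
    markers int8 (AA=0/AB=1/BB=2/NA=-1), marker columns ordered by group
    then position, and crossover_counts is individuals x 2 gametes.
    """
    rng = np.random.default_rng([seed, 2])
    lgs = list(marker_cm)
    n_markers = sum(len(v) for v in marker_cm.values())
    calls = np.empty((n_individuals, n_markers), dtype=np.int8)
    xo_counts = np.zeros((n_individuals, 2), dtype=np.int64)
    for ind in range(n_individuals):
        col = 0
        gametes_per_lg: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for lg in lgs:
            cms = np.asarray(marker_cm[lg], dtype=float)
            total = (chrom_cm or {}).get(lg, float(cms[-1]) if len(cms) else 0.0)
            pair = []
            for gi in range(2):
                k = rng.poisson(total / 100.0)
                xo = np.sort(rng.uniform(0.0, max(total, 1e-12), k))
                start = int(rng.integers(0, 2))
                alleles = (start + np.searchsorted(xo, cms)) % 2
                pair.append(alleles)
                xo_counts[ind, gi] += k
            gametes_per_lg[lg] = (pair[0], pair[1])
        for lg in lgs:
            g1, g2 = gametes_per_lg[lg]
            geno = (g1 + g2).astype(np.int8)
            calls[ind, col : col + len(geno)] = geno
            col += len(geno)
    if genotyping_error > 0:
        flip = np.random.default_rng([seed, 21]).random(calls.shape) < genotyping_error
        shift = np.random.default_rng([seed, 22]).integers(1, 3, calls.shape)
        calls = np.where(flip, (calls + shift) % 3, calls).astype(np.int8)
    if missing_rate > 0:
        na = np.random.default_rng([seed, 23]).random(calls.shape) < missing_rate
        calls[na] = -1
    return calls, xo_counts


def simulate_f2(truth: TruthSet, cfg: SimConfig | None = None) -> GenotypeMatrix:
    """F2 genotypes for the truth set's planted markers (stored on the truth)."""
    cfg = cfg or truth.config
    marker_cm = {}
    names = []
    for lg in truth.genome.ids:
        mk = sorted((m for m in truth.markers if m.lg == lg), key=lambda m: m.pos)
        if not mk:
            continue
        marker_cm[lg] = np.array([m.cm for m in mk])
        names.extend(m.marker_id for m in mk)
    chrom_cm = {lg: truth.config.lg_size * truth.config.cm_per_mb / 1e6
                for lg in marker_cm}
    calls, xo = simulate_f2_genotypes(
        marker_cm,
        cfg.n_individuals,
        cfg.genotyping_error,
        cfg.missing_rate,
        cfg.seed,
        chrom_cm,
    )
    individuals = [f"F2_{i + 1:04d}" for i in range(cfg.n_individuals)]
    gm = GenotypeMatrix(individuals, names, calls)
    truth.genotypes = gm
    truth.crossover_counts = xo
    return gm


# ---------------------------------------------------------------------------
# fragmentation with planted defects
# ---------------------------------------------------------------------------


def _cut_pieces(truth: TruthSet, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Cut each LG at inter-marker midpoints so every piece keeps >= 1 marker
    and no cut lands inside a probe context."""
    cfg = truth.config
    total = sum(len(s) for _, s in truth.genome)
    pieces: list[tuple[str, int, int]] = []
    want = {lg: max(1, int(round(cfg.n_scaffolds * len(truth.genome[lg]) / total)))
            for lg in truth.genome.ids}
    for lg in truth.genome.ids:
        mpos = [m.pos for m in sorted(
            (m for m in truth.markers if m.lg == lg), key=lambda m: m.pos)]
        n_pieces = want[lg]
        gaps = [
            (mpos[i] + mpos[i + 1]) // 2 for i in range(len(mpos) - 1)
        ]
        n_cuts = min(n_pieces - 1, len(gaps))
        chosen = sorted(rng.choice(len(gaps), size=n_cuts, replace=False)) if n_cuts else []
        cuts = []
        for gi in chosen:
            jitter = int(rng.integers(-cfg.marker_spacing // 8, cfg.marker_spacing // 8 + 1))
            cuts.append(gaps[gi] + jitter)
        prev = 0
        for c in cuts:
            pieces.append((lg, prev, c))
            prev = c
        pieces.append((lg, prev, len(truth.genome[lg])))
    return pieces


def fragment_assembly(
    truth: TruthSet, cfg: SimConfig | None = None
) -> tuple[SequenceSet, list[tuple[str, str]]]:
    """Fragment the genome into scaffolds with planted misassemblies.

    Chimeras join two marker-bearing pieces from different LGs; inversions
    reverse-complement an internal span covering at least two (but not all)
    markers of a piece with >= 3 markers, which contradicts the map's
    marker order. Each scaffold is independently emitted on a random
    strand. Returns the scaffold set and the defect log
    ``[(scaffold_id, kind)]``; full provenance lands on
    ``truth.scaffold_truth``.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 3])
    pieces = _cut_pieces(truth, rng)

    def markers_in(piece):
        lg, s, e = piece
        return [m for m in truth.markers
                if m.lg == lg and s + PROBE_FLANK <= m.pos < e - PROBE_FLANK]

    n_chim = cfg.n_chimeras if cfg.n_chimeras is not None else int(
        round(cfg.chimera_rate * len(pieces)))
    n_inv = cfg.n_inversions if cfg.n_inversions is not None else int(
        round(cfg.inversion_rate * len(pieces)))

    order = list(rng.permutation(len(pieces)))
    used: set[int] = set()
    raw: list[tuple[tuple, str | None]] = []  # ((parts...), defect)

    # inversions first (they need the marker-richest pieces):
    # an internal span over >= 2 but not all markers of a piece with >= 3
    made = 0
    for i in order:
        if made >= n_inv:
            break
        if i in used:
            continue
        mk = markers_in(pieces[i])
        if len(mk) < 3:
            continue
        lg, s, e = pieces[i]
        mpos = [m.pos - s for m in mk]
        k = len(mpos)
        span_len = int(rng.integers(2, k))  # 2..k-1 markers inverted
        start_i = int(rng.integers(0, k - span_len + 1))
        end_i = start_i + span_len - 1
        clearance = max(100, cfg.marker_spacing // 3)
        a = ((mpos[start_i - 1] + mpos[start_i]) // 2 if start_i > 0
             else max(0, mpos[0] - clearance))
        b = ((mpos[end_i] + mpos[end_i + 1]) // 2 if end_i < k - 1
             else min(e - s, mpos[-1] + clearance))
        raw.append((((lg, s, s + a, "+"), (lg, s + a, s + b, "-"), (lg, s + b, e, "+")),
                    "inversion"))
        used.add(i)
        made += 1
    if made < n_inv:
        raise ValueError("not enough multi-marker pieces to plant inversions")

    # chimeras: pairs from different LGs, both with markers
    made = 0
    for i in order:
        if made >= n_chim:
            break
        if i in used or not markers_in(pieces[i]):
            continue
        for j in order:
            if j in used or j == i:
                continue
            if pieces[j][0] == pieces[i][0] or not markers_in(pieces[j]):
                continue
            lg1, s1, e1 = pieces[i]
            lg2, s2, e2 = pieces[j]
            raw.append((((lg1, s1, e1, "+"), (lg2, s2, e2, "+")), "inter_lg_chimera"))
            used.update((i, j))
            made += 1
            break
    if made < n_chim:
        raise ValueError("not enough marker-bearing pieces to plant chimeras")

    for i in order:
        if i not in used:
            lg, s, e = pieces[i]
            raw.append((((lg, s, e, "+"),), None))

    # emit with random strand and shuffled ids
    perm = rng.permutation(len(raw))
    records: list[tuple[str, str]] = []
    truths: list[ScaffoldTruth] = []
    for new_idx, old_idx in enumerate(perm):
        parts, defect = raw[old_idx]
        chunks = []
        for lg, s, e, strand in parts:
            sub = truth.genome[lg][s:e]
            chunks.append(revcomp(sub) if strand == "-" else sub)
        seq = "".join(chunks)
        flipped = bool(rng.integers(0, 2))
        if flipped:
            seq = revcomp(seq)
        sid = f"scf{new_idx + 1:04d}"
        records.append((sid, seq))
        truths.append(ScaffoldTruth(sid, tuple(parts), defect, flipped))
    scaffolds = SequenceSet(records, kind="scaffold")
    truth.scaffolds = scaffolds
    truth.scaffold_truth = truths
    return scaffolds, [(t.scaffold_id, t.defect) for t in truths if t.defect]


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

VARIANT_CLASS_COUNTS = {
    "valid": 30,
    "low_depth": 10,
    "freq_mid": 10,  # 0.75: passes the error-site gate, fails marker grade
    "low_freq": 10,  # 0.60: fails both frequency gates
    "strand_bias": 10,
    "het": 10,
    "flank_snp": 10,  # a second parent-B SNP 40 bp away
    "flank_snp_other": 5,  # contaminating SNP in the other parent's calls
    "nonunique_flank": 6,
    "parent_not_fixed": 10,
}


def _balanced_counts(depth: int, freq: float) -> tuple[int, int, int, int]:
    alt = int(round(depth * freq))
    ref = depth - alt
    return (ref - ref // 2, ref // 2, alt - alt // 2, alt // 2)


def simulate_variants(
    truth: TruthSet, cfg: SimConfig | None = None,
    class_counts: dict[str, int] | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord], pd.DataFrame]:
    """Two-parent variant tables over the simulated genome, with labels.

    Parent B is the divergent parent whose homozygous differences against
    the assembly become marker candidates; parent A is the assembly parent
    (its call set should be empty at fixed sites). Each decoy class
    violates exactly one marker-selection dimension. Returns
    ``(parent_b, parent_a, labels)`` where labels carries the class and the
    expected fate of each parent-B record.
    """
    cfg = cfg or truth.config
    counts = dict(VARIANT_CLASS_COUNTS, **(class_counts or {}))
    rng = np.random.default_rng([cfg.seed, 4])
    genome = truth.genome

    occupied: dict[str, list[int]] = {lg: [m.pos for m in truth.markers if m.lg == lg]
                                      for lg in genome.ids}

    def clear_of(lg: str, pos: int, margin: int = 150) -> bool:
        return all(abs(pos - p) >= margin for p in occupied[lg])

    def sample_pos(in_repeat: bool = False, need_unique: bool = True):
        for _ in range(3000):
            lg = genome.ids[int(rng.integers(0, len(genome)))]
            seq = genome[lg]
            if in_repeat:
                copies = [iv for iv in truth.repeat_intervals[lg]
                          if iv[1] - iv[0] >= 400]
                if not copies:
                    continue
                s, e, _elem = copies[int(rng.integers(0, len(copies)))]
                pos = (s + e) // 2
            else:
                pos = int(rng.integers(200, len(seq) - 200))
            if not clear_of(lg, pos):
                continue
            lo, hi = pos - PROBE_FLANK, pos + PROBE_FLANK + 1
            if lo < 0 or hi > len(seq):
                continue
            if not in_repeat and _intersects(truth.repeat_intervals[lg], lo, hi):
                continue
            uniq = _unique_in_genome(genome, seq[lo:hi])
            if in_repeat and uniq:
                continue
            if not in_repeat and need_unique and not uniq:
                continue
            occupied[lg].append(pos)
            return lg, pos
        raise ValueError("could not place variant")

    def make_record(lg, pos, depth, freq, strand=None, genotype="hom_alt"):
        seq = genome[lg]
        ref = seq[pos]
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        sc = strand if strand is not None else _balanced_counts(depth, freq)
        return VariantRecord(lg, pos, ref, alt, depth, freq, sc, genotype)

    parent_b: list[VariantRecord] = []
    parent_a: list[VariantRecord] = []
    labels = []

    def add(v, label, expected_marker, expected_error):
        parent_b.append(v)
        labels.append({"scaffold": v.scaffold_id, "position": v.position,
                       "label": label, "expected_marker": expected_marker,
                       "expected_error_site": expected_error})

    for _ in range(counts["valid"]):
        lg, pos = sample_pos()
        add(make_record(lg, pos, int(rng.integers(25, 41)), 0.97), "valid", True, True)
    for _ in range(counts["low_depth"]):
        lg, pos = sample_pos()
        add(make_record(lg, pos, 9, 1.0), "low_depth", False, False)
    for _ in range(counts["freq_mid"]):
        lg, pos = sample_pos()
        add(make_record(lg, pos, 30, 0.75), "freq_mid", False, True)
    for _ in range(counts["low_freq"]):
        lg, pos = sample_pos()
        add(make_record(lg, pos, 30, 0.60), "low_freq", False, False)
    for _ in range(counts["strand_bias"]):
        lg, pos = sample_pos()
        add(make_record(lg, pos, 30, 28 / 30, strand=(2, 0, 0, 28)),
            "strand_bias", False, False)
    for _ in range(counts["het"]):
        lg, pos = sample_pos()
        add(make_record(lg, pos, 30, 0.5, genotype="het"), "het", False, False)
    for _ in range(counts["flank_snp"]):
        lg, pos = sample_pos()
        add(make_record(lg, pos, 30, 0.97), "flank_snp", False, True)
        neighbor = make_record(lg, pos + 40, 30, 0.97)
        occupied[lg].append(pos + 40)
        add(neighbor, "neighbor", False, True)
    for _ in range(counts["flank_snp_other"]):
        lg, pos = sample_pos()
        add(make_record(lg, pos, 30, 0.97), "flank_snp_other", False, True)
        parent_a.append(make_record(lg, pos - 35, 25, 0.5, genotype="het"))
        occupied[lg].append(pos - 35)
    for _ in range(counts["nonunique_flank"]):
        lg, pos = sample_pos(in_repeat=True)
        add(make_record(lg, pos, 30, 0.97), "nonunique_flank", False, True)
    for _ in range(counts["parent_not_fixed"]):
        lg, pos = sample_pos()
        v = make_record(lg, pos, 30, 0.97)
        add(v, "parent_not_fixed", False, True)
        parent_a.append(VariantRecord(lg, pos, v.ref, v.alt, 25, 0.5,
                                      _balanced_counts(25, 0.5), "het"))
    return parent_b, parent_a, pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# k-mer histogram and family-table helpers
# ---------------------------------------------------------------------------


def simulate_kmer_histogram(
    genome_size: int, depth: float, seed: int = 0, error_kmers: int = 0
) -> list[tuple[int, int]]:
    """Multiplicity histogram of a shotgun run over a unique genome: each of
    the ``genome_size`` distinct k-mers is observed Poisson(depth) times;
    optional error k-mers pile up at multiplicity 1."""
    rng = np.random.default_rng([seed, 5])
    mult = rng.poisson(depth, genome_size)
    hist = np.bincount(mult)
    entries = [(m, int(c)) for m, c in enumerate(hist) if m >= 1 and c > 0]
    if error_kmers:
        merged = dict(entries)
        merged[1] = merged.get(1, 0) + error_kmers
        entries = sorted(merged.items())
    return entries


def simulate_family_table(
    seed: int = 0,
    n_shared: int = 50,
    n_reduced: int = 20,
    n_increased: int = 10,
    n_singletons: dict[str, int] | None = None,
    assemblies: tuple[str, ...] = ("asmA", "asmB", "ref"),
    reference: str = "ref",
) -> tuple[pd.DataFrame, dict]:
    """Gene-family membership table with a planted composition.

    Non-reference assemblies get ``n_reduced`` families one gene smaller and
    ``n_increased`` families one gene larger than the reference (base size
    3); singleton counts are planted per assembly. Returns the table and
    the expected per-assembly summary numbers.
    """
    rng = np.random.default_rng([seed, 6])
    rows = []
    fam = 0
    expected: dict[str, dict] = {
        a: {"n_increased_families": 0, "n_reduced_families": 0,
            "genes_gained": 0, "genes_lost": 0, "n_singletons": 0}
        for a in assemblies
    }
    others = [a for a in assemblies if a != reference]

    def emit(family, assembly, n):
        nonlocal rows
        for g in range(n):
            rows.append({"gene_id": f"g{family}_{assembly}_{g}",
                         "family_id": f"fam{family:05d}", "assembly_id": assembly})

    for _ in range(n_shared):
        for a in assemblies:
            emit(fam, a, 3)
        fam += 1
    for _ in range(n_reduced):
        victim = others[int(rng.integers(0, len(others)))]
        for a in assemblies:
            emit(fam, a, 2 if a == victim else 3)
        expected[victim]["n_reduced_families"] += 1
        expected[victim]["genes_lost"] += 1
        fam += 1
    for _ in range(n_increased):
        winner = others[int(rng.integers(0, len(others)))]
        for a in assemblies:
            emit(fam, a, 4 if a == winner else 3)
        expected[winner]["n_increased_families"] += 1
        expected[winner]["genes_gained"] += 1
        fam += 1
    for a, n in (n_singletons or {}).items():
        for _ in range(n):
            emit(fam, a, 1)
            expected[a]["n_singletons"] += 1
            if a == reference:
                # absent from every other assembly: a size-reduced family there
                for other in others:
                    expected[other]["n_reduced_families"] += 1
                    expected[other]["genes_lost"] += 1
            else:
                expected[a]["n_increased_families"] += 1
                expected[a]["genes_gained"] += 1
            fam += 1
    return pd.DataFrame(rows), expected


# ---------------------------------------------------------------------------
# one-call study simulation and file emission
# ---------------------------------------------------------------------------


def simulate_study(cfg: SimConfig = SimConfig()) -> TruthSet:
    """Genome + markers + F2 cross + fragmented scaffolds, in one call."""
    truth = simulate_genome(cfg)
    simulate_f2(truth, cfg)
    fragment_assembly(truth, cfg)
    return truth


def write_probe_fasta(probes: list[Probe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(
                f">{p.marker_id} allele_a={p.allele_a} allele_b={p.allele_b} "
                f"snp_offset={p.snp_offset}\n{p.sequence}\n"
            )


def read_probe_fasta(path: str | Path) -> list[Probe]:
    probes = []
    with open(path) as fh:
        header = None
        seq: list[str] = []
        for line in list(fh) + [">"]:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    name, *kv = header.split()
                    attrs = dict(item.split("=", 1) for item in kv)
                    probes.append(Probe(name, "".join(seq), attrs["allele_a"],
                                        attrs["allele_b"], int(attrs.get("snp_offset", 60))))
                header = line[1:]
                seq = []
            elif line:
                seq.append(line)
    return probes


def write_study(truth: TruthSet, outdir: str | Path) -> None:
    """Emit every pipeline input as plain-text files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.genome.to_fasta(out / "genome.fasta")
    if truth.scaffolds is not None:
        truth.scaffolds.to_fasta(out / "scaffolds.fasta")
    truth.truth_map().to_tsv(out / "map.tsv")
    if truth.genotypes is not None:
        truth.genotypes.to_tsv(out / "genotypes.tsv")
    write_probe_fasta(truth.probes(), out / "probes.fasta")
    hints = truth.synteny_hints()
    pd.DataFrame(sorted(hints.items()), columns=["scaffold", "orientation"]).to_csv(
        out / "synteny_hints.tsv", sep="\t", index=False
    )
    truth_doc = {
        "config": asdict(truth.config),
        "markers": [asdict(m) for m in truth.markers],
        "scaffolds": [
            {"scaffold_id": s.scaffold_id, "parts": list(map(list, s.parts)),
             "defect": s.defect, "flipped": s.flipped}
            for s in truth.scaffold_truth
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
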