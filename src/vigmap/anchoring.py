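"""Map-guided scaffold anchoring and pseudomolecule construction.

SNP-array probe sequences (121-mers with the SNP at the centre) are placed
on scaffolds by exact search of both allele variants on both strands; only
uniquely and identically matching probes are used. Scaffold marker content
is then compared against the genetic map to detect misassemblies (inter-LG
chimeras and within-LG marker-order conflicts), clean scaffolds are ordered
by median marker cM and oriented by the position-vs-cM rank correlation
(falling back to a synteny hint table for single-marker or tightly-linked
scaffolds), inter-scaffold gaps are estimated from the flanking marker
interval, and pseudomolecules are emitted as AGP v2.0 + FASTA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from vigmap.agp import GAP_UNKNOWN_LEN, AgpRow
from vigmap.seqs import SequenceSet, revcomp

CM_TIE_DECIMALS = 2  # markers within 0.01 cM count as tightly linked
MIN_GAP = 100


@dataclass(frozen=True)
class Probe:
    """A SNP-array probe: 121-mer with the SNP base at ``snp_offset``."""

    marker_id: str
    sequence: str
    allele_a: str
    allele_b: str
    snp_offset: int = 60

    def variants(self) -> tuple[str, str]:
        s, off = self.sequence.upper(), self.snp_offset
        return (
            s[:off] + self.allele_a.upper() + s[off + 1 :],
            s[:off] + self.allele_b.upper() + s[off + 1 :],
        )


@dataclass(frozen=True)
class MarkerPlacement:
    marker_id: str
    scaffold_id: str | None
    position: int  # 0-based offset of the SNP base on the scaffold
    n_hits: int
    identical: bool

    @property
    def usable(self) -> bool:
        return self.n_hits == 1 and self.identical


@dataclass(frozen=True)
class ContradictionRecord:
    scaffold_id: str
    kind: str  # inter_lg_chimera | order_conflict
    evidence: tuple[tuple[str, int, str, float], ...]  # (marker, pos, lg, cm)


@dataclass
class AnchoredScaffold:
    scaffold_id: str
    lg: str
    orientation: str  # '+', '-' or '?' (unknown; emitted as '+')
    markers: list[tuple[str, int, float]]  # (marker_id, position, cm)
    length: int
    median_cm: float
    gap_after: int | None = None  # bases to next scaffold; None after the last


@dataclass
class AnchorPlan:
    """Ordered, oriented scaffolds per linkage group plus the unanchored rest."""

    lgs: dict[str, list[AnchoredScaffold]] = field(default_factory=dict)
    unanchored: list[str] = field(default_factory=list)

    def all_anchored_ids(self) -> list[str]:
        return [s.scaffold_id for entries in self.lgs.values() for s in entries]


# ---------------------------------------------------------------------------
# probe placement
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def place_probes(probes: list[Probe], scaffolds: SequenceSet) -> list[MarkerPlacement]:
    """Exact-match placement of both allele variants on both strands.

    ``n_hits`` counts every occurrence genome-wide; a placement is usable
    only when the probe matches exactly once.
    """
    out = []
    for probe in probes:
        plen = len(probe.sequence)
        hits: list[tuple[str, int]] = []  # (scaffold, SNP position)
        for variant in probe.variants():
            rc = revcomp(variant)
            for sid, seq in scaffolds:
                for i in _find_all(seq, variant):
                    hits.append((sid, i + probe.snp_offset))
                for i in _find_all(seq, rc):
                    hits.append((sid, i + (plen - 1 - probe.snp_offset)))
        hits = sorted(set(hits))
        if hits:
            sid, pos = hits[0]
            out.append(MarkerPlacement(probe.marker_id, sid, pos, len(hits), True))
        else:
            out.append(MarkerPlacement(probe.marker_id, None, -1, 0, False))
    return out


# ---------------------------------------------------------------------------
# contradiction detection
# ---------------------------------------------------------------------------


def _monotone(values: list[float]) -> bool:
    inc = all(b >= a for a, b in zip(values, values[1:]))
    dec = all(b <= a for a, b in zip(values, values[1:]))
    return inc or dec


def _collapse_ties(values: list[float]) -> list[float]:
    rounded = [round(v, CM_TIE_DECIMALS) for v in values]
    out: list[float] = []
    for v in rounded:
        if not out or v != out[-1]:
            out.append(v)
    return out


def detect_contradictions(
    placements: list[MarkerPlacement], gmap
) -> list[ContradictionRecord]:
    """Compare marker order on each scaffold against the genetic map.

    Two kinds of conflict are reported, at most one record per scaffold per
    kind: ``inter_lg_chimera`` when a scaffold carries usable markers from
    more than one linkage group, and ``order_conflict`` when, within one
    linkage group and after collapsing cM ties, the cM sequence in physical
    order is neither non-decreasing nor non-increasing. The headline
    misassembly statistic is the number of contradicted scaffolds.
    """
    lookup = gmap.marker_lookup()
    by_scaffold: dict[str, list[tuple[str, int, str, float]]] = {}
    for p in placements:
        if not p.usable or p.marker_id not in lookup:
            continue
        lg, cm = lookup[p.marker_id]
        by_scaffold.setdefault(p.scaffold_id, []).append(
            (p.marker_id, p.position, lg, cm)
        )
    records: list[ContradictionRecord] = []
    for sid in sorted(by_scaffold):
        ev = sorted(by_scaffold[sid], key=lambda t: t[1])
        lgs = sorted({lg for _, _, lg, _ in ev})
        if len(lgs) > 1:
            records.append(ContradictionRecord(sid, "inter_lg_chimera", tuple(ev)))
        conflict_ev: list[tuple[str, int, str, float]] = []
        for lg in lgs:
            sub = [e for e in ev if e[2] == lg]
            cms = _collapse_ties([cm for _, _, _, cm in sub])
            if len(cms) >= 3 and not _monotone(cms):
                conflict_ev.extend(sub)
        if conflict_ev:
            records.append(
                ContradictionRecord(sid, "order_conflict", tuple(conflict_ev))
            )
    return records


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def _orient(markers: list[tuple[str, int, float]], hint: str | None) -> str:
    cms = [round(cm, CM_TIE_DECIMALS) for _, _, cm in markers]
    if len(set(cms)) >= 2:
        rho = stats.spearmanr(
            [pos for _, pos, _ in markers], [cm for _, _, cm in markers]
        ).statistic
        if not math.isnan(rho) and rho != 0:
            return "+" if rho > 0 else "-"
    if hint in ("+", "-"):
        return hint
    return "?"


def anchor(
    placements: list[MarkerPlacement],
    gmap,
    scaffolds: SequenceSet,
    synteny_hint: dict[str, str] | None = None,
) -> AnchorPlan:
    """Assign scaffolds to linkage groups, order them by median marker cM and
    orient them by the sign of the position-vs-cM rank correlation.

    Scaffolds whose markers are all at one cM value (after rounding to
    0.01 cM) or that carry a single marker cannot be oriented from the map;
    the synteny hint table is consulted, else the orientation is unknown
    (emitted as '+' and flagged '?'). Scaffolds still spanning two linkage
    groups must be resolved upstream and raise an error here.
    """
    synteny_hint = synteny_hint or {}
    lookup = gmap.marker_lookup()
    by_scaffold: dict[str, list[tuple[str, int, float, str]]] = {}
    for p in placements:
        if not p.usable or p.marker_id not in lookup:
            continue
        lg, cm = lookup[p.marker_id]
        by_scaffold.setdefault(p.scaffold_id, []).append(
            (p.marker_id, p.position, cm, lg)
        )
    plan = AnchorPlan()
    for sid in sorted(by_scaffold):
        entries = sorted(by_scaffold[sid], key=lambda t: t[1])
        lgs = {lg for _, _, _, lg in entries}
        if len(lgs) > 1:
            raise ValueError(f"unresolved chimera: {sid}")
        lg = lgs.pop()
        markers = [(m, pos, cm) for m, pos, cm, _ in entries]
        plan.lgs.setdefault(lg, []).append(
            AnchoredScaffold(
                scaffold_id=sid,
                lg=lg,
                orientation=_orient(markers, synteny_hint.get(sid)),
                markers=markers,
                length=len(scaffolds[sid]),
                median_cm=float(np.median([cm for _, _, cm in markers])),
            )
        )
    for lg in plan.lgs:
        plan.lgs[lg].sort(key=lambda s: (s.median_cm, s.scaffold_id))
    plan.unanchored = [sid for sid in scaffolds.ids if sid not in by_scaffold]
    return plan


# ---------------------------------------------------------------------------
# gap estimation and pseudomolecule emission
# ---------------------------------------------------------------------------


def _oriented_positions(s: AnchoredScaffold) -> list[tuple[int, float]]:
    """Marker (position, cM) in the scaffold's emitted orientation."""
    flip = s.orientation == "-"
    return sorted(
        ((s.length - 1 - pos) if flip else pos, cm) for _, pos, cm in s.markers
    )


def estimate_gap(
    left: AnchoredScaffold, right: AnchoredScaffold, bp_per_cm: float
) -> int:
    """Estimate the gap between two adjacent anchored scaffolds.

    The genetic interval between the two markers nearest the junction is
    converted to bases at ``bp_per_cm`` and the scaffold overhangs beyond
    those markers are subtracted. Tied markers or a negative/undefined
    result fall back to the 1,000-N sentinel; positive estimates are
    clamped below at 100 bases.
    """
    lpos = _oriented_positions(left)
    rpos = _oriented_positions(right)
    l_marker_pos, l_cm = lpos[-1]  # nearest left's right end
    r_marker_pos, r_cm = rpos[0]  # nearest right's left end
    delta_cm = r_cm - l_cm
    if round(delta_cm, CM_TIE_DECIMALS) <= 0:
        return GAP_UNKNOWN_LEN
    left_overhang = left.length - 1 - l_marker_pos
    right_overhang = r_marker_pos
    gap = delta_cm * bp_per_cm - left_overhang - right_overhang
    if gap < 0:
        return GAP_UNKNOWN_LEN
    return max(MIN_GAP, int(round(gap)))


def build_pseudomolecules(
    plan: AnchorPlan, scaffolds: SequenceSet, bp_per_cm: float
) -> tuple[SequenceSet, list[AgpRow]]:
    """Concatenate oriented scaffolds with estimated-N gaps per linkage group.

    Returns the emitted sequences (one pseudomolecule per LG, plus
    unanchored scaffolds passed through unchanged as their own objects) and
    the corresponding AGP v2.0 rows. AGP/FASTA length consistency is
    asserted on every build.
    """
    out_seqs: list[tuple[str, str]] = []
    rows: list[AgpRow] = []
    for lg in sorted(plan.lgs):
        entries = plan.lgs[lg]
        parts: list[str] = []
        pos = 0  # 0-based length so far
        part_no = 0
        for i, entry in enumerate(entries):
            seq = scaffolds[entry.scaffold_id]
            emit_orient = "-" if entry.orientation == "-" else "+"
            parts.append(revcomp(seq) if emit_orient == "-" else seq)
            part_no += 1
            rows.append(
                AgpRow(lg, pos + 1, pos + len(seq), part_no, "W",
                       component_id=entry.scaffold_id, component_beg=1,
                       component_end=len(seq), orientation=emit_orient)
            )
            pos += len(seq)
            if i < len(entries) - 1:
                gap = estimate_gap(entry, entries[i + 1], bp_per_cm)
                entry.gap_after = gap
                ctype = "U" if gap == GAP_UNKNOWN_LEN else "N"
                parts.append("N" * gap)
                part_no += 1
                rows.append(
                    AgpRow(lg, pos + 1, pos + gap, part_no, ctype,
                           gap_length=gap)
                )
                pos += gap
        seq = "".join(parts)
        assert len(seq) == pos, f"AGP/FASTA length mismatch for {lg}"
        out_seqs.append((lg, seq))
    for sid in plan.unanchored:
        seq = scaffolds[sid]
        out_seqs.append((sid, seq))
        rows.append(
            AgpRow(sid, 1, len(seq), 1, "W", component_id=sid,
                   component_beg=1, component_end=len(seq), orientation="+")
        )
    return SequenceSet(out_seqs, kind="pseudomolecule"), rows


def relabel_groups(
    plan: AnchorPlan, reference_markers: dict[str, str]
) -> tuple[AnchorPlan, list[str]]:
    """Rename linkage groups by majority vote of reference chromosome labels
    among each group's markers; ties break to the smaller label.

    Returns the relabelled plan and a list of warnings (groups with no
    overlapping markers keep their provisional name; vote conflicts are
    reported).
    """
    if not reference_markers:
        raise ValueError("reference table is empty")
    warnings: list[str] = []
    new_lgs: dict[str, list[AnchoredScaffold]] = {}
    for lg in sorted(plan.lgs):
        votes: dict[str, int] = {}
        for entry in plan.lgs[lg]:
            for mid, _, _ in entry.markers:
                label = reference_markers.get(mid)
                if label is not None:
                    votes[label] = votes.get(label, 0) + 1
        if not votes:
            warnings.append(f"{lg}: no overlapping reference markers; name kept")
            label = lg
        else:
            best = max(votes.values())
            winners = sorted(k for k, v in votes.items() if v == best)
            label = winners[0]
            if len(winners) > 1:
                warnings.append(f"{lg}: tie between {winners}; chose {label}")
            losers = {k: v for k, v in votes.items() if k != label}
            if losers:
                warnings.append(f"{lg}: minority votes {losers}")
        if label in new_lgs:
            warnings.append(f"label {label} assigned to more than one group")
            label = f"{label}_{lg}"
        entries = plan.lgs[lg]
        for e in entries:
            e.lg = label
        new_lgs[label] = entries
    return AnchorPlan(lgs=new_lgs, unanchored=list(plan.unanchored)), warnings
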