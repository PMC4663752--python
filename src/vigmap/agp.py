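"""AGP v2.0 reading, writing and reconstruction.

Only the two row flavours a map-anchoring pipeline emits are supported:
``W`` component rows (whole scaffolds, 1-based inclusive coordinates) and
``N``/``U`` gap rows (specified vs. unknown gap length). ``rebuild_fasta``
reconstitutes object sequences from an AGP plus component sequences, the
round-trip check used after every pseudomolecule build.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from vigmap.seqs import SequenceSet, revcomp

GAP_UNKNOWN_LEN = 1000  # inserted when a gap size cannot be estimated


@dataclass(frozen=True)
class AgpRow:
    object_id: str
    object_beg: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # W, N or U
    # W rows:
    component_id: str = ""
    component_beg: int = 0
    component_end: int = 0
    orientation: str = "+"
    # N/U rows:
    gap_length: int = 0
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "map"

    def to_line(self) -> str:
        if self.component_type == "W":
            cols = [
                self.object_id,
                str(self.object_beg),
                str(self.object_end),
                str(self.part_number),
                "W",
                self.component_id,
                str(self.component_beg),
                str(self.component_end),
                self.orientation,
            ]
        else:
            cols = [
                self.object_id,
                str(self.object_beg),
                str(self.object_end),
                str(self.part_number),
                self.component_type,
                str(self.gap_length),
                self.gap_type,
                self.linkage,
                self.evidence,
            ]
        return "\t".join(cols)


def write_agp(rows: list[AgpRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            c = line.split("\t")
            if c[4] == "W":
                rows.append(
                    AgpRow(c[0], int(c[1]), int(c[2]), int(c[3]), "W",
                           component_id=c[5], component_beg=int(c[6]),
                           component_end=int(c[7]), orientation=c[8])
                )
            elif c[4] in ("N", "U"):
                rows.append(
                    AgpRow(c[0], int(c[1]), int(c[2]), int(c[3]), c[4],
                           gap_length=int(c[5]), gap_type=c[6], linkage=c[7],
                           evidence=c[8])
                )
            else:
                raise ValueError(f"unsupported AGP component type {c[4]!r}")
    return rows


def rebuild_fasta(rows: list[AgpRow], components: SequenceSet) -> SequenceSet:
    """Reconstruct object sequences from AGP rows and component sequences."""
    objects: dict[str, list[str]] = {}
    expected: dict[str, int] = {}
    for row in rows:
        parts = objects.setdefault(row.object_id, [])
        if row.component_type == "W":
            seq = components[row.component_id][row.component_beg - 1 : row.component_end]
            if row.orientation == "-":
                seq = revcomp(seq)
            parts.append(seq)
        else:
            parts.append("N" * row.gap_length)
        expected[row.object_id] = max(expected.get(row.object_id, 0), row.object_end)
    out = []
    for oid, parts in objects.items():
        seq = "".join(parts)
        if len(seq) != expected[oid]:
            raise ValueError(
                f"AGP object {oid!r}: rebuilt length {len(seq)} != stated {expected[oid]}"
            )
        out.append((oid, seq))
    return SequenceSet(out, kind="pseudomolecule")
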