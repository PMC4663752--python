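"""Nucleotide sequence container and FASTA I/O.

``SequenceSet`` is the in-memory form of an assembly at any stage (contigs,
scaffolds, or pseudomolecules): an ordered mapping of unique ids to upper-case
sequences over ``{A, C, G, T, N}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_KINDS = ("contig", "scaffold", "pseudomolecule")


def revcomp(seq: str) -> str:
    """Reverse complement (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceSet:
    """An ordered set of named nucleotide sequences.

    Parameters
    ----------
    records
        Iterable of ``(id, sequence)`` pairs. Ids must be unique and
        sequences non-empty.
    kind
        One of ``contig``, ``scaffold``, ``pseudomolecule``. Contigs are
        expected to be gap-free; scaffolds may contain N-runs of estimated
        size.
    """

    records: list[tuple[str, str]] = field(default_factory=list)
    kind: str = "scaffold"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        clean: list[tuple[str, str]] = []
        seen: set[str] = set()
        for sid, seq in self.records:
            if sid in seen:
                raise ValueError(f"duplicate sequence id {sid!r}")
            if not seq:
                raise ValueError(f"empty sequence for {sid!r}")
            seen.add(sid)
            clean.append((sid, seq.upper()))
        self.records = clean
        self._index = {sid: i for i, (sid, _) in enumerate(self.records)}

    # -- mapping-ish access -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, sid: str) -> bool:
        return sid in self._index

    def __getitem__(self, sid: str) -> str:
        return self.records[self._index[sid]][1]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.records]

    @property
    def total_bp(self) -> int:
        return sum(self.lengths)

    @property
    def n_count(self) -> int:
        return sum(seq.count("N") for _, seq in self.records)

    def subset(self, ids: Iterable[str], kind: str | None = None) -> "SequenceSet":
        wanted = list(ids)
        return SequenceSet([(sid, self[sid]) for sid in wanted], kind or self.kind)

    # -- FASTA --------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path, kind: str = "scaffold") -> "SequenceSet":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(records, kind)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        recs = [
            SeqRecord(Seq(seq), id=sid, description="") for sid, seq in self.records
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(recs)
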