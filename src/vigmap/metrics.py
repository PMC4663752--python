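"""Length-based assembly statistics.

Implements the evaluation side of a genome project: Nx/NGx statistics and NG
graphs, the two coverage conventions found in assembly tables (total length
over genome size vs. non-gap length over genome size), gap fraction, a
telomere-motif scan for chromosome termini, and a k-mer-histogram genome-size
estimate.

Conventions pinned by published assembly tables:

* mean length is **floor** division of total by count;
* percentages are reported to one decimal, ties rounded half-up;
* ``ng(x)`` returns 0 when the assembly never reaches x% of the genome size,
  so NG graphs can be drawn to their termination point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vigmap.seqs import SequenceSet, revcomp
from vigmap.util import round_half_up

DEFAULT_TELOMERE_MOTIF = "TTTAGGG"


@dataclass(frozen=True)
class AssemblyStats:
    """Summary statistics for one assembly against an estimated genome size."""

    n_sequences: int
    total_bp: int
    mean_bp: int
    max_bp: int
    n50_bp: int
    ng: tuple[int, ...]  # NG1..NG100, 0 where unreached
    coverage_pct: float
    gap_pct: float


def _sorted_cumsum(lengths) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    return arr, np.cumsum(arr)


def nx(lengths, x: float) -> int:
    """Nx statistic: length at which the cumulative descending-sorted sum
    first reaches x% of the total assembly length.

    N50 is ``nx(lengths, 50)``.
    """
    if len(lengths) == 0:
        raise ValueError("no sequences")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    if any(l <= 0 for l in lengths):
        raise ValueError("sequence lengths must be positive")
    arr, cum = _sorted_cumsum(lengths)
    target = x / 100.0 * cum[-1]
    idx = int(np.searchsorted(cum, target, side="left"))
    return int(arr[idx])


def ng(lengths, genome_size: int, x: float) -> int:
    """NGx statistic: the last-counted length when the cumulative
    descending-sorted sum first reaches x% of the *estimated genome size*;
    0 if the assembly total never reaches it.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if len(lengths) == 0:
        return 0
    arr, cum = _sorted_cumsum(lengths)
    target = x / 100.0 * genome_size
    if cum[-1] < target:
        return 0
    idx = int(np.searchsorted(cum, target, side="left"))
    return int(arr[idx])


def ng_curve(lengths, genome_size: int) -> tuple[int, ...]:
    """NG1..NG100 vector (an "NG graph" when plotted)."""
    if len(lengths) == 0:
        return tuple([0] * 100)
    arr, cum = _sorted_cumsum(lengths)
    targets = np.arange(1, 101) / 100.0 * genome_size
    idx = np.searchsorted(cum, targets, side="left")
    out = np.where(idx < len(arr), arr[np.minimum(idx, len(arr) - 1)], 0)
    return tuple(int(v) for v in out)


def coverage_pct(seqs: SequenceSet, genome_size: int, dialect: str = "length") -> float:
    """Assembly coverage of the estimated genome, percent, one decimal.

    ``dialect="length"`` divides the total assembly length by the genome
    size; ``dialect="nongap"`` first subtracts N characters. Published
    tables use both conventions without saying which; both are exposed.
    """
    if len(seqs) == 0:
        return 0.0
    return coverage_from_totals(seqs.total_bp, seqs.n_count, genome_size, dialect)


def coverage_from_totals(
    total_bp: int, n_count: int, genome_size: int, dialect: str = "length"
) -> float:
    """Coverage computed from pre-tabulated totals (see :func:`coverage_pct`)."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if dialect == "length":
        num = total_bp
    elif dialect == "nongap":
        num = total_bp - n_count
    else:
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    return round_half_up(100.0 * num / genome_size, 1)


def gap_fraction(seqs: SequenceSet) -> float:
    """Percent of assembly bases that are Ns (unrounded)."""
    total = seqs.total_bp
    if total == 0:
        return 0.0
    return 100.0 * seqs.n_count / total


def mean_length(total_bp: int, n_sequences: int) -> int:
    """Mean sequence length as printed in assembly tables: floor division."""
    if n_sequences <= 0:
        raise ValueError("no sequences")
    return total_bp // n_sequences


def summarize(seqs: SequenceSet, genome_size: int) -> AssemblyStats:
    """Full length-statistics record for one assembly."""
    if len(seqs) == 0:
        raise ValueError("no sequences")
    lengths = seqs.lengths
    total = seqs.total_bp
    return AssemblyStats(
        n_sequences=len(seqs),
        total_bp=total,
        mean_bp=mean_length(total, len(seqs)),
        max_bp=max(lengths),
        n50_bp=nx(lengths, 50),
        ng=ng_curve(lengths, genome_size),
        coverage_pct=coverage_pct(seqs, genome_size, "length"),
        gap_pct=round_half_up(gap_fraction(seqs), 1),
    )


def _count_occurrences(window: str, motif: str) -> int:
    return window.count(motif) + window.count(revcomp(motif))


def telomere_scan(
    seq: str,
    motif: str = DEFAULT_TELOMERE_MOTIF,
    terminal_window: int = 1000,
    min_copies: int = 3,
) -> tuple[bool, bool]:
    """Detect telomeric repeat arrays at the two termini of a sequence.

    A terminus tests positive when its terminal window contains at least
    ``min_copies`` occurrences of the motif in either orientation (plant
    telomere arrays read ``CCCTAAA...`` on the left end of the forward
    strand and ``...TTTAGGG`` on the right end).

    Sequences shorter than the window are scanned whole.
    """
    if terminal_window < len(motif) * min_copies:
        raise ValueError("terminal_window too small for min_copies of the motif")
    seq = seq.upper()
    w = min(terminal_window, len(seq))
    left = seq[:w]
    right = seq[-w:]
    return (
        _count_occurrences(left, motif) >= min_copies,
        _count_occurrences(right, motif) >= min_copies,
    )


def plot_ng_curves(curves: dict[str, tuple[int, ...]], path) -> None:
    """Write an NG-graph figure (NG1..NG100 per assembly) to ``path``.

    Zero (unreached) values terminate each line, so assemblies of
    different coverage end at different x, as NG graphs are drawn.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        xs = [x for x, v in enumerate(curve, start=1) if v > 0]
        ys = [v for v in curve if v > 0]
        ax.plot(xs, ys, label=label)
    ax.set_yscale("log")
    ax.set_xlabel("NG(x)")
    ax.set_ylabel("length (bp)")
    ax.set_xlim(1, 100)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def genome_size_from_kmers(entries, min_multiplicity: int = 4) -> int:
    """Estimate genome size from a k-mer multiplicity histogram.

    ``entries`` is a sequence of ``(multiplicity, n_distinct_kmers)`` rows.
    Rows below ``min_multiplicity`` are excluded as the sequencing-error
    peak; the coverage peak is the modal multiplicity of the remainder and
    the genome size is the total retained k-mer mass divided by that mode.
    """
    arr = np.asarray([(m, c) for m, c in entries], dtype=np.float64).reshape(-1, 2)
    if arr.size and np.any(np.diff(arr[:, 0]) <= 0):
        raise ValueError("multiplicities must be strictly increasing")
    kept = arr[arr[:, 0] >= min_multiplicity] if arr.size else arr
    if kept.size == 0 or kept[:, 1].sum() == 0:
        raise ValueError("cannot locate coverage peak")
    mode_i = int(np.argmax(kept[:, 1]))
    # A mode sitting on the cutoff boundary of a monotonically decaying tail
    # is the shoulder of the error peak, not a coverage peak.
    if mode_i == 0 and len(kept) > 1 and np.all(np.diff(kept[:, 1]) <= 0):
        raise ValueError("cannot locate coverage peak")
    mode = kept[mode_i, 0]
    mass = float(np.sum(kept[:, 0] * kept[:, 1]))
    return int(round(mass / mode))
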