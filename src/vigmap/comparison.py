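"""Cross-assembly accounting and recombination-landscape tracks.

Gene-family membership tables (one clustering over the genes annotated on
several assemblies of the same genome) are summarised into per-assembly
family-size deltas against a reference assembly — fragmented or missing loci
in a poorer assembly show up as size-reduced families and falsely-called
singletons. Core-gene presence fractions and windowed recombination tracks
(cM/Mb and cM/gene) round out the comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vigmap.util import round_half_up

CEG_TOTAL = 458  # size of the conserved core-gene set


@dataclass(frozen=True)
class FamilyDelta:
    """Per-assembly gene-family accounting against the reference assembly."""

    assembly_id: str
    n_increased_families: int
    n_reduced_families: int
    genes_gained: int
    genes_lost: int
    n_singletons: int


def family_deltas(
    table: pd.DataFrame, reference_assembly: str
) -> dict[str, FamilyDelta]:
    """Summarise family-size differences of each assembly vs the reference.

    ``table`` has columns ``gene_id, family_id, assembly_id`` (a gene
    appears once per assembly). For each family, the delta is its size in
    the assembly minus its size in the reference; gains and losses are
    aggregated separately. A singleton is a gene whose family has exactly
    one member overall (hence present in exactly one assembly).
    """
    required = {"gene_id", "family_id", "assembly_id"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    sizes = (
        table.groupby(["family_id", "assembly_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    if reference_assembly not in sizes.columns:
        raise ValueError(f"reference assembly {reference_assembly!r} not in table")
    fam_total = sizes.sum(axis=1)
    singleton_assembly = (
        sizes.loc[fam_total == 1].idxmax(axis=1) if (fam_total == 1).any() else pd.Series(dtype=object)
    )
    singleton_counts = singleton_assembly.value_counts()
    out: dict[str, FamilyDelta] = {}
    ref = sizes[reference_assembly]
    for asm in sizes.columns:
        delta = sizes[asm] - ref
        out[asm] = FamilyDelta(
            assembly_id=asm,
            n_increased_families=int((delta > 0).sum()),
            n_reduced_families=int((delta < 0).sum()),
            genes_gained=int(delta[delta > 0].sum()),
            genes_lost=int(-delta[delta < 0].sum()),
            n_singletons=int(singleton_counts.get(asm, 0)),
        )
    return out


def ceg_fraction(present: int, total: int = CEG_TOTAL) -> float:
    """Percent of the conserved core-gene set present, one decimal."""
    if not 0 <= present <= total:
        raise ValueError("present must be between 0 and total")
    return round_half_up(100.0 * present / total, 1)


def recomb_tracks(
    markers: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    window: int = 1_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed recombination tracks over anchored pseudomolecules.

    ``markers`` has columns ``lg, pos, cm`` (physical position on the
    pseudomolecule and map position); ``genes`` optionally has columns
    ``lg, start, end``. The cM value at any physical coordinate is linear
    interpolation between flanking markers (clamped to the terminal markers
    beyond the map ends); each window reports its cM span, cM/Mb, gene
    count (genes whose start falls in the window) and cM/gene (NaN where
    the window has no genes).
    """
    rows = []
    for lg, sub in markers.groupby("lg", sort=True):
        sub = sub.sort_values("pos", kind="stable")
        if len(sub) < 2:
            continue
        pos = sub["pos"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        length = (chrom_lengths or {}).get(lg, int(pos[-1]) + 1)
        gene_starts = (
            np.sort(genes.loc[genes["lg"] == lg, "start"].to_numpy())
            if genes is not None
            else np.array([])
        )
        start = 0
        while start < length:
            end = min(start + window, length)
            cm_span = float(np.interp(end, pos, cm) - np.interp(start, pos, cm))
            n_genes = int(
                np.searchsorted(gene_starts, end) - np.searchsorted(gene_starts, start)
            )
            mb = (end - start) / 1e6
            rows.append(
                {
                    "lg": lg,
                    "start": start,
                    "end": end,
                    "cm_span": cm_span,
                    "gene_count": n_genes,
                    "cm_per_mb": cm_span / mb if mb > 0 else np.nan,
                    "cm_per_gene": cm_span / n_genes if n_genes > 0 else np.nan,
                }
            )
            start = end
    return pd.DataFrame(
        rows,
        columns=["lg", "start", "end", "cm_span", "gene_count", "cm_per_mb", "cm_per_gene"],
    )


def population_size_for(cm_per_gene: float) -> int:
    """Mapping population size needed to resolve a region of the given
    cM/gene: one expected recombinant between neighbouring genes among the
    2n gametes of n plants gives n = 100 / (cM/gene).
    """
    if cm_per_gene <= 0:
        raise ValueError("cm_per_gene must be positive")
    return int(round(100.0 / cm_per_gene))
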