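"""Genetic map construction from F2 genotype matrices.

Starting from codominant genotype calls (AA/AB/BB/NA) on an F2 population,
the module filters missing data, estimates pairwise recombination fractions
by maximum likelihood (EM over the nine joint-genotype classes, phase chosen
by likelihood), groups markers into linkage groups, orders each group by a
travelling-salesman-style objective (greedy nearest-neighbour chaining
refined by 2-opt), and converts adjacent recombination fractions into
cumulative map distances with the Haldane or Kosambi map function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx_graph
import numpy as np
import pandas as pd

CODE_OF = {"AA": 0, "AB": 1, "BB": 2, "NA": -1}
NAME_OF = {v: k for k, v in CODE_OF.items()}

# F1 gametes for a marker pair: (allele at A, allele at B, recombinant?)
_GAMETES = [(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0)]

EM_TOL = 1e-8
EM_MAX_ITER = 1000
EM_R0 = 0.25
MIN_INFORMATIVE = 20


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """F2 genotype calls: individuals x markers, codes AA/AB/BB/NA.

    ``calls`` is int8 with AA=0, AB=1, BB=2, NA=-1.
    """

    individuals: list[str]
    markers: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("calls shape does not match individual/marker lists")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be AA/AB/BB/NA")

    def column(self, marker: str) -> np.ndarray:
        return self.calls[:, self.markers.index(marker)]

    @property
    def missing_by_individual(self) -> np.ndarray:
        return (self.calls == -1).mean(axis=1)

    @property
    def missing_by_marker(self) -> np.ndarray:
        return (self.calls == -1).mean(axis=0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        calls = df.fillna("NA").map(lambda v: CODE_OF[str(v)]).to_numpy(dtype=np.int8)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), calls)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0, dtype=str))

    def to_dataframe(self) -> pd.DataFrame:
        named = np.vectorize(NAME_OF.get)(self.calls)
        return pd.DataFrame(named, index=self.individuals, columns=self.markers)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="individual")


@dataclass(frozen=True)
class RfEstimate:
    """Maximum-likelihood recombination fraction for one marker pair."""

    r: float
    lod: float
    n_informative: int
    phase: str = "coupling"  # or "repulsion"


@dataclass
class GeneticMap:
    """Ordered markers with cM positions, per linkage group."""

    groups: list[tuple[str, list[tuple[str, float]]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lg, markers in self.groups:
            last = -math.inf
            for mid, cm in markers:
                if mid in seen:
                    raise ValueError(f"marker {mid!r} appears in more than one group")
                seen.add(mid)
                if cm < last - 1e-9:
                    raise ValueError(f"cM positions not non-decreasing in {lg}")
                last = cm

    def marker_lookup(self) -> dict[str, tuple[str, float]]:
        return {
            mid: (lg, cm) for lg, markers in self.groups for mid, cm in markers
        }

    @property
    def n_markers(self) -> int:
        return sum(len(m) for _, m in self.groups)

    def total_length(self) -> float:
        return sum(m[-1][1] for _, m in self.groups if m)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"lg": str, "marker": str})
        groups = []
        for lg, sub in df.groupby("lg", sort=True):
            sub = sub.sort_values("cm", kind="stable")
            groups.append((str(lg), list(zip(sub["marker"], sub["cm"].astype(float)))))
        return cls(groups)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"lg": lg, "marker": mid, "cm": round(cm, 4)}
            for lg, markers in self.groups
            for mid, cm in markers
        ]
        pd.DataFrame(rows, columns=["lg", "marker", "cm"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# missing-data filtering
# ---------------------------------------------------------------------------


def filter_missing(g: GenotypeMatrix, max_missing: float = 0.10) -> GenotypeMatrix:
    """Iteratively drop individuals and markers whose NA fraction exceeds
    ``max_missing``, worst offender first, until every row and column passes.
    """
    ind = list(g.individuals)
    mk = list(g.markers)
    calls = g.calls.copy()
    while True:
        if calls.size == 0:
            raise ValueError("no data after filtering")
        na = calls == -1
        row_frac = na.mean(axis=1)
        col_frac = na.mean(axis=0)
        worst_row = int(np.argmax(row_frac))
        worst_col = int(np.argmax(col_frac))
        if row_frac[worst_row] <= max_missing and col_frac[worst_col] <= max_missing:
            break
        # worst offender first; exact ties drop the marker (cheaper to lose)
        if col_frac[worst_col] >= row_frac[worst_row]:
            calls = np.delete(calls, worst_col, axis=1)
            del mk[worst_col]
        else:
            calls = np.delete(calls, worst_row, axis=0)
            del ind[worst_row]
    if not ind or not mk:
        raise ValueError("no data after filtering")
    return GenotypeMatrix(ind, mk, calls)


# ---------------------------------------------------------------------------
# recombination fraction (EM)
# ---------------------------------------------------------------------------


def _class_tables(r: float) -> tuple[np.ndarray, np.ndarray]:
    """Per joint-genotype class: probability and expected recombinant-gamete
    count x probability, under recombination fraction ``r``."""
    p = np.empty(4)
    p[0] = p[3] = (1.0 - r) / 2.0
    p[1] = p[2] = r / 2.0
    den = np.zeros((3, 3))
    num = np.zeros((3, 3))
    for a1, b1, r1 in _GAMETES:
        for a2, b2, r2 in _GAMETES:
            pr = p[a1 + 2 * b1] * p[a2 + 2 * b2]
            den[a1 + a2, b1 + b2] += pr
            num[a1 + a2, b1 + b2] += pr * (r1 + r2)
    return den, num


def _loglik(r: float, counts: np.ndarray) -> float:
    den, _ = _class_tables(r)
    with np.errstate(divide="ignore"):
        logp = np.log(den)
    mask = counts > 0
    return float(np.sum(counts[mask] * logp[mask]))


def _em_rf(counts: np.ndarray) -> float:
    n = counts.sum()
    r = EM_R0
    for _ in range(EM_MAX_ITER):
        den, num = _class_tables(r)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_rec = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        r_new = float(np.sum(counts * e_rec) / (2.0 * n))
        r_new = min(max(r_new, 1e-12), 0.5)
        if abs(r_new - r) < EM_TOL:
            r = r_new
            break
        r = r_new
    return r


def joint_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over individuals with both calls present."""
    a = np.asarray(a)
    b = np.asarray(b)
    ok = (a >= 0) & (b >= 0)
    idx = a[ok].astype(np.int64) * 3 + b[ok].astype(np.int64)
    return np.bincount(idx, minlength=9).reshape(3, 3).astype(np.float64)


def estimate_rf(a: np.ndarray, b: np.ndarray) -> RfEstimate:
    """ML recombination fraction for two codominant F2 marker columns.

    Both linkage phases are fitted and the higher-likelihood one is kept;
    the LOD score compares the fitted ``r`` against independence (r=0.5).
    """
    counts = joint_counts(a, b)
    n_inf = int(counts.sum())
    if n_inf < MIN_INFORMATIVE:
        raise ValueError("uninformative pair")
    best = None
    for phase, c in (("coupling", counts), ("repulsion", counts[:, ::-1])):
        r = _em_rf(c)
        ll = _loglik(r, c)
        if best is None or ll > best[2]:
            best = (phase, r, ll, c)
    phase, r, ll, c = best
    lod = max(0.0, (ll - _loglik(0.5, c)) / math.log(10.0))
    return RfEstimate(r=r, lod=lod, n_informative=n_inf, phase=phase)


def pairwise_rf(
    g: GenotypeMatrix, markers: Sequence[str] | None = None
) -> dict[tuple[str, str], RfEstimate]:
    """All-pairs recombination fractions; uninformative pairs are omitted."""
    mk = list(markers) if markers is not None else list(g.markers)
    cols = {m: g.column(m) for m in mk}
    out: dict[tuple[str, str], RfEstimate] = {}
    for i, mi in enumerate(mk):
        for mj in mk[i + 1 :]:
            try:
                out[(mi, mj)] = estimate_rf(cols[mi], cols[mj])
            except ValueError:
                continue
    return out


def rf_between(rf: dict, a: str, b: str) -> RfEstimate | None:
    return rf.get((a, b)) or rf.get((b, a))


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------


def haldane_cm(r: float) -> float:
    """Haldane map distance (no crossover interference): d = -50 ln(1-2r)."""
    if not 0 <= r < 0.5:
        raise ValueError("unlinked")
    return -50.0 * math.log1p(-2.0 * r)


def kosambi_cm(r: float) -> float:
    """Kosambi map distance (partial interference): d = 25 ln((1+2r)/(1-2r))."""
    if not 0 <= r < 0.5:
        raise ValueError("unlinked")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


MAP_FUNCTIONS = {"haldane": haldane_cm, "kosambi": kosambi_cm}


# ---------------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------------


def group_markers(
    markers: Sequence[str],
    rf: dict[tuple[str, str], RfEstimate],
    lod_min: float = 3.0,
    r_max: float = 0.35,
) -> tuple[list[list[str]], list[str]]:
    """Partition markers into linkage groups: connected components of the
    graph with an edge wherever LOD >= ``lod_min`` and r <= ``r_max``.

    Returns ``(groups, singletons)``; groups are sorted by size (descending)
    then by smallest member id, members sorted lexicographically.
    """
    graph = nx_graph.Graph()
    graph.add_nodes_from(markers)
    for (a, b), est in rf.items():
        if est.lod >= lod_min and est.r <= r_max:
            graph.add_edge(a, b)
    comps = [sorted(c) for c in nx_graph.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    groups = [c for c in comps if len(c) > 1]
    singletons = sorted(m for c in comps if len(c) == 1 for m in c)
    return groups, singletons


def _path_cost(order: list[str], dist: dict[tuple[str, str], float]) -> float:
    return sum(dist[(order[i], order[i + 1])] for i in range(len(order) - 1))


def _two_opt(order: list[str], dist: dict[tuple[str, str], float]) -> list[str]:
    improved = True
    while improved:
        improved = False
        n = len(order)
        for i in range(n - 1):
            for j in range(i + 1, n):
                # reverse order[i..j]; only edges (i-1,i) and (j,j+1) change
                before = 0.0
                after = 0.0
                if i > 0:
                    before += dist[(order[i - 1], order[i])]
                    after += dist[(order[i - 1], order[j])]
                if j < n - 1:
                    before += dist[(order[j], order[j + 1])]
                    after += dist[(order[i], order[j + 1])]
                if after < before - 1e-12:
                    order[i : j + 1] = reversed(order[i : j + 1])
                    improved = True
    return order


def order_markers(
    group: Sequence[str], rf: dict[tuple[str, str], RfEstimate]
) -> list[str]:
    """Order markers within a linkage group by seriation.

    Greedy nearest-neighbour chaining from every start (ties broken by
    marker id) seeds a 2-opt refinement that minimises the sum of adjacent
    recombination fractions. Pairs without an estimate are penalised as
    r = 0.5. The whole-group orientation is fixed by the smaller terminal
    marker id.
    """
    mk = sorted(group)
    if len(mk) < 2:
        return list(mk)
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(mk):
        for b in mk[i + 1 :]:
            est = rf_between(rf, a, b)
            d = est.r if est is not None else 0.5
            dist[(a, b)] = dist[(b, a)] = d
    best_order: list[str] | None = None
    best_cost = math.inf
    for start in mk:
        remaining = [m for m in mk if m != start]
        order = [start]
        while remaining:
            cur = order[-1]
            nxt = min(remaining, key=lambda m: (dist[(cur, m)], m))
            order.append(nxt)
            remaining.remove(nxt)
        cost = _path_cost(order, dist)
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_order = order
    order = _two_opt(best_order, dist)
    if order[-1] < order[0]:
        order.reverse()
    return order


def map_distances(
    order: Sequence[str],
    rf: dict[tuple[str, str], RfEstimate],
    map_function: str = "kosambi",
) -> list[tuple[str, float]]:
    """Cumulative cM positions along an ordered marker list (first at 0)."""
    fn = MAP_FUNCTIONS[map_function]
    out = [(order[0], 0.0)]
    cm = 0.0
    for a, b in zip(order, order[1:]):
        est = rf_between(rf, a, b)
        if est is None or est.r >= 0.5:
            raise ValueError("break group")
        cm += fn(est.r)
        out.append((b, cm))
    return out


def build_map(
    g: GenotypeMatrix,
    max_missing: float = 0.10,
    lod_min: float = 3.0,
    r_max: float = 0.35,
    map_function: str = "kosambi",
) -> tuple[GeneticMap, list[str]]:
    """End-to-end map construction; returns the map and unplaced singletons.

    Linkage groups are labelled LG1, LG2, ... in decreasing marker count.
    """
    g = filter_missing(g, max_missing)
    rf = pairwise_rf(g)
    groups, singletons = group_markers(g.markers, rf, lod_min, r_max)
    built = []
    for i, grp in enumerate(groups, start=1):
        order = order_markers(grp, rf)
        built.append((f"LG{i}", map_distances(order, rf, map_function)))
    return GeneticMap(built), singletons
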