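"""Shortest-path analysis of (real or synthetic) metabolic networks.

Metabolic networks are bipartite: metabolites connect only through
reactions.  After stripping cofactors and non-carbon metabolites, the
stoichiometric matrix becomes an unweighted undirected bipartite graph whose
metabolite-to-metabolite distances, divided by two, count reactions along
the path.  The headline summary is the nearest-size matrix A[i][j]: for each
i-carbon compound take the distance to its *nearest* j-carbon compound, then
average over all i-carbon compounds (min first, then mean).  Because plain
graph paths ignore mass balance, these distances lower-bound the
flux-consistent pathway lengths; the EFM-based variant recomputes the same
matrix from minimal elementary-mode supports on networks small enough to
enumerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BipartiteMetabolicGraph",
    "NearestSizeMatrix",
    "read_stoichiometric_tsv",
    "build_graph",
    "all_pairs_shortest",
    "nearest_size_matrix",
    "efm_nearest_size_matrix",
]

#: sentinel for unreachable pairs (written as "NA" in TSV output)
UNREACHABLE = math.inf


@dataclass
class BipartiteMetabolicGraph:
    graph: nx.Graph = field(repr=False)
    metabolites: list[str] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for u, v in self.graph.edges:
            um, vm = u in set(self.metabolites), v in set(self.metabolites)
            if um == vm:
                raise AssertionError(f"edge {u}-{v} is not metabolite-reaction")


def read_stoichiometric_tsv(path: str | Path) -> pd.DataFrame:
    """Metabolites x reactions table: first column = metabolite ids, header =
    reaction ids (the dialect written by the chemistry module's export)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def build_graph(
    stoich: pd.DataFrame,
    *,
    cofactors: set[str] | None = None,
    carbon_counts: dict[str, int] | None = None,
    drop_exchange: bool = True,
    directed: bool = False,
) -> BipartiteMetabolicGraph:
    """Bipartite graph from a stoichiometric table.

    Removes blacklisted cofactors and (when carbon counts are supplied)
    zero-carbon metabolites such as water or phosphate; exchange/transport
    columns (ids starting ``EX_`` or ``TR_``) are dropped unless
    ``drop_exchange`` is False.  By default edges are undirected (all
    reactions treated as reversible); with ``directed`` the stoichiometric
    signs orient them substrate -> reaction -> product.  Raises if nothing
    is left.
    """
    cofactors = cofactors or set()
    keep_mets = []
    for met in stoich.index:
        if met in cofactors:
            continue
        if carbon_counts is not None and carbon_counts.get(met, 0) == 0:
            continue
        keep_mets.append(met)
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(keep_mets, kind="metabolite")
    used_rxns = []
    for rxn in stoich.columns:
        if drop_exchange and (rxn.startswith("EX_") or rxn.startswith("TR_")):
            continue
        partners = [m for m in keep_mets if stoich.at[m, rxn] != 0]
        if not partners:
            continue
        g.add_node(rxn, kind="reaction")
        used_rxns.append(rxn)
        for m in partners:
            if directed:
                if stoich.at[m, rxn] < 0:
                    g.add_edge(m, rxn)
                else:
                    g.add_edge(rxn, m)
            else:
                g.add_edge(m, rxn)
    if not used_rxns:
        raise ValueError("graph is empty after cofactor/carbon filtering")
    out = BipartiteMetabolicGraph(graph=g, metabolites=keep_mets, reactions=used_rxns)
    out.validate()
    return out


def all_pairs_shortest(bg: BipartiteMetabolicGraph) -> pd.DataFrame:
    """Metabolite-to-metabolite distances in reaction counts.

    Runs Johnson's all-pairs algorithm (exact on these unit-weight graphs,
    where it reduces to repeated Dijkstra/BFS) and halves the bipartite
    node-path length.  Unreachable pairs get the infinity sentinel.
    """
    if not bg.metabolites:
        raise ValueError("graph has no metabolites")
    dist = nx.johnson(bg.graph, weight="weight")
    mets = bg.metabolites
    out = pd.DataFrame(UNREACHABLE, index=mets, columns=mets)
    for m in mets:
        row = dist.get(m, {})
        for t, path in row.items():
            if t in out.columns:
                out.at[m, t] = (len(path) - 1) / 2
    return out


def nearest_size_matrix(
    distances: pd.DataFrame, carbon_counts: dict[str, int]
) -> "NearestSizeMatrix":
    """Min-then-average aggregation of distances into size classes.

    For each input compound the distance to its nearest j-carbon target is
    taken first (excluding itself), and only then averaged over all i-carbon
    inputs.  Classes with no finite pair stay at the sentinel.
    """
    missing = [m for m in distances.index if m not in carbon_counts]
    if missing:
        raise ValueError(f"no carbon count for {missing[:5]}")
    sizes = sorted({carbon_counts[m] for m in distances.index})
    by_size: dict[int, list[str]] = {s: [] for s in sizes}
    for m in distances.index:
        by_size[carbon_counts[m]].append(m)
    A = pd.DataFrame(UNREACHABLE, index=sizes, columns=sizes)
    counts = pd.DataFrame(0, index=sizes, columns=sizes)
    for i in sizes:
        for j in sizes:
            per_input = []
            for m in by_size[i]:
                targets = [t for t in by_size[j] if t != m]
                if not targets:
                    continue
                d = min(distances.at[m, t] for t in targets)
                if math.isfinite(d):
                    per_input.append(d)
            if per_input:
                A.at[i, j] = float(np.mean(per_input))
                counts.at[i, j] = len(per_input)
    return NearestSizeMatrix(values=A, contributors=counts)


@dataclass
class NearestSizeMatrix:
    values: pd.DataFrame = field(repr=False)
    contributors: pd.DataFrame = field(repr=False)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.replace(UNREACHABLE, "NA")
        out.to_csv(path, sep="\t")


def efm_nearest_size_matrix(
    stoich: pd.DataFrame,
    carbon_counts: dict[str, int],
    *,
    cofactors: set[str] | None = None,
    allow_large: bool = False,
    max_internal_support: int | None = None,
) -> NearestSizeMatrix:
    """Nearest-size matrix built from minimal elementary-mode lengths.

    For every ordered pair of carbon metabolites an uptake and a secretion
    exchange are opened, the elementary modes are enumerated, and the number
    of internal reactions of the minimal mode that uses both exchanges is
    taken as the pair's pathway length; aggregation is min-then-average as in
    :func:`nearest_size_matrix`.  Mass balance makes these lengths at least
    as large as the plain graph distances.
    """
    from .efm import EfmSizeError, enumerate_efms

    cofactors = cofactors or set()
    mets = [m for m in stoich.index
            if m not in cofactors and carbon_counts.get(m, 0) > 0]
    rxns = [r for r in stoich.columns
            if not (r.startswith("EX_") or r.startswith("TR_"))]
    if not mets or not rxns:
        raise ValueError("nothing to analyse after filtering")
    S = stoich.loc[:, rxns].to_numpy(dtype=np.int64)
    all_mets = list(stoich.index)
    n_meta = len(all_mets)
    pair_len = pd.DataFrame(UNREACHABLE, index=mets, columns=mets)
    for a in mets:
        for b in mets:
            if a == b:
                continue
            up = np.zeros(n_meta, dtype=np.int64)
            up[all_mets.index(a)] = 1
            out = np.zeros(n_meta, dtype=np.int64)
            out[all_mets.index(b)] = -1
            cols = np.column_stack([S, up, out])
            ids = rxns + [f"EX__{a}", f"EX__{b}"]
            rev = [True] * len(rxns) + [False, False]
            modes = enumerate_efms(cols, rev, ids, allow_large=allow_large,
                                   max_support=None if max_internal_support is None
                                   else max_internal_support + 2)
            best = UNREACHABLE
            for mode in modes:
                fx = mode.flux_dict()
                if fx.get(f"EX__{a}", 0) > 0 and fx.get(f"EX__{b}", 0) != 0:
                    best = min(best, len(mode.internal_support()))
            pair_len.at[a, b] = best
    return nearest_size_matrix(pair_len, {m: carbon_counts[m] for m in mets})
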