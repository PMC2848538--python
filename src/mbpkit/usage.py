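"""Ecosystem-level statistics over a collection of minimal balanced pathways.

Treating each task's optimal pathway as one "organism" filling a metabolic
niche, these routines ask which reactions and metabolites are universal
tools: how many pathways use each reaction, how often each metabolite
participates in pathway reactions, how the ranked usage decays (a power law
with exponent near -1), whether metabolite usage oscillates with size (the
even/odd alternation of the ligation chemistry), and how fast the ecosystem
degrades when reactions are knocked out in usage order versus random order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chemistry import ChemistryNetwork
from .milp import MbpSolution, MbpTask, V_IN

__all__ = [
    "UsageTable",
    "PowerLawFit",
    "reaction_usage",
    "metabolite_usage",
    "fit_power_law",
    "periodicity",
    "knockout_curve",
]


@dataclass
class UsageTable:
    """Counts per entity with a deterministic descending-count ranking."""

    kind: str  # "reaction" | "metabolite"
    counts: dict

    def ranked(self) -> list[tuple[object, int]]:
        """Descending by count; ties broken by entity id for reproducibility."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], str(kv[0])))

    def nonzero_counts(self) -> np.ndarray:
        return np.array([c for _, c in self.ranked() if c > 0], dtype=float)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PowerLawFit:
    exponent: float
    r_squared: float
    n_ranks: int


def _species_of(reaction_id: str) -> tuple[int, ...]:
    left, rest = reaction_id[2:].split("+")
    right, product = rest.split("=")
    left, right, product = int(left), int(right), int(product)
    return (left, product) if left == right else (left, right, product)


def reaction_usage(mbps) -> UsageTable:
    """How many pathways use each reaction (each pathway counts a reaction
    once, regardless of flux)."""
    mbps = list(mbps)
    if not mbps:
        raise ValueError("empty pathway collection")
    counts: dict[str, int] = {}
    for sol in mbps:
        reactions = sol.active_reactions if isinstance(sol, MbpSolution) else sol
        for rid in reactions:
            counts[rid] = counts.get(rid, 0) + 1
    return UsageTable(kind="reaction", counts=counts)


def metabolite_usage(mbps) -> UsageTable:
    """Occurrences of each metabolite in pathway reactions: per pathway, a
    metabolite counts once for every active reaction it appears in (either
    side); a self-ligation substrate counts once for that reaction."""
    mbps = list(mbps)
    if not mbps:
        raise ValueError("empty pathway collection")
    counts: dict[int, int] = {}
    for sol in mbps:
        reactions = sol.active_reactions if isinstance(sol, MbpSolution) else sol
        for rid in reactions:
            for size in _species_of(rid):
                counts[size] = counts.get(size, 0) + 1
    return UsageTable(kind="metabolite", counts=counts)


def task_weighted_reaction_usage(sets_by_task) -> UsageTable:
    """Expected reaction usage when each task picks one of its equally
    optimal pathways uniformly at random.

    ``sets_by_task`` is an iterable of collections of reaction sets, one
    collection per task; each task contributes total weight 1, split evenly
    over its degenerate realizations.  This makes usage statistics robust to
    which degenerate solution an algorithm happens to return.
    """
    counts: dict[str, float] = {}
    any_task = False
    for sets in sets_by_task:
        sets = list(sets)
        if not sets:
            continue
        any_task = True
        w = 1.0 / len(sets)
        for s in sets:
            for rid in s:
                counts[rid] = counts.get(rid, 0.0) + w
    if not any_task:
        raise ValueError("empty pathway collection")
    return UsageTable(kind="reaction", counts=counts)


def fit_power_law(table: UsageTable) -> PowerLawFit:
    """OLS of log10(count) on log10(rank) over all nonzero ranks.

    The slope is the power-law exponent of the rank-usage curve (the whole
    curve is fit, not a tail window).
    """
    y = table.nonzero_counts()
    if len(y) < 5:
        raise ValueError(f"need >= 5 nonzero ranks, got {len(y)}")
    x = np.log10(np.arange(1, len(y) + 1))
    res = stats.linregress(x, np.log10(y))
    return PowerLawFit(exponent=float(res.slope),
                       r_squared=float(res.rvalue**2), n_ranks=len(y))


def periodicity(table: UsageTable, N: int) -> float:
    """Dominant period of metabolite usage versus size.

    The usage-vs-size signal (sizes 1..N, zero where unused) is linearly
    detrended and Fourier transformed; the period of the largest non-DC peak
    is returned in size units.
    """
    if N < 6:
        raise ValueError("need N >= 6 for a meaningful spectrum")
    sizes = np.arange(1, N + 1)
    signal = np.array([table.counts.get(int(s), 0) for s in sizes], dtype=float)
    trend = np.polynomial.Polynomial.fit(sizes, signal, deg=1)
    detrended = signal - trend(sizes)
    spectrum = np.abs(np.fft.rfft(detrended))
    k = int(np.argmax(spectrum[1:])) + 1  # skip DC
    return float(N / k)


def knockout_curve(
    net: ChemistryNetwork,
    order: list[str],
    *,
    input_size: int = 1,
    feasible=None,
) -> list[int]:
    """Producible-output census along a reaction-removal order.

    Removes internal reactions one at a time following ``order`` (a
    permutation of all internal reaction ids) and, after each removal, counts
    the output sizes j for which a steady-state full-yield flux from
    ``a_input_size`` still exists within the surviving reactions.  The input
    itself is always producible, so the count starts at N and ends at 1.
    """
    ids = [r.id for r in net.internal_reactions]
    if sorted(order) != sorted(ids):
        raise ValueError("order must be a permutation of the internal reactions")
    if feasible is None:
        feasible = _lp_feasible
    alive = set(ids)
    curve = []
    producible = set(range(1, net.N + 1))
    for rid in order:
        alive.discard(rid)
        # once lost, an output can never come back as reactions only disappear
        producible = {
            j for j in producible
            if j == input_size or feasible(net, alive, input_size, j)
        }
        curve.append(len(producible))
    return curve


def _lp_feasible(net: ChemistryNetwork, alive: set[str], i: int, j: int) -> bool:
    """LP feasibility of a full-yield flux supported within ``alive``."""
    from scipy.optimize import linprog

    cols = [net.internal_index(r) for r in sorted(alive)]
    if not cols:
        return i == j
    A = net.S_internal[:, cols].astype(float)
    rhs = np.zeros(net.N)
    rhs[i - 1] += V_IN
    rhs[j - 1] -= V_IN * i / j
    n = len(cols)
    res = linprog(
        c=np.zeros(n),
        A_eq=A, b_eq=-rhs,
        bounds=[(-10.0 * net.N * V_IN, 10.0 * net.N * V_IN)] * n,
        method="highs",
    )
    return bool(res.success)


def random_orders(net: ChemistryNetwork, n_orders: int, seed: int) -> list[list[str]]:
    """Seeded random removal orders (for knockout comparisons)."""
    rng = np.random.default_rng(seed)
    ids = [r.id for r in net.internal_reactions]
    out = []
    for _ in range(n_orders):
        perm = list(ids)
        rng.shuffle(perm)
        out.append(perm)
    return out
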