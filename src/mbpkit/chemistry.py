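"""Construction of the string-ligation artificial chemistry R_N.

The universe R_N contains species ``a_1 .. a_N`` (linear polymers of a single
monomer) and every reversible ligation/cleavage reaction ``a_i + a_j <-> a_k``
with ``i <= j`` and ``i + j = k <= N``.  Each species ``a_k`` with ``k >= 2``
can therefore be assembled in exactly ``floor(k/2)`` distinct ways, and the
internal reaction count of R_N is ``sum_{k=2..N} floor(k/2) ~ N^2/4``.

Every species also carries one exchange reaction with the environment; a task
opens exactly two of them (uptake of the input, secretion of the output) and
leaves the rest closed, which enforces the waste-free, maximal-yield condition
on any steady-state pathway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Species",
    "LigationReaction",
    "ExchangeReaction",
    "ExchangeRole",
    "ChemistryNetwork",
    "build_network",
    "reaction_count",
]


@dataclass(frozen=True)
class Species:
    """One polymer species ``a_size`` (size = number of monomer units)."""

    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"species size must be >= 1, got {self.size}")

    @property
    def id(self) -> str:
        return f"a{self.size}"


@dataclass(frozen=True, order=True)
class LigationReaction:
    """Reversible ligation ``a_left + a_right <-> a_product`` (left <= right)."""

    product: int
    left: int

    def __post_init__(self) -> None:
        if not (1 <= self.left <= self.right):
            raise ValueError(f"need 1 <= left <= right, got {self.left}, {self.right}")

    @property
    def right(self) -> int:
        return self.product - self.left

    @property
    def reversible(self) -> bool:
        return True

    @property
    def id(self) -> str:
        return f"L_{self.left}+{self.right}={self.product}"

    @property
    def is_self_ligation(self) -> bool:
        return self.left == self.right

    def species_sizes(self) -> tuple[int, ...]:
        """Distinct participating species sizes."""
        if self.is_self_ligation:
            return (self.left, self.product)
        return (self.left, self.right, self.product)


class ExchangeRole(str, Enum):
    UPTAKE = "uptake"
    SECRETION = "secretion"
    CLOSED = "closed"


@dataclass
class ExchangeReaction:
    """Exchange of one species with the environment (default closed)."""

    size: int
    role: ExchangeRole = ExchangeRole.CLOSED

    @property
    def id(self) -> str:
        return f"EX_{self.size}"


@dataclass
class ChemistryNetwork:
    """R_N: species, internal ligations, per-species exchanges and S matrix.

    Column order of ``S`` is deterministic: internal reactions sorted by
    (product, left), then exchanges by species size.  Internal ligation
    columns carry -1 on each substrate and +1 on the product (-2 on the
    substrate of a self-ligation); an exchange column for ``a_k`` carries +1
    on ``a_k`` (uptake direction positive).
    """

    N: int
    species: list[Species] = field(repr=False)
    internal_reactions: list[LigationReaction] = field(repr=False)
    exchanges: list[ExchangeReaction] = field(repr=False)
    S: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self._internal_index = {r.id: i for i, r in enumerate(self.internal_reactions)}

    # -- lookups ---------------------------------------------------------
    @property
    def n_internal(self) -> int:
        return len(self.internal_reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.internal_reactions] + [e.id for e in self.exchanges]

    def internal_index(self, reaction_id: str) -> int:
        return self._internal_index[reaction_id]

    def reaction_by_id(self, reaction_id: str) -> LigationReaction:
        return self.internal_reactions[self._internal_index[reaction_id]]

    @property
    def S_internal(self) -> np.ndarray:
        """Species x internal-reaction block of the stoichiometric matrix."""
        return self.S[:, : self.n_internal]

    def producers_of(self, size: int) -> list[LigationReaction]:
        return [r for r in self.internal_reactions if r.product == size]

    # -- export / import -------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write S as TSV: header = reaction ids, first column = species ids."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("species\t" + "\t".join(self.reaction_ids) + "\n")
            for row, sp in zip(self.S, self.species):
                fh.write(sp.id + "\t" + "\t".join(str(int(x)) for x in row) + "\n")

    def to_json(self, path: str | Path) -> None:
        """Write the reaction list as JSON."""
        payload = {
            "N": self.N,
            "internal": [
                {"left": r.left, "right": r.right, "product": r.product}
                for r in self.internal_reactions
            ],
            "exchanges": [{"size": e.size, "role": e.role.value} for e in self.exchanges],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChemistryNetwork":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        sizes = [int(r[0].lstrip("a")) for r in rows]
        net = build_network(max(sizes))
        if header != net.reaction_ids:
            raise ValueError("TSV columns do not match canonical R_N ordering")
        S = np.array([[int(x) for x in r[1:]] for r in rows], dtype=np.int64)
        if not np.array_equal(S, net.S):
            raise ValueError("TSV stoichiometry does not match R_N")
        return net

    @classmethod
    def from_json(cls, path: str | Path) -> "ChemistryNetwork":
        payload = json.loads(Path(path).read_text())
        net = build_network(int(payload["N"]))
        declared = {(d["left"], d["right"], d["product"]) for d in payload["internal"]}
        ours = {(r.left, r.right, r.product) for r in net.internal_reactions}
        if declared != ours:
            raise ValueError("JSON reaction list does not match R_N")
        return net


def reaction_count(N: int) -> int:
    """Number of internal ligation reactions in R_N: sum_{k=2..N} floor(k/2).

    Grows as ~N^2/4; e.g. R_19 has 90 internal reactions.
    """
    if N < 2:
        raise ValueError(f"R_N needs N >= 2, got {N}")
    return sum(k // 2 for k in range(2, N + 1))


def build_network(N: int) -> ChemistryNetwork:
    """Build R_N with its full stoichiometric matrix.

    Raises ``ValueError`` for N < 2 (no ligation is possible among fewer than
    two monomer units).
    """
    if N < 2:
        raise ValueError(f"R_N needs N >= 2, got {N}")
    species = [Species(k) for k in range(1, N + 1)]
    internal = [
        LigationReaction(product=k, left=i)
        for k in range(2, N + 1)
        for i in range(1, k // 2 + 1)
    ]
    internal.sort()  # (product, left)
    exchanges = [ExchangeReaction(size=k) for k in range(1, N + 1)]

    S = np.zeros((N, len(internal) + N), dtype=np.int64)
    for col, r in enumerate(internal):
        if r.is_self_ligation:
            S[r.left - 1, col] = -2
        else:
            S[r.left - 1, col] = -1
            S[r.right - 1, col] = -1
        S[r.product - 1, col] += 1
    for k in range(1, N + 1):
        S[k - 1, len(internal) + k - 1] = 1  # uptake-positive exchange
    net = ChemistryNetwork(N=N, species=species, internal_reactions=internal,
                           exchanges=exchanges, S=S)
    _check_invariants(net)
    return net


def _check_invariants(net: ChemistryNetwork) -> None:
    if net.n_internal != reaction_count(net.N):
        raise AssertionError("internal reaction count mismatch")
    sizes = np.arange(1, net.N + 1)
    mass = sizes @ net.S_internal
    if np.any(mass != 0):
        raise AssertionError("monomer mass not conserved by an internal column")


def reaction_id(left: int, right: int) -> str:
    """Canonical id of the ligation a_left + a_right <-> a_{left+right}."""
    lo, hi = sorted((left, right))
    return f"L_{lo}+{hi}={lo + hi}"
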