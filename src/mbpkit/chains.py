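"""Addition and addition-subtraction chain arithmetic.

An addition chain for a target ``j`` is an integer sequence starting at 1 in
which every later element is the sum of two (not necessarily distinct)
earlier elements, ending at ``j``; an addition-subtraction chain also allows
differences.  The shortest chain length is the arithmetic skeleton of the
minimal-pathway problem in the string-ligation chemistry: producing ``a_j``
from ``a_1`` by ligations mirrors building ``j`` from 1 by additions, and the
number of ligation reactions equals the operation count of the chain.

Two length conventions coexist in the chain literature and both are exposed:
``n_elements`` counts the sequence entries including the initial 1 (the
doubling chain 1,2,4,...,2^k has k+1 elements), while ``n_operations`` =
``n_elements - 1`` counts the construction steps, i.e. reactions.

The closed-form pieces: the shortest chain for ``j`` has at least
``ceil(log2 j) + 1`` elements and at most ``floor(log2 j) + nu(j)`` elements,
where ``nu(j)`` is the number of 1-bits of ``j`` (binary method).  The
pathway-length predictor reduces a task (i, j) by the gcd and scores it
``log2(i') + log2(j')`` reactions; the induced reaction-usage prediction is a
rank-frequency law ``e_rank ~ 1/rank``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChainRecord",
    "LengthPrediction",
    "shortest_addition_chain",
    "chain_bounds",
    "predict_mbp_length",
    "predicted_rank_frequency",
]

#: practical guard for the exhaustive search
MAX_TARGET = 10_000


@dataclass(frozen=True)
class ChainRecord:
    target: int
    sequence: tuple[int, ...]
    allows_subtraction: bool

    @property
    def n_elements(self) -> int:
        return len(self.sequence)

    @property
    def n_operations(self) -> int:
        return len(self.sequence) - 1

    def is_valid(self) -> bool:
        seq = self.sequence
        if not seq or seq[0] != 1 or seq[-1] != self.target:
            return False
        for idx in range(1, len(seq)):
            prev = seq[:idx]
            ok = any(
                seq[idx] == a + b or (self.allows_subtraction and seq[idx] == abs(a - b))
                for ai, a in enumerate(prev)
                for b in prev[ai:]
            )
            if not ok:
                return False
        return True


def shortest_addition_chain(j: int, allow_subtraction: bool = False) -> ChainRecord:
    """Exhaustive shortest chain for ``j`` by iterative-deepening DFS.

    Pruning: with ``d`` steps remaining the largest reachable value is
    ``max(chain) * 2**d``, so branches that cannot reach ``j`` are cut; in
    subtraction mode intermediate values are capped at ``2 * j``.
    """
    if not 1 <= j <= MAX_TARGET:
        raise ValueError(f"target must be in [1, {MAX_TARGET}], got {j}")
    if j == 1:
        return ChainRecord(1, (1,), allow_subtraction)

    cap = 2 * j if allow_subtraction else j

    def dfs(chain: list[int], depth_left: int) -> tuple[int, ...] | None:
        top = chain[-1]
        if top == j:
            return tuple(chain)
        if depth_left == 0:
            return None
        if max(chain) << depth_left < j:
            return None
        candidates: set[int] = set()
        for ai, a in enumerate(chain):
            for b in chain[ai:]:
                s = a + b
                if chain[-1] < s <= cap or (allow_subtraction and 1 <= s <= cap):
                    candidates.add(s)
                if allow_subtraction:
                    d = abs(a - b)
                    if 1 <= d <= cap:
                        candidates.add(d)
        # try large candidates first: reaches the target sooner
        for nxt in sorted(candidates, reverse=True):
            if nxt in chain:
                continue
            chain.append(nxt)
            found = dfs(chain, depth_left - 1)
            chain.pop()
            if found is not None:
                return found
        return None

    depth = math.ceil(math.log2(j))  # lower bound on operations
    while True:
        found = dfs([1], depth)
        if found is not None:
            return ChainRecord(j, found, allow_subtraction)
        depth += 1


def chain_bounds(j: int) -> dict[str, int]:
    """Element-count bounds for the shortest pure addition chain.

    lower = ceil(log2 j) + 1 (doubling is the fastest growth); upper =
    floor(log2 j) + nu(j) (square-and-multiply on the binary expansion).
    """
    if j < 1:
        raise ValueError("target must be >= 1")
    if j == 1:
        return {"lower_elements": 1, "upper_elements": 1}
    nu = bin(j).count("1")
    return {
        "lower_elements": math.ceil(math.log2(j)) + 1,
        "upper_elements": math.floor(math.log2(j)) + nu,
    }


@dataclass(frozen=True)
class LengthPrediction:
    i: int
    j: int
    g: int
    predicted: float


def predict_mbp_length(i: int, j: int) -> LengthPrediction:
    """Analytic reaction-count estimate for the task a_i => a_j.

    After dividing out g = gcd(i, j) (which never changes the minimal
    length), the estimate is log2(i/g) + log2(j/g): roughly log2(j') steps to
    build the output from monomers plus log2(i') to break the input down.
    Exact 0 for i = j.
    """
    if i < 1 or j < 1:
        raise ValueError("species sizes must be >= 1")
    g = math.gcd(i, j)
    ip, jp = i // g, j // g
    return LengthPrediction(i=i, j=j, g=g, predicted=math.log2(ip) + math.log2(jp))


def predicted_rank_frequency(n_ranks: int) -> np.ndarray:
    """Predicted reaction usage frequency by rank: e_r proportional to 1/r,
    normalized to sum to 1 (a log-log slope of exactly -1)."""
    if n_ranks < 1:
        raise ValueError("need at least one rank")
    e = 1.0 / np.arange(1, n_ranks + 1)
    return e / e.sum()
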