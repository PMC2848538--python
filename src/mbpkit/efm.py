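"""Elementary flux mode enumeration and degenerate-pathway extraction.

An elementary flux mode (EFM) of a stoichiometric system is a flux vector
that (i) satisfies steady state S v = 0, (ii) respects irreversibility, and
(iii) is non-decomposable: no other steady-state flux has a support that is a
proper subset.  For a task a_i => a_j in R_N we open exactly two irreversible
exchanges (uptake of a_i, secretion of a_j); every mode that touches the
exchanges then automatically runs at full yield i*v_in = j*v_out, because the
ligation chemistry conserves monomers and no other exchange exists.  The
modes of minimal internal support are exactly the minimal balanced pathways,
and their multiplicity per task is the pathway degeneracy.

The enumerator is the classical tableau (double description) algorithm run in
exact integer arithmetic: reversible reactions are split into forward and
backward columns, metabolite constraints are eliminated one at a time by
combining rows of opposite residual sign, and candidate rows are kept only if
no other row's support is contained in theirs (the rank/subset elementarity
test).  Supports are tracked as bitmasks so the subset test is a couple of
integer operations.  Futile forward+backward two-cycles are discarded and the
split columns re-fused to signed fluxes for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .chemistry import ChemistryNetwork
from .milp import MbpSolution, MbpTask, V_IN

__all__ = [
    "ElementaryMode",
    "DegenerateMbpSet",
    "EfmSizeError",
    "enumerate_efms",
    "task_efms",
    "mbps_from_efms",
    "detect_autocatalytic",
    "degenerate_catalogue",
]

#: refuse enumeration beyond this many irreversible (split) columns
SIZE_GUARD = 60


class EfmSizeError(RuntimeError):
    """Network too large for exhaustive EFM enumeration without override."""


@dataclass(frozen=True)
class ElementaryMode:
    """One elementary mode: reaction id -> signed integer flux (coprime)."""

    fluxes: tuple[tuple[str, int], ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(rid for rid, _ in self.fluxes)

    def flux_dict(self) -> dict[str, int]:
        return dict(self.fluxes)

    def internal_support(self) -> frozenset[str]:
        return frozenset(r for r, _ in self.fluxes if not r.startswith("EX_"))


@dataclass
class DegenerateMbpSet:
    """All distinct minimal-length realizations of one task."""

    task: MbpTask
    solutions: list[MbpSolution] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.solutions[0].length if self.solutions else 0

    def supports(self) -> set[frozenset[str]]:
        return {s.active_reactions for s in self.solutions}


class _Row:
    """One tableau row: integer flux coefficients over the split (all
    irreversible) columns, support bitmask, and residual metabolite
    balances."""

    __slots__ = ("flux", "mask", "res")

    def __init__(self, flux, mask, res):
        self.flux = flux
        self.mask = mask
        self.res = res


def _combine(a: int, ra: _Row, b: int, rb: _Row, n_cols: int) -> _Row:
    flux = [a * x + b * y for x, y in zip(ra.flux, rb.flux)]
    res = [a * x + b * y for x, y in zip(ra.res, rb.res)]
    g = math.gcd(*flux, *res)
    if g > 1:
        flux = [x // g for x in flux]
        res = [x // g for x in res]
    mask = 0
    for idx in range(n_cols):
        if flux[idx]:
            mask |= 1 << idx
    return _Row(flux, mask, res)


def _core_enumerate(columns: list[np.ndarray], n_meta: int,
                    max_support: int | None = None) -> list[_Row]:
    """Pointed-cone tableau elimination over irreversible columns.

    Metabolites are eliminated one at a time; rows of opposite residual sign
    are combined with positive coefficients, and a combination survives only
    if no other current row's support fits strictly inside it (the canonical
    elementarity test, valid because every column is irreversible).  Two
    exact pruning rules keep the row count down: after k eliminations a
    surviving mode's support has at most k+1 columns (its support submatrix
    always has nullity one), and an optional caller bound restricts the run
    to modes no larger than the bound -- any non-elementary candidate within
    the bound is still killed by a strictly smaller surviving row.
    """
    n = len(columns)
    n_words = (n + 63) // 64
    rows = [
        _Row([1 if k == r else 0 for k in range(n)], 1 << r,
             [int(x) for x in col])
        for r, col in enumerate(columns)
    ]

    def mask_array(items: list[int]) -> np.ndarray:
        arr = np.zeros((len(items), n_words), dtype=np.uint64)
        for k, mask in enumerate(items):
            for w in range(n_words):
                arr[k, w] = (mask >> (64 * w)) & 0xFFFFFFFFFFFFFFFF
        return arr

    remaining = list(range(n_meta))
    processed = 0
    while remaining:
        def cost(m: int) -> int:
            p = sum(1 for row in rows if row.res[m] > 0)
            q = sum(1 for row in rows if row.res[m] < 0)
            return p * q

        remaining.sort(key=cost)
        m = remaining.pop(0)
        processed += 1
        cap = processed + 1
        if max_support is not None:
            cap = min(cap, max_support)
        zero = [row for row in rows if row.res[m] == 0]
        pos = [row for row in rows if row.res[m] > 0]
        neg = [row for row in rows if row.res[m] < 0]
        if not pos or not neg:
            rows = zero
            continue
        all_masks = mask_array([row.mask for row in rows])
        new_rows = list(zero)
        for ri in pos:
            a0 = ri.res[m]
            for rj in neg:
                union = ri.mask | rj.mask
                if union.bit_count() > cap:
                    continue
                cand = mask_array([union])[0]
                inside = np.all((all_masks & ~cand) == 0, axis=1)
                if int(np.count_nonzero(inside)) > 2:  # a third row fits inside
                    continue
                new_rows.append(_combine(-rj.res[m], ri, a0, rj, n))
        rows = _drop_non_minimal(new_rows)
    return rows


def _drop_non_minimal(rows: list["_Row"]) -> list["_Row"]:
    """Drop rows whose support strictly contains another row's support, and
    collapse duplicates."""
    if not rows:
        return rows
    mask_ints = [r.mask for r in rows]
    n_words = max(1, (max(mask_ints).bit_length() + 63) // 64)
    masks = np.zeros((len(rows), n_words), dtype=np.uint64)
    for k, mask in enumerate(mask_ints):
        for w in range(n_words):
            masks[k, w] = (mask >> (64 * w)) & 0xFFFFFFFFFFFFFFFF
    keep = []
    seen: set[tuple] = set()
    for idx, row in enumerate(rows):
        mi = masks[idx]
        inside = np.all((masks & ~mi) == 0, axis=1)
        equal = np.all(masks == mi, axis=1)
        if int(np.count_nonzero(inside)) > int(np.count_nonzero(equal)):
            continue  # a strictly smaller support fits inside
        sig = (row.mask, tuple(row.flux), tuple(row.res))
        if sig in seen:
            continue
        seen.add(sig)
        keep.append(row)
    return keep


def enumerate_efms(
    S: np.ndarray,
    reversible: list[bool],
    reaction_ids: list[str],
    *,
    allow_large: bool = False,
    max_support: int | None = None,
) -> list[ElementaryMode]:
    """All elementary modes of the system ``S v = 0`` (columns = reactions).

    Reversible columns are split for the computation and re-fused afterwards;
    a mode supported on both directions of one reaction (futile two-cycle) is
    discarded.  A fully reversible mode and its reversal are reported once,
    normalized so that the first nonzero flux is positive.
    """
    n_meta, n_rxn = S.shape
    split_cols: list[np.ndarray] = []
    origin: list[tuple[int, int]] = []  # (reaction index, direction sign)
    for r in range(n_rxn):
        split_cols.append(S[:, r])
        origin.append((r, +1))
        if reversible[r]:
            split_cols.append(-S[:, r])
            origin.append((r, -1))
    if len(split_cols) > SIZE_GUARD and not allow_large:
        raise EfmSizeError(
            f"{len(split_cols)} irreversible columns exceeds the enumeration "
            f"guard ({SIZE_GUARD}); pass allow_large=True to override "
            "(bounded runs stay tractable well beyond the guard)")

    seen: set[tuple[tuple[str, int], ...]] = set()
    modes: list[ElementaryMode] = []
    for row in _core_enumerate(split_cols, n_meta, max_support=max_support):
        net_flux: dict[int, int] = {}
        futile = False
        for idx, v in enumerate(row.flux):
            if not v:
                continue
            r, sign = origin[idx]
            if r in net_flux:
                futile = True  # forward+backward of one reaction: 2-cycle
                break
            net_flux[r] = sign * v
        if futile or not net_flux:
            continue
        items = sorted((reaction_ids[r], v) for r, v in net_flux.items())
        if all(reversible[r] for r in net_flux):
            if items[0][1] < 0:  # orientation-free mode: canonical sign
                items = [(rid, -v) for rid, v in items]
        key = tuple(items)
        if key not in seen:
            seen.add(key)
            modes.append(ElementaryMode(fluxes=key))
    return modes


def task_efms(
    net: ChemistryNetwork,
    task: MbpTask,
    *,
    allow_large: bool = False,
    max_internal_support: int | None = None,
) -> list[ElementaryMode]:
    """EFMs of R_N with only the task's two exchanges open.

    The uptake exchange (input species) is irreversible into the system, the
    secretion exchange (output species) irreversible out; all internal
    ligations are reversible.  With ``max_internal_support`` the enumeration
    is restricted (exactly) to modes using at most that many internal
    reactions -- enough for pathway extraction when an upper bound on the
    minimal length is already known.
    """
    task.validate(net)
    i, j = task.input_size, task.output_size
    cols = [net.S_internal[:, c] for c in range(net.n_internal)]
    ids = [r.id for r in net.internal_reactions]
    rev = [True] * net.n_internal
    up = np.zeros(net.N, dtype=np.int64)
    up[i - 1] = 1
    cols.append(up)
    ids.append(f"EX_{i}")
    rev.append(False)
    if j != i:
        out = np.zeros(net.N, dtype=np.int64)
        out[j - 1] = -1  # secretion column; its flux is a nonnegative rate
        cols.append(out)
        ids.append(f"EX_{j}")
        rev.append(False)
    S = np.column_stack(cols)
    cap = None
    if max_internal_support is not None:
        cap = max_internal_support + (1 if j == i else 2)  # exchange columns
    modes = enumerate_efms(S, rev, ids, allow_large=allow_large, max_support=cap)
    # report exchanges uptake-positive / secretion-negative
    ex_out = f"EX_{j}"
    flipped = []
    for m in modes:
        items = tuple(sorted(
            (rid, -v if rid == ex_out else v) for rid, v in m.fluxes))
        flipped.append(ElementaryMode(fluxes=items))
    return flipped


def mbps_from_efms(modes: list[ElementaryMode], task: MbpTask) -> DegenerateMbpSet:
    """Minimal-support full-yield modes of a task, as a degenerate MBP set.

    Keeps modes in which both task exchanges are active (monomer conservation
    then forces full yield), filters to minimal internal support size, and
    reports each distinct support once with a witness flux normalized to
    v_in = 10.
    """
    ex_in, ex_out = f"EX_{task.input_size}", f"EX_{task.output_size}"
    candidates = []
    for mode in modes:
        fx = mode.flux_dict()
        if fx.get(ex_in, 0) > 0 and fx.get(ex_out, 0) != 0:
            candidates.append(mode)
    if task.input_size == task.output_size:
        # the identity task: the pure uptake->secretion mode has empty support
        sol = MbpSolution(task=task, active_reactions=frozenset(),
                          flux={ex_in: V_IN, ex_out: -V_IN})
        return DegenerateMbpSet(task=task, solutions=[sol])
    if not candidates:
        raise RuntimeError(
            f"no full-yield mode for a{task.input_size} => a{task.output_size}; "
            "were the EFMs enumerated with this task's exchanges open?")
    best = min(len(m.internal_support()) for m in candidates)
    seen: set[frozenset[str]] = set()
    solutions = []
    for mode in candidates:
        supp = mode.internal_support()
        if len(supp) != best or supp in seen:
            continue
        seen.add(supp)
        fx = mode.flux_dict()
        scale = Fraction(10, fx[ex_in])
        flux = {rid: float(Fraction(v) * scale) for rid, v in fx.items()}
        solutions.append(MbpSolution(task=task, active_reactions=supp, flux=flux))
    solutions.sort(key=lambda s: sorted(s.active_reactions))
    return DegenerateMbpSet(task=task, solutions=solutions)


def detect_autocatalytic(solution: MbpSolution, task: MbpTask | None = None) -> bool:
    """True iff the pathway cannot bootstrap from its input species alone.

    Constructive reachability: start with the input species available and
    repeatedly fire any active reaction, in the direction it is used, whose
    consumed species are all available; its products become available.  If
    some active reaction can never fire the pathway needs an intermediate to
    be seeded before it can run (it regenerates that seed in surplus at
    steady state) -- an autocatalytic cycle.
    """
    task = task or solution.task
    pending = []
    for rid in solution.active_reactions:
        v = solution.flux.get(rid, 0.0)
        left, rest = rid[2:].split("+")
        right, product = rest.split("=")
        left, right, product = int(left), int(right), int(product)
        if v >= 0:  # ligation direction
            pending.append((frozenset((left, right)), frozenset((product,))))
        else:  # cleavage direction
            pending.append((frozenset((product,)), frozenset((left, right))))
    available = {task.input_size}
    progress = True
    while pending and progress:
        progress = False
        for item in list(pending):
            needs, makes = item
            if needs <= available:
                available |= makes
                pending.remove(item)
                progress = True
    return bool(pending)


def degenerate_catalogue(
    net: ChemistryNetwork,
    *,
    allow_large: bool = False,
    include_identity: bool = False,
    length_bounds: dict[tuple[int, int], int] | None = None,
) -> dict[tuple[int, int], DegenerateMbpSet]:
    """Degenerate MBP sets for every ordered task (i, j), i != j, of R_N.

    Because every ligation is reversible, the modes of task (j, i) are the
    reversals of those of (i, j); each unordered pair is enumerated once and
    mirrored.  Per-task support bounds keep the enumeration tractable without
    losing any minimal mode; by default they come from the iterative additive
    assembly, which always upper-bounds the true minimum.
    """
    if length_bounds is None:
        from .iterative import build_all_mbps_iterative

        table = build_all_mbps_iterative(net.N, max_sets_per_task=1)
        length_bounds = {
            (i, j): table.length(i, j)
            for i in range(1, net.N + 1)
            for j in range(1, net.N + 1)
            if i != j
        }
    out: dict[tuple[int, int], DegenerateMbpSet] = {}
    for i in range(1, net.N + 1):
        for j in range(i + 1, net.N + 1):
            task = MbpTask(i, j)
            dset = mbps_from_efms(
                task_efms(net, task, allow_large=allow_large,
                          max_internal_support=length_bounds.get((i, j))),
                task)
            out[(i, j)] = dset
            mirror = DegenerateMbpSet(
                task=MbpTask(j, i),
                solutions=[
                    MbpSolution(
                        task=MbpTask(j, i),
                        active_reactions=s.active_reactions,
                        flux={rid: -v for rid, v in s.flux.items()},
                    )
                    for s in dset.solutions
                ],
            )
            out[(j, i)] = mirror
    if include_identity:
        for i in range(1, net.N + 1):
            t = MbpTask(i, i)
            out[(i, i)] = DegenerateMbpSet(task=t, solutions=[MbpSolution(
                task=t, active_reactions=frozenset(), flux={f"EX_{i}": 0.0})])
    return out


def minimal_length_bounded(net: ChemistryNetwork, task: MbpTask,
                           upper_bound: int) -> int:
    """Exact minimal balanced-pathway length via bounded mode enumeration.

    ``upper_bound`` must be achievable (e.g. the iterative assembly's
    length).  One support-bounded enumeration with cap ``upper_bound - 1``
    either finds the true smaller minimum (the bounded run is complete for
    all modes within its cap) or proves that nothing shorter exists.
    """
    if task.input_size == task.output_size:
        return 0
    if upper_bound <= 1:
        return upper_bound
    modes = task_efms(net, task, allow_large=True,
                      max_internal_support=upper_bound - 1)
    ex_in, ex_out = f"EX_{task.input_size}", f"EX_{task.output_size}"
    best = None
    for mode in modes:
        fx = mode.flux_dict()
        if fx.get(ex_in, 0) > 0 and fx.get(ex_out, 0) != 0:
            k = len(mode.internal_support())
            best = k if best is None else min(best, k)
    return upper_bound if best is None else best


def exact_length_table(net: ChemistryNetwork, *, upper_bounds=None) -> "np.ndarray":
    """Exact pathway-length matrix for all ordered tasks of R_N.

    Equivalent to the MILP optimum on every task (both are exact), but
    computed by bounded mode enumeration seeded with the iterative assembly's
    upper bounds, which scales to networks where branch-and-bound stalls.
    Lengths are symmetric in (i, j) because every ligation is reversible.
    """
    if upper_bounds is None:
        from .iterative import build_all_mbps_iterative

        table = build_all_mbps_iterative(net.N, max_sets_per_task=1)
        upper_bounds = {(i, j): table.length(i, j)
                        for i in range(1, net.N + 1)
                        for j in range(1, net.N + 1) if i != j}
    L = np.full((net.N + 1, net.N + 1), -1, dtype=int)
    np.fill_diagonal(L, 0)
    L[0, :] = L[:, 0] = -1
    for i in range(1, net.N + 1):
        for j in range(i + 1, net.N + 1):
            val = minimal_length_bounded(net, MbpTask(i, j),
                                         upper_bounds[(i, j)])
            L[i, j] = L[j, i] = val
    return L
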