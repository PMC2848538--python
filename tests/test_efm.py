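import itertools

import numpy as np
import pytest

from mbpkit.chemistry import build_network
from mbpkit.efm import (
    EfmSizeError,
    detect_autocatalytic,
    enumerate_efms,
    mbps_from_efms,
    minimal_length_bounded,
    task_efms,
)
from mbpkit.milp import MbpSolution, MbpTask, find_mbp, verify_balanced


def brute_force_minimal_supports(net, i, j, max_size):
    """Oracle: enumerate internal subsets by size; keep full-yield supports
    whose kernel is one-dimensional and fully active (exact up to max_size)."""
    Sint = net.S_internal.astype(float)
    u = np.zeros(net.N)
    u[i - 1] = 1
    w = np.zeros(net.N)
    w[j - 1] = -1
    hits = []
    for size in range(1, max_size + 1):
        for comb in itertools.combinations(range(net.n_internal), size):
            A = np.column_stack([Sint[:, list(comb)], u, w])
            sv = np.linalg.svd(A, compute_uv=True)
            s, Vt = sv[1], sv[2]
            rank = int((s > 1e-9).sum())
            if A.shape[1] - rank != 1:
                continue
            v = Vt[-1]
            if abs(v[-2]) < 1e-9 or abs(v[-1]) < 1e-9:
                continue
            if v[-2] < 0:
                v = -v
            if v[-1] < 0 or np.any(np.abs(v[:-2]) < 1e-9):
                continue
            hits.append(frozenset(net.internal_reactions[c].id for c in comb))
        if hits:
            return size, set(hits)
    return None, set()


def test_single_reaction_network_has_one_mode():
    net = build_network(2)
    modes = task_efms(net, MbpTask(1, 2))
    assert len(modes) == 1
    assert dict(modes[0].fluxes) == {"EX_1": 2, "EX_2": -1, "L_1+1=2": 1}


def test_r4_minimal_support_is_two_doublings():
    net = build_network(4)
    task = MbpTask(1, 4)
    dset = mbps_from_efms(task_efms(net, task), task)
    assert dset.length == 2
    assert dset.supports() == {frozenset({"L_1+1=2", "L_2+2=4"})}


def test_identity_task_mode_is_exchange_only():
    net = build_network(4)
    task = MbpTask(3, 3)
    dset = mbps_from_efms([], task)
    assert dset.length == 0 and len(dset.solutions) == 1


def test_modes_form_an_antichain():
    """No enumerated mode's support strictly contains another's."""
    net = build_network(6)
    modes = task_efms(net, MbpTask(1, 6))
    supports = [m.support for m in modes]
    for a in supports:
        for b in supports:
            assert not (a < b)


def test_mode_set_invariant_under_reaction_permutation():
    net = build_network(6)
    task = MbpTask(2, 5)
    base = task_efms(net, task)
    ids = [r.id for r in net.internal_reactions]
    cols = [net.S_internal[:, c] for c in range(net.n_internal)]
    order = list(range(net.n_internal))[::-1]
    up = np.zeros(net.N, dtype=np.int64)
    up[task.input_size - 1] = 1
    out = np.zeros(net.N, dtype=np.int64)
    out[task.output_size - 1] = -1
    S = np.column_stack([np.column_stack([cols[c] for c in order]), up, out])
    shuffled_ids = [ids[c] for c in order] + [f"EX_{task.input_size}",
                                             f"EX_{task.output_size}"]
    rev = [True] * net.n_internal + [False, False]
    shuffled = enumerate_efms(S, rev, shuffled_ids)
    assert {m.support for m in shuffled} == {m.support for m in base}
    assert len(shuffled) == len(base)


def test_bounded_run_agrees_with_brute_force_oracle():
    """Minimal full-yield supports of an R_8 task match subset enumeration."""
    net = build_network(8)
    task = MbpTask(7, 8)
    size, oracle = brute_force_minimal_supports(net, 7, 8, max_size=4)
    dset = mbps_from_efms(task_efms(net, task, max_internal_support=size), task)
    assert dset.length == size
    assert dset.supports() == oracle


def test_minimal_length_bounded_matches_milp():
    net = build_network(8)
    for (i, j) in [(1, 8), (7, 8), (5, 7), (3, 8)]:
        milp_len = find_mbp(net, MbpTask(i, j)).length
        assert minimal_length_bounded(net, MbpTask(i, j), milp_len + 2) == milp_len


def test_every_minimal_mode_verifies_balanced(net10):
    task = MbpTask(9, 10)
    dset = mbps_from_efms(task_efms(net10, task, max_internal_support=5), task)
    assert len(dset.solutions) >= 4  # several equally optimal realizations
    for sol in dset.solutions:
        assert verify_balanced(net10, sol.active_reactions, task)


def test_autocatalytic_detection():
    # a plain assembly chain bootstraps from its input
    chain = MbpSolution(task=MbpTask(1, 4),
                        active_reactions=frozenset({"L_1+1=2", "L_2+2=4"}),
                        flux={"L_1+1=2": 2.0, "L_2+2=4": 1.0})
    assert not detect_autocatalytic(chain)
    # the a7 => a8 cycle seeds a1 from cleaved product: cannot self-start
    net10 = build_network(10)
    task = MbpTask(7, 8)
    dset = mbps_from_efms(task_efms(net10, task, max_internal_support=4), task)
    assert any(detect_autocatalytic(s) for s in dset.solutions)


def test_size_guard_refuses_unbounded_large_networks():
    net = build_network(12)
    with pytest.raises(EfmSizeError):
        task_efms(net, MbpTask(1, 12))
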