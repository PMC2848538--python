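import numpy as np
import pytest

from mbpkit.chemistry import build_network
from mbpkit.usage import (
    UsageTable,
    fit_power_law,
    knockout_curve,
    metabolite_usage,
    periodicity,
    random_orders,
    reaction_usage,
)


def test_single_pathway_counts():
    t = reaction_usage([frozenset({"L_1+1=2"})])
    assert t.counts == {"L_1+1=2": 1}
    m = metabolite_usage([frozenset({"L_1+1=2"})])
    assert m.counts == {1: 1, 2: 1}


def test_empty_collection_rejected():
    with pytest.raises(ValueError):
        reaction_usage([])
    with pytest.raises(ValueError):
        metabolite_usage([])


def test_metabolite_participation_in_a_nine_to_ten_pathway():
    """In the a9 => a10 pathway the input a9 sits in one reaction while the
    product a10 sits in two (made by ligation, recycled by cleavage)."""
    mbp = frozenset({"L_1+9=10", "L_5+5=10", "L_1+4=5", "L_2+2=4", "L_1+1=2"})
    m = metabolite_usage([mbp])
    assert m.counts[9] == 1
    assert m.counts[10] == 2


def test_usage_total_equals_summed_lengths():
    sets = [frozenset({"L_1+1=2"}), frozenset({"L_1+1=2", "L_2+2=4"}),
            frozenset({"L_1+2=3", "L_1+1=2", "L_1+3=4"})]
    t = reaction_usage(sets)
    assert t.total() == sum(len(s) for s in sets)


def test_power_law_trivial_cases():
    harmonic = UsageTable("reaction", {f"r{k}": 1000 / k for k in range(1, 30)})
    fit = fit_power_law(harmonic)
    assert fit.exponent == pytest.approx(-1.0, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
    flat = UsageTable("reaction", {f"r{k}": 7 for k in range(10)})
    assert fit_power_law(flat).exponent == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        fit_power_law(UsageTable("reaction", {"a": 1, "b": 2}))


def test_power_law_scale_invariance():
    counts = {f"r{k}": 900.0 / (k + 1) ** 1.3 for k in range(40)}
    base = fit_power_law(UsageTable("reaction", counts)).exponent
    scaled = fit_power_law(UsageTable(
        "reaction", {k: 17 * v for k, v in counts.items()})).exponent
    assert scaled == pytest.approx(base, abs=1e-9)


def test_periodicity_detects_planted_periods():
    alternating = UsageTable("metabolite",
                             {s: (10 if s % 2 == 0 else 1) for s in range(1, 21)})
    assert periodicity(alternating, 20) == pytest.approx(2.0)
    comb = UsageTable("metabolite",
                      {s: (50 if s % 5 == 0 else 2) for s in range(1, 21)})
    assert periodicity(comb, 20) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        periodicity(alternating, 5)


def test_knockout_curve_endpoints():
    net = build_network(6)
    order = [r.id for r in net.internal_reactions]
    curve = knockout_curve(net, order, input_size=1)
    assert len(curve) == net.n_internal
    assert curve[-1] == 1  # only the input itself survives a bare network
    assert all(a >= b for a, b in zip(curve, curve[1:]))  # monotone decay
    with pytest.raises(ValueError):
        knockout_curve(net, order[:-1])


def test_usage_ranked_removal_degrades_faster_than_random(milp_table10, net10):
    """Removing universal tools first collapses producibility quickest."""
    _, sols = milp_table10
    table = reaction_usage([s for (i, j), s in sols.items() if i != j])
    counts = table.counts
    ids = [r.id for r in net10.internal_reactions]
    by_usage = sorted(ids, key=lambda r: (-counts.get(r, 0), r))
    usage_curve = np.array(knockout_curve(net10, by_usage))
    rng_curves = []
    for order in random_orders(net10, 5, seed=7):
        rng_curves.append(knockout_curve(net10, order))
    mean_random = np.mean(rng_curves, axis=0)
    half = len(ids) // 2
    assert usage_curve[:half].mean() <= mean_random[:half].mean()
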