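"""Ecosystem statistics: which reactions are universal tools?

Computes one optimal pathway per ordered task of R_10, counts how many
pathways use each reaction, fits the rank-usage power law (exponent near -1)
and shows the even/odd alternation of metabolite usage.
"""

from mbpkit import (
    build_network,
    fit_power_law,
    metabolite_usage,
    periodicity,
    reaction_usage,
)
from mbpkit.milp import mbp_length_table

net = build_network(10)
_, sols = mbp_length_table(net, collect_solutions=True)
pathways = [s.active_reactions for (i, j), s in sols.items() if i != j]

r = reaction_usage(pathways)
print("top reactions by number of pathways using them:")
for rank, (rid, count) in enumerate(r.ranked()[:5], 1):
    print(f"  {rank}. {rid:12s} {count} pathways")

fit = fit_power_law(r)
print(f"rank-usage power law: exponent {fit.exponent:.2f} "
      f"(R^2 = {fit.r_squared:.2f})")

m = metabolite_usage(pathways)
print("metabolite usage by size:", [m.counts.get(s, 0) for s in range(1, 11)])
print(f"dominant usage period: {periodicity(m, 10):.0f} "
      "(even sizes are the preferred building blocks)")
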