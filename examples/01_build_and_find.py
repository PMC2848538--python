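"""Build R_19 and find minimal balanced pathways for two neighbouring tasks.

Converting a_9 into a_6 shares a factor of 3, so two reactions suffice
(cleave a_9 into a_3 + a_6, fuse two a_3 into a_6).  Converting a_9 into the
coprime a_7 is far harder; the MILP proves the minimum and prints the
witness fluxes (uptake fixed at 10 units, secretion at full yield 10*i/j).
"""

from mbpkit import build_network, find_mbp
from mbpkit.milp import MbpTask

net = build_network(19)
print(f"R_19: {net.n_internal} internal reactions")

for i, j in [(9, 6), (9, 7)]:
    sol = find_mbp(net, MbpTask(i, j))
    print(f"\na_{i} => a_{j}: {sol.length} reactions")
    for rid in sorted(sol.active_reactions):
        print(f"  {rid:12s} flux {sol.flux[rid]: .3f}")
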