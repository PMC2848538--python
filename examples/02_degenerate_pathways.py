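"""Enumerate all equally-optimal pathways of one task and spot the
autocatalytic ones.

The a_9 => a_10 task has many distinct minimal 5-reaction realizations: each
ligates a_1 + a_9 -> a_10 and regenerates the a_1 by breaking one a_10 back
down in a different way.  Pathways that cannot fire from the input alone
(they need an intermediate seeded, then return it with interest) are flagged
as autocatalytic cycles.
"""

from mbpkit import build_network, detect_autocatalytic, mbps_from_efms, task_efms
from mbpkit.milp import MbpTask

net = build_network(10)
task = MbpTask(9, 10)
modes = task_efms(net, task, max_internal_support=5)
dset = mbps_from_efms(modes, task)
print(f"a_9 => a_10: minimal length {dset.length}, "
      f"{len(dset.solutions)} distinct optimal pathways")
for sol in dset.solutions:
    tag = "autocatalytic" if detect_autocatalytic(sol) else "bootstraps"
    print(f"  [{tag:13s}] {', '.join(sorted(sol.active_reactions))}")
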