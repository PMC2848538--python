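"""Addition-chain arithmetic predicts pathway lengths without solving.

The shortest way to assemble a_128 from monomers mirrors the shortest
addition chain reaching 128 (seven doublings).  The analytic estimate
log2(i') + log2(j') -- after dividing the task by gcd(i, j) -- tracks the
computed optima: ~2.6 for (9,6) and ~6 for (9,7).
"""

from mbpkit import chain_bounds, predict_mbp_length, shortest_addition_chain

for target in [16, 31, 128]:
    rec = shortest_addition_chain(target)
    b = chain_bounds(target)
    print(f"target {target:3d}: chain {rec.sequence} "
          f"({rec.n_operations} ops, {rec.n_elements} elements; "
          f"element bounds {b['lower_elements']}..{b['upper_elements']})")

sub = shortest_addition_chain(127, allow_subtraction=True)
print(f"with subtraction, 127 needs only {sub.n_operations} ops: {sub.sequence}")

for i, j in [(9, 6), (9, 7), (1, 128)]:
    p = predict_mbp_length(i, j)
    print(f"predicted length a_{i} => a_{j}: {p.predicted:.2f} reactions")
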