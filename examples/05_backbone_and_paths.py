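"""Project a reaction table onto its carbon backbone and measure shortest
paths in a small metabolic network.

Uses the synthetic fixture generators (no downloads): a LIGAND-style table
with a planted duplicated reaction, and a toy central-carbon network whose
glucose-to-pyruvate geodesic is known by construction.
"""

import tempfile
from pathlib import Path

from mbpkit import (
    all_pairs_shortest,
    backbone_usage,
    build_graph,
    generate_fixture,
    nearest_size_matrix,
    parse_compound_table,
    parse_reaction_table,
    read_stoichiometric_tsv,
    reduce_reactions,
)
from mbpkit.fixtures import FixtureSpec

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    mani = generate_fixture(FixtureSpec(kind="kegg_like_table", seed=1), tmp / "kegg")
    comps, _ = parse_compound_table(tmp / "kegg" / mani["compounds"])
    rxns, _ = parse_reaction_table(tmp / "kegg" / mani["reactions"])
    reduced, report = reduce_reactions(rxns, comps, "C")
    rxn_usage, met_usage = backbone_usage(reduced)
    print(f"reduced {len(reduced)} reactions "
          f"({sum(len(v) for v in report.values())} excluded by the filters)")
    top_key, top_count = rxn_usage.ranked()[0]
    subs, prods = top_key
    print("most frequent backbone reaction: "
          f"C{'+C'.join(map(str, subs))} <-> C{'+C'.join(map(str, prods))} "
          f"({top_count} occurrences; planted truth {mani['planted_count']})")

    mani = generate_fixture(FixtureSpec(kind="toy_central_carbon"), tmp / "toy")
    stoich = read_stoichiometric_tsv(tmp / "toy" / mani["network"])
    carbons = {l.split("\t")[0]: int(l.split("\t")[1])
               for l in (tmp / "toy" / mani["carbons"]).read_text().splitlines()}
    bg = build_graph(stoich, carbon_counts=carbons)
    dist = all_pairs_shortest(bg)
    print(f"glc -> pyr: {dist.at['glc', 'pyr']:.0f} reactions "
          f"(planted {mani['planted_distances']['glc->pyr']})")
    A = nearest_size_matrix(dist, carbons)
    print("average distance from a 6-carbon compound to its nearest "
          f"3-carbon compound: {A.values.at[6, 3]:.2f} reactions")
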