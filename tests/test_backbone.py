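import pytest

from mbpkit.backbone import (
    Reaction,
    backbone_usage,
    compare_rankings,
    model_key_of_ligation,
    parse_compound_table,
    parse_formula,
    parse_reaction_table,
    reduce_reactions,
)
from mbpkit.fixtures import FixtureSpec, generate_fixture
from mbpkit.usage import UsageTable


@pytest.mark.parametrize("formula,expected", [
    ("C6H14O12P2", {"C": 6, "H": 14, "O": 12, "P": 2}),
    ("C3H7O6P", {"C": 3, "H": 7, "O": 6, "P": 1}),
    ("H2O", {"H": 2, "O": 1}),
    ("C2H3ZnN", {"C": 2, "H": 3, "Zn": 1, "N": 1}),
])
def test_formula_parsing(formula, expected):
    f = parse_formula("X1", formula)
    assert not f.uncertain
    assert f.elements == expected


@pytest.mark.parametrize("formula", [
    "(C5H8)n", "C10H15R", "C5H8X2", "C12H20O10.H2O", "", "C6H12*",
])
def test_uncertain_formulas_flagged(formula):
    assert parse_formula("X1", formula).uncertain


def test_compound_table_reports_malformed_rows(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text("C1\tC6H12O6\nbadline\nC2\tC3H7O6P\n\nC3\tH2O\textra\n")
    comps, errors = parse_compound_table(p)
    assert [c.compound_id for c in comps] == ["C1", "C2"]
    assert len(errors) == 2


def _toy_tables():
    compounds = [
        parse_formula("fbp", "C6H14O12P2"),
        parse_formula("dhap", "C3H7O6P"),
        parse_formula("g3p", "C3H7O6P"),
        parse_formula("water", "H2O"),
        parse_formula("rgroup", "C4H7R"),
    ]
    reactions = [
        Reaction("ald", [(1, "fbp")], [(1, "dhap"), (1, "g3p")]),
        Reaction("tpi", [(1, "dhap")], [(1, "g3p")]),
        Reaction("bad", [(1, "rgroup")], [(1, "dhap")]),
        Reaction("hydr", [(1, "fbp"), (1, "water")], [(1, "fbp")]),
        Reaction("missing", [(1, "nothere")], [(1, "g3p")]),
    ]
    return reactions, compounds


def test_aldolase_reduces_to_carbon_partition():
    reactions, compounds = _toy_tables()
    reduced, report = reduce_reactions(reactions, compounds, "C")
    keys = [r.key for r in reduced]
    assert ((3, 3), (6,)) in keys  # C6 <-> C3 + C3 with small side first
    assert report["identity"] == ["tpi", "hydr"]  # C3<->C3; water adds no C
    assert report["uncertain"] == ["bad"]
    assert report["unknown_compound"] == ["missing"]


def test_reduction_is_orientation_free():
    _, compounds = _toy_tables()
    fwd = Reaction("f", [(1, "fbp")], [(1, "dhap"), (1, "g3p")])
    rev = Reaction("r", [(1, "dhap"), (1, "g3p")], [(1, "fbp")])
    (a,), _ = reduce_reactions([fwd], compounds, "C")
    (b,), _ = reduce_reactions([rev], compounds, "C")
    assert a.key == b.key


def test_stoichiometric_multipliers_expand():
    compounds = [parse_formula("tri", "C3H6O3"), parse_formula("hex", "C6H12O6")]
    rxn = Reaction("condense", [(2, "tri")], [(1, "hex")])
    (red,), _ = reduce_reactions([rxn], compounds, "C")
    assert red.key == ((3, 3), (6,))


def test_backbone_usage_counts():
    _, compounds = _toy_tables()
    rxns = [
        Reaction("a1", [(1, "fbp")], [(1, "dhap"), (1, "g3p")]),
        Reaction("a2", [(1, "dhap"), (1, "g3p")], [(1, "fbp")]),
    ]
    reduced, _ = reduce_reactions(rxns, compounds, "C")
    rxn_table, met_table = backbone_usage(reduced)
    assert rxn_table.counts == {((3, 3), (6,)): 2}
    # per reaction each atom count appears once: C6 twice, C3 twice
    assert met_table.counts == {6: 2, 3: 2}


def test_spearman_comparison_directions():
    model = UsageTable("reaction", {
        f"L_{i}+{i}={2 * i}": 10 - i for i in range(1, 7)})
    same = UsageTable("reaction", {
        model_key_of_ligation(k): v for k, v in model.counts.items()})
    assert compare_rankings(model, same)["rho"] == pytest.approx(1.0)
    reverse = UsageTable("reaction", {
        model_key_of_ligation(k): 20 - v for k, v in model.counts.items()})
    assert compare_rankings(model, reverse)["rho"] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        compare_rankings(model, UsageTable("reaction", {((1, 1), (2,)): 3}))


def test_kegg_like_fixture_round_trip(tmp_path):
    """The planted duplicate count must be recovered by the full parse +
    reduce + count pipeline."""
    manifest = generate_fixture(
        FixtureSpec(kind="kegg_like_table", seed=11, planted_duplicates=7),
        tmp_path)
    comps, cerr = parse_compound_table(tmp_path / manifest["compounds"])
    rxns, rerr = parse_reaction_table(tmp_path / manifest["reactions"])
    assert not cerr and not rerr
    reduced, report = reduce_reactions(rxns, comps, "C")
    assert len(reduced) == manifest["n_reduced_expected"]
    assert sum(len(v) for v in report.values()) == manifest["n_excluded_expected"]
    rxn_table, _ = backbone_usage(reduced)
    a, b = manifest["planted_key"]
    key = (tuple(a), tuple(b))
    assert rxn_table.counts[key] == manifest["planted_count"]
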