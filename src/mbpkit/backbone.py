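"""Single-atom backbone reduction of real reaction tables.

Real biochemistry can be compared with the string-ligation chemistry by
projecting every compound onto its count of one element: the aldolase
cleavage of fructose-1,6-bisphosphate (C6H14O12P2) into two C3 triose
phosphates becomes simply ``C6 <-> C3 + C3``, formally the ``a_6 <-> a_3 +
a_3`` reaction of the model.  This module parses a small documented TSV
dialect (a two-column compound table ``compound_id<TAB>formula`` and a
three-column reaction table ``reaction_id<TAB>substrates<TAB>products`` with
sides written ``2 C00001 + 1 C00002``), applies the exclusion filters
(uncertain formulas, missing formulas, identity reactions that leave the
atom-count multiset unchanged), and counts usage of the surviving reduced
reactions and their atom-count metabolites.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from scipy import stats

from .usage import UsageTable

__all__ = [
    "CompoundFormula",
    "BackboneReaction",
    "parse_formula",
    "parse_compound_table",
    "parse_reaction_table",
    "reduce_reactions",
    "backbone_usage",
    "compare_rankings",
    "DEFAULT_COFACTORS",
]

#: cofactors stripped before graph analyses (shuttle molecules that do not
#: transfer carbon skeleton between the main substrates)
DEFAULT_COFACTORS = [
    "ATP", "ADP", "AMP", "NAD+", "NADH", "NADP+", "NADPH",
    "CoA", "acetyl-CoA", "ACP",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
#: placeholder "element" symbols that denote unspecified parts
_WILDCARDS = {"R", "X"}


@dataclass
class CompoundFormula:
    compound_id: str
    elements: dict[str, int] = field(default_factory=dict)
    uncertain: bool = False

    def count(self, element: str) -> int:
        return self.elements.get(element, 0)


def parse_formula(compound_id: str, formula: str) -> CompoundFormula:
    """Parse a Hill-style formula string into element counts.

    Any R-group, wildcard, parenthesised repeat or variable ``n`` subscript
    marks the compound as uncertain; uncertain compounds are excluded from
    all downstream reductions.
    """
    formula = formula.strip()
    uncertain = CompoundFormula(compound_id, {}, uncertain=True)
    # parentheses, wildcards, repeat counts ("(C5H8)n") never tokenize cleanly
    if not formula or not formula.isalnum():
        return uncertain
    elements: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            return uncertain  # stray lowercase such as a trailing "n"
        pos = m.end()
        symbol = m.group(1)
        if symbol in _WILDCARDS:
            return uncertain  # R-group / unspecified side chain
        elements[symbol] = elements.get(symbol, 0) + int(m.group(2) or 1)
    if pos != len(formula) or not elements:
        return uncertain
    return CompoundFormula(compound_id, elements, uncertain=False)


def parse_compound_table(path: str | Path) -> tuple[list[CompoundFormula], list[str]]:
    """Read the two-column compound TSV; returns (compounds, error lines).

    Malformed rows are reported with their line number, skipped and counted;
    they never abort the parse.
    """
    compounds: list[CompoundFormula] = []
    errors: list[str] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip():
                errors.append(f"line {lineno}: expected 2 columns, got {len(parts)}")
                continue
            compounds.append(parse_formula(parts[0].strip(), parts[1]))
    return compounds, errors


@dataclass
class Reaction:
    reaction_id: str
    substrates: list[tuple[int, str]]
    products: list[tuple[int, str]]


def _parse_side(text: str) -> list[tuple[int, str]]:
    out = []
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ValueError("empty term")
        bits = term.split()
        if len(bits) == 1:
            out.append((1, bits[0]))
        elif len(bits) == 2:
            out.append((int(bits[0]), bits[1]))
        else:
            raise ValueError(f"bad term {term!r}")
    return out


def parse_reaction_table(path: str | Path) -> tuple[list[Reaction], list[str]]:
    """Read the three-column reaction TSV; returns (reactions, error lines)."""
    reactions: list[Reaction] = []
    errors: list[str] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                errors.append(f"line {lineno}: expected 3 columns, got {len(parts)}")
                continue
            try:
                reactions.append(Reaction(parts[0].strip(),
                                          _parse_side(parts[1]),
                                          _parse_side(parts[2])))
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    return reactions, errors


@dataclass(frozen=True)
class BackboneReaction:
    """A reaction projected to one element's atom counts.

    ``key`` is orientation-free: each side is a sorted tuple of atom counts
    (stoichiometric multipliers expanded into multiset multiplicity) and the
    lexicographically smaller side comes first, so A<->B and B<->A reduce to
    the same key.
    """

    element: str
    key: tuple[tuple[int, ...], tuple[int, ...]]

    @property
    def substrate_counts(self) -> tuple[int, ...]:
        return self.key[0]

    @property
    def product_counts(self) -> tuple[int, ...]:
        return self.key[1]


def _reduce_side(side, lookup, element):
    counts = []
    for coeff, cid in side:
        n = lookup[cid].count(element)
        if n > 0:
            counts.extend([n] * coeff)
    return tuple(sorted(counts))


def reduce_reactions(
    reactions: list[Reaction],
    compounds: list[CompoundFormula],
    element: str = "C",
) -> tuple[list[BackboneReaction], dict[str, list[str]]]:
    """Project reactions onto one element's backbone, applying the filters.

    Excluded (and reported by reason): reactions touching a compound with an
    uncertain formula; reactions referencing an unknown compound id; identity
    reactions whose atom-count multiset is unchanged by the reaction (e.g.
    C3 <-> C3 isomerizations); reactions with an empty side after dropping
    zero-count participants.
    """
    if element not in {"C", "H", "N", "O", "P", "S"}:
        raise ValueError(f"unsupported backbone element {element!r}")
    lookup = {c.compound_id: c for c in compounds}
    reduced: list[BackboneReaction] = []
    report: dict[str, list[str]] = {
        "uncertain": [], "unknown_compound": [], "identity": [], "empty_side": [],
    }
    for rxn in reactions:
        cids = [cid for _, cid in rxn.substrates + rxn.products]
        missing = [cid for cid in cids if cid not in lookup]
        if missing:
            report["unknown_compound"].append(rxn.reaction_id)
            continue
        if any(lookup[cid].uncertain for cid in cids):
            report["uncertain"].append(rxn.reaction_id)
            continue
        left = _reduce_side(rxn.substrates, lookup, element)
        right = _reduce_side(rxn.products, lookup, element)
        if left == right:
            report["identity"].append(rxn.reaction_id)
            continue
        if not left or not right:
            report["empty_side"].append(rxn.reaction_id)
            continue
        key = (left, right) if left <= right else (right, left)
        reduced.append(BackboneReaction(element=element, key=key))
    return reduced, report


def backbone_usage(
    reduced: list[BackboneReaction], *, weight_by_stoichiometry: bool = False
) -> tuple[UsageTable, UsageTable]:
    """Usage tables over reduced reactions and their atom-count metabolites.

    Reaction usage counts identical canonical keys; metabolite usage counts,
    for each atom count, the number of reduced reactions it appears in (once
    per reaction by default, mirroring the model-side counting rule; with
    ``weight_by_stoichiometry`` every multiset occurrence counts).
    """
    if not reduced:
        raise ValueError("no reactions survived the reduction filters")
    rxn_counts: Counter = Counter(r.key for r in reduced)
    met_counts: Counter = Counter()
    for r in reduced:
        sizes = list(r.substrate_counts + r.product_counts)
        if not weight_by_stoichiometry:
            sizes = set(sizes)
        for s in sizes:
            met_counts[s] += 1
    return (
        UsageTable(kind="reaction", counts=dict(rxn_counts)),
        UsageTable(kind="metabolite", counts=dict(met_counts)),
    )


def model_key_of_ligation(reaction_id: str) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Canonical backbone key of a model ligation ``L_i+j=k``."""
    left, rest = reaction_id[2:].split("+")
    right, product = rest.split("=")
    a = tuple(sorted((int(left), int(right))))
    b = (int(product),)
    return (a, b) if a <= b else (b, a)


def compare_rankings(model_table: UsageTable, backbone_table: UsageTable) -> dict:
    """Spearman rank correlation between model and backbone reaction usage.

    The model ligation ``a_i + a_j <-> a_k`` is matched with the backbone
    reaction ``C_i + C_j <-> C_k``; only reactions present in both tables
    enter the correlation.
    """
    if not model_table.counts or not backbone_table.counts:
        raise ValueError("empty usage table")
    model = {model_key_of_ligation(rid): c for rid, c in model_table.counts.items()}
    common = sorted(set(model) & set(backbone_table.counts))
    if len(common) < 5:
        raise ValueError(f"only {len(common)} reactions in common; need >= 5")
    x = [model[k] for k in common]
    y = [backbone_table.counts[k] for k in common]
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "n_common": len(common)}
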