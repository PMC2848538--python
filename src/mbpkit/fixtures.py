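"""Synthetic input generation and pipeline orchestration.

Everything here is synthetic and self-contained: fixtures emulate the file
dialects of real-network exports (compound/reaction tables, stoichiometric
TSVs) with *planted ground truth* recorded in a manifest, so that parsers,
reducers and shortest-path code can be verified without any download.  The
``run_pipeline`` entry point chains network construction, pathway discovery
by a chosen algorithm, usage statistics and power-law fitting into one
machine-readable summary.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FixtureSpec", "RunConfig", "generate_fixture", "run_pipeline"]


@dataclass
class FixtureSpec:
    kind: str  # kegg_like_table | toy_central_carbon | planted_geodesic_graph
    seed: int = 0
    n_compounds: int = 30
    n_reactions: int = 40
    planted_duplicates: int = 7
    geodesic_length: int = 4

    def validate(self) -> None:
        kinds = {"kegg_like_table", "toy_central_carbon", "planted_geodesic_graph"}
        if self.kind not in kinds:
            raise ValueError(f"unknown fixture kind {self.kind!r}; one of {sorted(kinds)}")


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write fixture files plus a JSON manifest of planted truths.

    Same spec + seed produces byte-identical files.  Returns the manifest.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "kegg_like_table":
        manifest = _kegg_like(spec, outdir, rng)
    elif spec.kind == "toy_central_carbon":
        manifest = _toy_central_carbon(spec, outdir)
    else:
        manifest = _planted_geodesic(spec, outdir, rng)
    manifest["kind"] = spec.kind
    manifest["seed"] = spec.seed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def _kegg_like(spec: FixtureSpec, outdir: Path, rng) -> dict:
    """Compound + reaction TSVs emulating a LIGAND-style export.

    Carbon contents are drawn 1..12; reactions are ligation-shaped
    (C_p + C_q -> C_{p+q}) over compounds with matching carbon counts, with
    one designated reaction key repeated ``planted_duplicates`` times.  A
    sprinkle of uncertain compounds (R-groups, polymer repeats) and an
    identity isomerization exercise every exclusion filter.
    """
    carbons = rng.integers(1, 13, size=spec.n_compounds)
    rows, compounds = [], {}
    for idx, c in enumerate(carbons):
        cid = f"C{idx:05d}"
        h = int(2 * c + 2)
        o = int(rng.integers(0, c + 1))
        compounds[cid] = int(c)
        rows.append(f"{cid}\tC{c}H{h}" + (f"O{o}" if o else ""))
    # uncertain entries (always excluded downstream)
    rows.append("CRGRP\tC10H15R")
    rows.append("CPOLY\t(C5H8)n")
    compounds_path = outdir / "compounds.tsv"
    compounds_path.write_text("\n".join(rows) + "\n")

    by_carbon: dict[int, list[str]] = {}
    for cid, c in compounds.items():
        by_carbon.setdefault(c, []).append(cid)
    usable = sorted(c for c in by_carbon if c >= 2)
    rxn_rows = []
    planted_key = None
    key_counts: dict[tuple, int] = {}
    n_written = 0
    attempts = 0
    while n_written < spec.n_reactions and attempts < 50 * spec.n_reactions:
        attempts += 1
        k = int(rng.choice(usable))
        p = int(rng.integers(1, k // 2 + 1))
        q = k - p
        if p not in by_carbon or q not in by_carbon:
            continue
        s1 = str(rng.choice(by_carbon[p]))
        s2 = str(rng.choice(by_carbon[q]))
        prod = str(rng.choice(by_carbon[k]))
        rxn_rows.append(f"R{n_written:05d}\t1 {s1} + 1 {s2}\t1 {prod}")
        key = (tuple(sorted((p, q))), (k,))
        key_counts[key] = key_counts.get(key, 0) + 1
        if planted_key is None:
            planted_key = key
            planted_parts = (s1, s2, prod)
        n_written += 1
    # planted duplicates of the first reaction's carbon key (accidental
    # collisions among the random rows are part of the recorded truth)
    s1, s2, prod = planted_parts
    extra = spec.planted_duplicates - 1
    for d in range(extra):
        rxn_rows.append(f"RDUP{d:03d}\t1 {s1} + 1 {s2}\t1 {prod}")
    planted_count = key_counts[planted_key] + extra
    # excluded rows: identity isomerization, R-group participant, unknown id
    first_cid = next(iter(compounds))
    rxn_rows.append(f"RIDENT\t1 {first_cid}\t1 {first_cid}")
    rxn_rows.append(f"RUNCRT\t1 CRGRP\t1 {first_cid}")
    rxn_rows.append(f"RUNKWN\t1 CMISSING\t1 {first_cid}")
    reactions_path = outdir / "reactions.tsv"
    reactions_path.write_text("\n".join(rxn_rows) + "\n")
    a, b = planted_key
    return {
        "compounds": compounds_path.name,
        "reactions": reactions_path.name,
        "planted_key": [list(a), list(b)],
        "planted_count": planted_count,
        "n_excluded_expected": 3,
        "n_reduced_expected": n_written + extra,
    }


#: a glycolysis-flavoured 10-metabolite toy: hexose -> 2 triose -> ...
_TOY_REACTIONS = [
    ("R_hk", {"glc": -1, "g6p": 1}),
    ("R_pgi", {"g6p": -1, "f6p": 1}),
    ("R_ald", {"f6p": -1, "dhap": 1, "g3p": 1}),
    ("R_tpi", {"dhap": -1, "g3p": 1}),
    ("R_gapd", {"g3p": -1, "pg3": 1}),
    ("R_eno", {"pg3": -1, "pep": 1}),
    ("R_pyk", {"pep": -1, "pyr": 1}),
    ("R_pdc", {"pyr": -1, "acald": 1, "co2": 1}),
    ("R_synth", {"pyr": -2, "hex": 1}),  # 2 C3 -> C6 condensation
]

_TOY_CARBONS = {
    "glc": 6, "g6p": 6, "f6p": 6, "dhap": 3, "g3p": 3, "pg3": 3,
    "pep": 3, "pyr": 3, "acald": 2, "co2": 1, "hex": 6, "atp": 0,
}


def _toy_central_carbon(spec: FixtureSpec, outdir: Path) -> dict:
    """Small deterministic central-carbon-style stoichiometric TSV.

    Ground truth: glc and pyr are 4 reactions apart (hk, pgi, ald/tpi route
    compressed), and the carbon map marks atp as a zero-carbon cofactor that
    must vanish from the graph.
    """
    mets = sorted(_TOY_CARBONS)
    rxns = [name for name, _ in _TOY_REACTIONS]
    lines = ["species\t" + "\t".join(rxns)]
    for m in mets:
        row = [str(dict(stoich).get(m, 0)) for _, stoich in _TOY_REACTIONS]
        lines.append(m + "\t" + "\t".join(row))
    net_path = outdir / "network.tsv"
    net_path.write_text("\n".join(lines) + "\n")
    carb_path = outdir / "carbons.tsv"
    carb_path.write_text(
        "\n".join(f"{m}\t{_TOY_CARBONS[m]}" for m in mets) + "\n")
    return {
        "network": net_path.name,
        "carbons": carb_path.name,
        "planted_distances": {"glc->pyr": 6, "glc->g6p": 1, "dhap->g3p": 1},
        "zero_carbon": ["atp"],
    }


def _planted_geodesic(spec: FixtureSpec, outdir: Path, rng) -> dict:
    """A chain of reactions planting an exact geodesic of known length, with
    random decoy branches that never shorten it."""
    L = spec.geodesic_length
    mets = [f"m{i}" for i in range(L + 1)]
    rxns = [f"r{i}" for i in range(L)]
    stoich: dict[str, dict[str, int]] = {r: {} for r in rxns}
    for i, r in enumerate(rxns):
        stoich[r][mets[i]] = -1
        stoich[r][mets[i + 1]] = 1
    # decoys hang off the chain as dead ends
    n_decoys = int(rng.integers(2, 5))
    for d in range(n_decoys):
        src = mets[int(rng.integers(0, L + 1))]
        dm, dr = f"d{d}", f"rd{d}"
        mets.append(dm)
        rxns.append(dr)
        stoich[dr] = {src: -1, dm: 1}
    lines = ["species\t" + "\t".join(rxns)]
    for m in mets:
        lines.append(m + "\t" + "\t".join(str(stoich[r].get(m, 0)) for r in rxns))
    net_path = outdir / "network.tsv"
    net_path.write_text("\n".join(lines) + "\n")
    carb_path = outdir / "carbons.tsv"
    carb_path.write_text("\n".join(f"{m}\t1" for m in mets) + "\n")
    return {
        "network": net_path.name,
        "carbons": carb_path.name,
        "planted_distance": {"from": "m0", "to": mets[L], "reactions": L},
    }


@dataclass
class RunConfig:
    N: int = 10
    algorithm: str = "efm"  # efm | milp | iterative
    seed: int = 0
    solver_timeout: float | None = None
    outdir: str | Path = "mbp_run"
    dry_run: bool = False
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.algorithm not in {"efm", "milp", "iterative"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def to_json(self) -> dict:
        return {
            "N": self.N, "algorithm": self.algorithm, "seed": self.seed,
            "solver_timeout": self.solver_timeout, "outdir": str(self.outdir),
        }


def run_pipeline(config: RunConfig) -> dict:
    """Build R_N, find pathways with the chosen algorithm, compute usage and
    the power-law fit, and write a versioned summary JSON.

    Stage timings are collected; a dry run validates the config and touches
    nothing.
    """
    config.validate()
    if config.dry_run:
        return {"schema": 1, "config": config.to_json(), "dry_run": True}
    from .chemistry import build_network
    from .usage import fit_power_law, metabolite_usage, reaction_usage

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {"schema": 1, "config": config.to_json()}

    t0 = time.perf_counter()
    net = build_network(config.N)
    timings["build"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.algorithm == "milp":
        from .milp import mbp_length_table

        L, sols = mbp_length_table(net, time_limit=config.solver_timeout,
                                   collect_solutions=True)
        supports = [s.active_reactions for (i, j), s in sols.items() if i != j]
        summary["length_matrix"] = L[1:, 1:].tolist()
    elif config.algorithm == "efm":
        from .efm import degenerate_catalogue

        cat = degenerate_catalogue(net, include_identity=True)
        supports = [s.active_reactions
                    for (i, j), d in cat.items() if i != j
                    for s in d.solutions]
        summary["degenerate_counts"] = {
            f"{i}->{j}": len(d.solutions) for (i, j), d in sorted(cat.items())}
        summary["total_degenerates"] = sum(
            len(d.solutions) for d in cat.values())
    else:
        from .iterative import build_all_mbps_iterative

        table = build_all_mbps_iterative(config.N)
        supports = [table.representative(i, j)
                    for i in range(1, config.N + 1)
                    for j in range(1, config.N + 1) if i != j]
        summary["length_matrix"] = table.length_matrix()[1:, 1:].tolist()
    timings["pathways"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    nonempty = [s for s in supports if s]
    r_usage = reaction_usage(nonempty)
    m_usage = metabolite_usage(nonempty)
    fit = fit_power_law(r_usage)
    timings["usage"] = time.perf_counter() - t0
    summary["reaction_usage"] = {k: v for k, v in r_usage.ranked()}
    summary["metabolite_usage"] = {str(k): v for k, v in m_usage.ranked()}
    summary["power_law"] = {"exponent": fit.exponent, "r_squared": fit.r_squared}
    summary["timings"] = timings
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
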