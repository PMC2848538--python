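# Methods

## Model

The chemistry is the set of linear polymers `a_1 … a_N` of one monomer with
every reversible uni-bi ligation/cleavage `a_i + a_j ⇌ a_{i+j}` (`i ≤ j`,
`i + j ≤ N`).  Monomer count is the only conserved quantity; each species
`a_k` (k ≥ 2) is producible in exactly `⌊k/2⌋` ways, giving
`Σ_{k=2..N} ⌊k/2⌋ ≈ N²/4` internal reactions.  Self-ligations are encoded
with stoichiometric coefficient −2 on the substrate so that steady-state
accounting is exact.  Every species carries one exchange reaction, closed by
default; a task `a_i ⇒ a_j` opens exactly two (uptake of `a_i`, fixed at
`v_in = 10` arbitrary flux units, and secretion of `a_j`).  With only those
two exchanges open, `S·v = 0` forces the waste-free maximal yield
`i·v_in = j·v_out`; the package enforces the monomer-conserving ratio
`v_out = v_in·i/j` throughout (the inverted ratio sometimes quoted for this
model violates conservation whenever `i ≠ j` and cannot admit a steady
state).

A minimal balanced pathway (MBP) is a support-minimal set of internal
reactions carrying such a flux.  Pathway *length* counts distinct active
internal reactions — a reversible reaction used in either direction counts
once, and exchange fluxes never count.

## Exact algorithms

**Flux-minimizing MILP.**  Each reversible reaction is split into forward
and backward nonnegative fluxes sharing one binary activity indicator
`b_r`; the objective is `min Σ b_r` subject to steady state, the two fixed
exchange rates, and `v ≤ M·b` with `M = 10·N·v_in`.  Two families of valid
cuts tighten the weak big-M relaxation without touching the optimum: a
species-touched binary `y_s` with `b_r ≤ y_s` for every species of `r`, and
degree constraints `Σ_{r∋s} b_r ≥ 2·y_s` for intermediates (an intermediate
has no exchange, so any touched one must appear in at least two active
reactions) and `≥ 1` for the task species.  These cuts reduce the hardest
`R_19` instances from minutes to seconds under HiGHS.  Because the
objective is integral and well below 20, a relative MIP gap of 0.05
certifies optimality (absolute gap < 1).  Binaries are rounded at 0.5 and
fluxes below `10⁻⁶·v_in` treated as zero.  Tasks with `i = j` return the
empty pathway directly.  Length tables exploit the exact reversal symmetry
`L(i,j) = L(j,i)` (negating a witness flux maps one task onto the other)
and solve each unordered pair once.

**Elementary flux modes.**  The enumerator is the canonical tableau /
double-description algorithm in exact integer arithmetic: reversible
columns are split, one metabolite is eliminated per step by combining rows
of opposite residual sign, and a combination survives only when no third
row's support fits inside the union (supports are bitmask sets, so the test
is vectorized word-wise).  Two exact pruning rules control growth: after
`k` eliminations any surviving mode has support ≤ `k + 1` (its support
submatrix always has nullity one), and an optional caller bound restricts
the run to modes no larger than the bound — complete for all modes within
it, since every non-elementary candidate inside the bound is witnessed by a
strictly smaller surviving row.  Unbounded enumeration is guarded above 60
split columns (an `R_10` task already has ~42 000 modes).  For the
degenerate-pathway census the bound is seeded from the iterative assembly's
upper bound, an independent route; minimal-support full-yield modes equal
the MBP set exactly, and their count per task is the degeneracy.  The
`R_10` census was additionally cross-checked against brute-force subset
enumeration (SVD kernel test over all supports up to the minimal size).

Autocatalytic cycles are detected by constructive reachability: starting
from the input species alone, fire any active reaction (in its used
direction, read off the witness flux sign) whose substrates are available;
a pathway with an unfireable residue needs an intermediate seeded before it
can run — it regenerates that seed with interest at steady state.

**Identity-task convention.**  Census totals count all ordered pairs
including the ten trivial `i = j` tasks of `R_10` (whose single "pathway"
is the empty reaction set); the non-identity total is 374 and the inclusive
total 384.

## Approximate algorithm

The iterative additive assembly composes candidate pathways from
already-solved smaller tasks, iterated to a fixpoint on set-union
cardinality: composition-up (`j = p + q`: merge `i⇒p` and `i⇒q`, add
`p+q→j`), cleavage-down (`i = p + q`: cleave the input, merge `p⇒j` and
`q⇒j`), and gcd pre-reduction (rescale a solved reduced task by
`g = gcd(i,j)` when all scaled species fit).  Reaction sets are bitmasks;
all minimal-cardinality sets per task are kept up to a cap (default 64,
lowest masks kept, making the table order-independent).  The recursion for
general inputs is this package's design: it deliberately has no overshoot
rule, so it misses pathways that exceed the target and subtract down, and
pathways not built modularly — hence its lengths upper-bound the exact
optimum (on `R_19` the excess is never more than one reaction).  Those
upper bounds also seed the MILP and the bounded mode enumeration.

## Analytics

Shortest addition(-subtraction) chains are found by iterative-deepening
depth-first search with the power-of-two reachability prune; subtraction
search caps intermediates at `2·target`, and targets are guarded at 10⁴.
Both length conventions are exposed: `n_elements` (the doubling chain to
`2^k` has `k+1` elements) and `n_operations = n_elements − 1`, which is the
reaction count.  Element-count bounds are `⌈log2 j⌉ + 1` (below) and
`⌊log2 j⌋ + ν(j)` (above, `ν` = binary ones).  The pathway-length predictor
is `log2(i′) + log2(j′)` after gcd reduction, zero on the diagonal; the
induced rank-usage prediction is `e_r ∝ 1/r`.

## Usage statistics

Reaction usage counts, per pathway, each distinct active reaction once
(never flux-weighted); metabolite usage counts one occurrence per active
reaction a species appears in.  When a task has several equally optimal
pathways, `task_weighted_reaction_usage` splits the task's unit weight
evenly across them — the expected usage under a uniformly random choice of
representative, which makes cross-algorithm comparisons insensitive to
which degenerate solution a solver happens to return.  Power-law exponents
are ordinary least squares of `log10(count)` on `log10(rank)` over the full
nonzero range (no tail cut).  Usage periodicity is the period of the
largest non-DC peak of the Fourier transform of the linearly detrended
usage-versus-size signal; for odd `N` the even/odd alternation lands in the
bin nearest period 2 (`19/9 ≈ 2.1` for `R_19`).  The knockout experiment
removes internal reactions in a given order and counts, by LP feasibility,
how many outputs remain producible from the default input `a_1` at full
yield; random orders are seeded and default to 20 replicates.

## Backbone reduction and graph distances

Compound formulas are parsed to element counts; any wildcard (R, X),
parenthesised repeat, stray lowercase tail or empty formula marks the
compound uncertain and excludes every reaction touching it, as do unknown
compound ids, and reactions whose atom-count multiset is unchanged
(`C_3 ⇌ C_3` isomerizations) are dropped.  Stoichiometric multipliers
expand into multiset multiplicity before reduction, zero-count participants
vanish, and keys are orientation-free (sorted sides, smaller side first).
File dialects are deliberately minimal TSVs documented in the parsers;
malformed rows are reported with line numbers and skipped.

Graph analyses treat the filtered stoichiometric matrix as an unweighted
undirected bipartite graph (metabolites ↔ reactions); metabolite distances
are node-path lengths halved, i.e. reaction counts.  Johnson's all-pairs
algorithm is used (on unit weights it coincides with per-source BFS, which
the tests assert).  The nearest-size matrix takes, per input compound, the
minimum distance to a `j`-carbon target first, then averages over
`i`-carbon inputs; the diagonal uses the nearest *other* same-size
compound, and unreachable entries carry an `NA` sentinel.  The
elementary-mode variant replaces graph distance by the minimal mode support
between the pair, which can only be larger since plain paths ignore mass
balance.

## Synthetic data

Fixture generators stand in for database exports so that nothing is ever
downloaded: a LIGAND-style compound/reaction table whose reactions are
ligation-shaped over random carbon contents with a planted duplicated
backbone key and deliberate uncertain/identity/unknown rows (every
exclusion filter is exercised and the exact surviving and planted counts
are recorded in a manifest); a deterministic ten-metabolite toy
central-carbon network with known geodesics and a zero-carbon cofactor; and
a planted-geodesic chain with random dead-end decoys.  All generators are
byte-reproducible from a seed.  They emulate table shape, filter edge cases
and distances — not the chemical realism, scale or degree distribution of
real databases, so passing them validates the machinery, not biological
conclusions.

## Problem sizes and known limitations

The shipped analyses use the network sizes the methods can treat exactly:
full `R_10` for the elementary-mode census (90 tasks, ~1 minute), full
`R_19` for the MILP sweep (171 unordered tasks, ~10–15 minutes), and the
iterative assembly up to `R_100` (seconds).  Computed optima can be
stricter than older reference values for this model: the MILP proves a
5-reaction pathway for `a_9 ⇒ a_7` in `R_19`, confirmed by an exact
rational witness and independently by bounded mode enumeration.  Exact
optimization also concentrates usage onto fewer universal reactions, so the
rank-usage exponents here are somewhat steeper (≈ −1.2 for `R_19`, ≈ −1.4
for the iterative `R_30…R_100` tables, mean ≈ −1.38) than the ≈ −1.1
sometimes associated with this model, while the power-law form itself and
the 1/rank prediction's qualitative fit are robust (R² > 0.92 throughout).
The iterative recursion is a heuristic by design; its stored degeneracy is
capped and lexicographically biased, so degenerate-set recovery counts
depend on that cap.  Unbounded mode enumeration beyond `R_10`-scale tasks
is out of reach of the tableau algorithm here, as is genome-scale mode
analysis generally.
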