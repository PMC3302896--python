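# Methods

This note documents the model implemented by `betatopo`, the parameters
that matter, the synthetic-data design, and the numerical and design
choices made where more than one reasonable option existed.

## Scope and assumptions

The model predicts the β-sheet topology — which strands pair, in which
orientation, at which register — of globular β and mixed α/β proteins with
at least three strands, taking the strand decomposition as given (from
DSSP output or a strand table). β-barrels are out of scope by design: the
contact graph of every returned topology is required to be acyclic, which
is what distinguishes open sheets from cyclically closed ones. Registers
are strictly gapless (pure sliding); β-bulges are not modeled.

## Pair scoring

Every strand pair is slid across itself in both orientations; each offset
scores the sum of a symmetric 20×20 residue-pair potential over aligned
positions, and the best-scoring offset per orientation is kept (ties break
to the smallest |offset|, then the smaller offset, for reproducibility).
Offsets with fewer than `min_overlap` (default 2) aligned residues are
discarded; a pair with no valid register is excluded from the model.

Database-derived pair potentials over-represent sequence-local contacts,
so scores are corrected by a per-separation multiplicative weight,
`locality_weights`: 0.9 at separation 1 and 1.0 at separation ≥ 2 by
default. Only the direction of this correction (down-weight local) is
established; the magnitude is a package default, configurable per
separation and deliberately mild. One shared vector is applied to both
orientations (a per-orientation override exists in the config).

The shipped default potential is a hydropathy-product table
(s(a,b) = kd(a)·kd(b)/20.25 with Kyte–Doolittle values, range ≈ [−1, 1]):
hydrophobic residues pair favorably, polar pairs are mildly penalized.
It is a documented stand-in with the right qualitative structure, not a
trained potential; any symmetric 20×20 TSV can be supplied instead, and
all accuracy-critical tests use designed tables. Residues outside the
standard 20 are read as 'X' and score 0 against everything.

## The optimization model

Variables: binary y^A_ij / y^P_ij per alignable pair (i < j); one
continuous w_kl ∈ [0, 1] per residue pair realized by any stored best
register; binary z_i (exactly-one-contact indicators) when terminal-strand
sets are active. w is tied to the strand binaries by *equality*
(w_kl = Σ of the y whose best register realizes (k, l)), so w integrality
is implied and — more importantly — the residue-level constraints have
force: with an upper-bound link the solver could zero every w and satisfy
the hydrogen-bond budget vacuously. The objective uses only y variables
with locality-corrected scores; w contributes through constraints.

Constraint families (defaults in parentheses; all configurable):

1. Orientation exclusivity: y^A_ij + y^P_ij ≤ 1.
2. Cardinalities: each strand 1–3 contacts (`max_contacts_per_strand` 3);
   total ≤ n − 1.
3. Residue face capacity: each residue in ≤ 2 active w.
4. Residue budget per strand: contacted residues of strand i in
   [max(1, L_i − 2), 2 L_i]. The upper bound is the geometric two-face
   maximum; the lower bound encodes that strands pair with partners of
   similar length. Both rules (`residue_budget_lo_slack`,
   `residue_budget_hi_factor`) are package choices.
5. Triple-overlap exclusion: for any three contacts of one strand whose
   aligned intervals on it pairwise overlap, at most two may be active —
   a third partner cannot wrap around an already double-covered face.
   Enumerated per (strand, partner-orientation triple); no big-M needed.
6. Edge rule: a strand keeps at most two contacts with partners outside
   {i−1, i+1, 1, n}. Applied to both orientations by default
   (`edge_rule_orientations`), with an antiparallel-only switch.
7. Non-local enabling: a contact with |j − i| ≥ `nonlocal_threshold` (3)
   requires an active contact of i or j with a *resolved* sequence
   neighbor. Neighbors are circular (the strand before the first is the
   last) and strands shorter than `min_neighbor_length` (4) are stepped
   over — a two/three-residue strand cannot pull distant chain segments
   together. At exactly the threshold separation, the two bridging
   contacts (i, j−1) and (i+1, j) also enable the pair: these are this
   package's reading of "two additional terms" for the boundary case —
   the contacts that close the gap one step at a time.
8. Pretzel exclusion: for every quartet i < j < k < l, the crossing
   chains {(i,k), (i,l), (j,l)} and {(i,k), (j,k), (j,l)} may each
   contain at most two active contacts.
9. Interlock: every active non-local contact (i, k) needs an active
   non-local (j, l) with i < j < k < l or j < i < l < k. "Exactly one"
   interlock is enforced as at-least-one in the model — an exactly-one
   formulation over quartic index sets explodes the model — with a
   post-hoc multiplicity flag in the validator's warnings.
10. Terminal sets: strands sorted by (length, hydrophobic count)
    ascending; for k = 1 … ⌊n/5⌋, at least k of the first 2k have exactly
    one contact (linearized via z_i: contacts_i + 2 z_i ≤ 3). Encodes
    hydrophobic collapse: short, less hydrophobic strands sit at sheet
    edges. The hydrophobic set defaults to {A, V, L, I, M, F, W, C, Y}.
11. Hydrogen-bond budget: ⌈0.85 T⌉ ≤ Σ w ≤ ⌊1.15 T⌋ with
    T = 0.638 · (β-residues); one active w counts as one hydrogen-bond
    unit. If rounding empties the interval (tiny proteins) the bound
    collapses to the nearest integer with a warning.

## Ranked solutions

The model is solved to a zero optimality gap with HiGHS
(`scipy.optimize.milp`; single-threaded, deterministic). After each
solve, the incumbent's strand-contact assignment O (cardinality c) is
excluded by the integer cut Σ_O y − Σ_{∉O} y ≤ c − 1; residue variables
never appear in cuts. Before an incumbent consumes a rank it must pass
two graph checks:

- **Acyclicity.** Any simple cycle of length ≥ 3 in the strand-contact
  graph marks a (sub-)barrel and is cut away. The n−1 total-contact bound
  alone does not prevent cycles when the graph is disconnected, so this
  check is done per solution rather than by up-front constraints (the
  number of potential cycle constraints grows exponentially).
- **Two-colorability.** Contacts become nodes; two contacts sharing a
  strand are connected when they have opposing orientations *or* their
  aligned intervals on the shared strand overlap in ≥ 1 position
  ("share an amino acid" is read as interval overlap; an exact-residue
  variant is a config option). Bipartiteness — checked by BFS, returning
  a 2-coloring or an odd-cycle witness — guarantees a consistent
  assignment of contacts to the two faces of every strand.

Rejected incumbents are cut without consuming a rank; accepted ones are
ranked by objective. Exact objective ties are resolved by the solver and
reported in rank order as tie groups; consecutive solutions always differ
in at least one strand binary. An iteration guard (100 K + 1000) bounds
pathological cut loops; infeasibility before the first solution returns
an empty list with a diagnostic log entry.

Every returned topology is re-validated outside the solver
(`validate_topology`), and the brute-force oracle filters its exhaustive
candidate set through the same validator — so solver and oracle can only
agree if objective, constraints and graph checks all match.

## Synthetic fixtures

The generator plants a topology that satisfies every constraint and
builds a table under which it is the unique optimum, so recovery is a
meaningful end-to-end test:

- Lengths: sheet-terminal strands 3–4 residues, interior strands 5–7,
  termini strictly shortest (matching the terminal-set rule).
- Topology: a sheet-order ladder — sequence order, or 1–4–3–2–5–…–n for
  n ≥ 5 (an interlocked greek-key-like order) half the time.
- Overlaps: initialized to full registers, then the largest registers are
  shrunk one residue at a time until the hydrogen-bond budget holds,
  respecting per-strand budgets.
- Sequences: poly-valine strands, glycine loops (≥ 1 residue, so strand
  boundaries are unambiguous), and per-contact *marker* residue pairs —
  two residue types unique to that contact, placed at positions aligned
  only by the planted register.
- Table: uniform background 2⁻⁴ (exact in binary floating point, so score
  comparisons have no rounding ambiguity) plus a boost of 2·overlap on
  each marker pair. Marker positions are chosen so the opposite
  orientation aligns them at a strictly smaller overlap, making the
  planted orientation, offset and register the unique optimum for its
  pair; non-planted pairs score ≤ background·overlap.
- The generator *verifies* all of this (best alignments equal the planted
  ones, planted passes full validation, every planted edge outscores every
  non-planted candidate edge) and deterministically retries with a derived
  sub-seed until the contract holds; (n, seed) is fully reproducible.

What these fixtures do not emulate: real energetics (the table is
designed, not learned), β-bulges, strand-assignment errors, or barrel
proteins. Passing the recovery and equivalence tests therefore shows the
*optimization machinery* is correct — it does not certify accuracy on
real proteins, which depends on the quality of the supplied potential.

## Numerical and degenerate-input choices

- Zero-denominator conventions in evaluation: precision/recall are 0 when
  their denominator is 0; MCC is 0 when any factor under the root is 0;
  all flagged in the `degenerate` field.
- Confusion counts default to orientation-agnostic pairs over all C(n, 2)
  pairs (including alignment-infeasible ones as negatives); the strict
  mode counts a right-pair/wrong-orientation prediction as both a false
  positive and a false negative.
- Strand mapping between predicted and native strand sets is greedy
  maximum-residue-overlap, one-to-one, requiring ≥ 1 shared residue;
  unmapped strands are excluded from evaluation.
- Parsers keep single-residue 'E' runs as strands; the minimum strand
  length for modeling (`min_strand_length`, default 2) is a config
  concern, not a parser concern. Strand indices are always re-derived
  from sequence order, never trusted from input files.
- Restraint export writes a Cα–Cα window of 4.2–5.5 Å per hydrogen-bonded
  pair (configurable), the conventional range for cross-strand partners.

## Problem sizes used in the automated checks

Solver-vs-oracle equivalence runs on 51 fixtures with 3–5 strands at
K = 8 (the exhaustive oracle is exponential and is capped at 6 strands);
planted-topology recovery on 50 four-strand fixtures at K = 5; the
two-colorability check on 1000 random graphs of up to 12 nodes against a
2^n exhaustive search; motif enumeration is cross-checked against the
closed form up to n = 7 (161 280 motifs). These sizes keep the full suite
under a minute while covering every constraint family; the model itself
handles the 3–10-strand fixture range in milliseconds per solve.

## Known limitations

- The exact weights of the locality correction and the residue-budget
  bound rules are package defaults (configurable), chosen for direction
  and scale rather than fitted.
- "Exactly one interlock" is relaxed to at-least-one inside the model
  (flagged post hoc).
- No β-barrels, no gapped registers, no β-bulges, no re-ranking by
  atomistic refinement — the restraint exporter is the hook for that
  stage.
- `brute_force_rank` is exponential and refuses n > 6.
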