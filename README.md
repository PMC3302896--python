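# betatopo

Rank-ordered β-sheet topology prediction for β and mixed α/β proteins by
mixed-integer linear optimization.

## The problem

Knowing which β-strands of a protein pair with which — in which orientation
(parallel or antiparallel) and at which register — pins down long-range
distance constraints that drastically shrink the conformational search
space of three-dimensional structure prediction. The combinatorics are
brutal: with the strand order within a sheet and the orientation of each
adjacent pair, a protein with *n* strands admits *n*!/2 · 2^(n−1) motifs
(8 strands → 2 580 480; 10 strands → 928 972 800), so enumeration is
hopeless beyond toy sizes and most arrangements are physically absurd.

`betatopo` takes only a sequence and its strand segments (a DSSP file or a
3-column strand table) and returns a rank-ordered list of biologically
plausible sheet topologies, each with explicit strand contacts, registers
and hydrogen-bonded residue pairs, plus an exporter of the corresponding
distance restraints for downstream atomistic refinement.

## The model

For every strand pair (i, j), i < j, and both orientations, the best
gapless register is found by sliding one strand along the other and
scoring aligned residues with a symmetric 20×20 contact potential (a
pluggable TSV; a hydropathy-based default ships with the package). Raw
scores are corrected for the local-contact bias of database-derived
potentials with a per-separation weight (0.9 at |j−i| = 1, 1.0 beyond).
Binary variables y^A_ij, y^P_ij select oriented contacts, and linked
residue variables w_kl mark the hydrogen-bonded pairs of the chosen
registers. The objective maximizes

    Σ_ij ( S^A_ij · y^A_ij + S^P_ij · y^P_ij )

subject to, for an n-strand protein:

- one orientation per pair: y^A_ij + y^P_ij ≤ 1;
- each strand has 1–3 contacts; a non-barrel protein has ≤ n−1 in total;
- each residue sits in ≤ 2 contacts (one per face);
- per-strand residue budget: total contacted residues of strand i within
  [max(1, L_i − 2), 2·L_i];
- three partners of one strand may not all overlap pairwise on it;
- a strand with three contacts keeps one among its sequence neighbors or
  the two chain-terminal strands;
- a non-local contact (|j−i| ≥ 3) requires an enabling contact of i or j
  with a resolved sequence neighbor (circular, skipping strands shorter
  than 4 residues);
- "pretzel" (crossing) quartet arrangements are forbidden, and every
  non-local contact must be matched by a bracketing non-local partner
  (an interlock);
- among the 2k shortest/least hydrophobic strands, at least k have exactly
  one contact (one such set per five strands);
- the total hydrogen-bond count lies within ±15 % of 0.638 · (β-residues).

Solving once gives the optimum; an integer cut then excludes the incumbent
contact assignment and the model is re-solved, producing ranks 1, 2, ….
Solutions whose contact graph contains a cycle (a barrel-like sheet) or
whose contact-incompatibility graph is not two-colorable (no consistent
assignment of contacts to the two faces of each strand) are cut away
without consuming a rank. The solver is HiGHS via `scipy.optimize.milp`,
single-threaded and deterministic.

A brute-force oracle (`brute_force_rank`) enumerates and validates *every*
candidate topology of small instances through exactly the same constraint
code path, which is how the solver is tested.

## Worked example

Generate a synthetic 5-strand protein with a known (planted) topology,
predict, and score the prediction:

```bash
betatopo fixture --n 5 --seed 42 --outdir demo/
betatopo predict --fasta demo/synth_n5_s42.fasta \
                 --strands demo/synth_n5_s42.strands.tsv \
                 --potential demo/synth_n5_s42.potential.tsv \
                 --top 5 --out demo/pred.json
betatopo evaluate --pred demo/pred.json --native demo/synth_n5_s42.native.json --k 5
```

prints

```
synth_n5_s42: 5 topologies, best objective 36.4750
k       precision       recall  mcc
1       1.0000  1.0000  1.0000
...
```

The rank-1 topology contains the contacts
`(1,4) parallel, (2,3) antiparallel, (2,5) antiparallel, (3,4) antiparallel`
— a single five-strand sheet in order 1–4–3–2–5 whose two non-local
contacts (1,4) and (2,5) form an interlock, exactly the planted
arrangement; precision, recall and Matthews correlation of 1.0 at every
k confirm the native topology sits at rank 1. The objective is the summed
locality-corrected contact potential of the four chosen registers.

`betatopo enumerate --n 10` prints the motif-count table, and
`--restraints` on `predict` writes one (res_k, res_l, lower Å, upper Å)
row per hydrogen-bonded residue pair of the rank-1 topology.

## Layout

- `src/betatopo/datamodel.py` — strands, proteins, contacts, topologies, config
- `src/betatopo/fileio.py` — FASTA / DSSP / strand-table readers, topology JSON, restraint TSV
- `src/betatopo/scoring.py` — sliding-register alignment and locality-corrected potentials
- `src/betatopo/milp.py` — the optimization model and ranked-solution loop
- `src/betatopo/checks.py` — cycle detection, two-colorability, full constraint validator
- `src/betatopo/enumeration.py` — motif combinatorics and the brute-force oracle
- `src/betatopo/evaluation.py` — precision / recall / MCC, strand mapping, register accuracy
- `src/betatopo/fixtures.py` — synthetic proteins with planted topologies
- `src/betatopo/cli.py` — `betatopo predict | enumerate | evaluate | fixture`

See `docs/methods.md` for the modeling choices and their rationale.
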