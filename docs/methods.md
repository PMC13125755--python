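# Methods

## Model

`regmis` couples two formalisms. Metabolism is a constraint-based model:
stoichiometric matrix `S` (metabolites × reactions), flux bounds
`lb ≤ v ≤ ub`, steady state `S·v = 0`, and one *target* reaction whose
maximal flux defines the phenotype of interest (biomass, a demand
reaction). Regulation is a signed directed graph over genes. The coupling
point is the Gene–Protein–Reaction (GPR) rule of each reaction, a Boolean
expression over metabolic genes.

### eGPR expansion

Each reaction is analyzed through its own Boolean network. The marker node
carries the GPR; its genes are layer 0. At layer `k` every gene introduced
at layer `k−1` that has regulators receives the update rule

    gene = OR(activators) AND NOT OR(repressors)

with unseen regulators entering as free inputs tagged layer `k`. Regulators
already in the network are wired back, so feedback loops and self-loops are
preserved. Nodes introduced at the final layer are additionally wired when
*all* of their regulators are already present (this closes cycles without
extending the horizon); genes with regulators beyond the horizon remain
free inputs. The combination rule is a deliberate threshold-free
convention, exposed as a strategy so alternative conventions can be
plugged in.

Expansion can make the marker unattainable (e.g. a lone negative
self-loop). After each per-gene wiring, a reachability check asks whether
some attractor leaves the marker attainable; on failure the wiring is
reverted and the gene stays a free input. Genes within a layer are
processed in lexicographic order, so the construction is deterministic.
Two readings of "attainable" are implemented: the default accepts a
minimal trap space in which the marker is not fixed to 0 (unfixed counts
as attainable); `strict_reachability=True` demands a trap space fixing it
to 1. The default is the permissive reading; the strict flag exists
because the two readings genuinely differ on oscillating markers.

### Attractors = minimal trap spaces

A subcube (partial state assignment) is a *trap space* when it is closed
under the dynamics: no fixed node's function can evaluate to the opposite
value inside the subcube. Minimal trap spaces are taken as the attractors;
under permissive update semantics this identification is exact, and it
makes every result independent of update order and checkable by brute
force. Free inputs are modeled as self-referential functions (`f_x = x`);
minimal trap spaces therefore pin them, while a node under pure negative
self-regulation stays unfixed (an oscillation).

The production algorithm characterizes a trap space by its literal set:
the subcube fixing literals `L` is closed iff every literal `x=v` in `L`
is witnessed by a prime implicant of `f_x` (for `v=1`) or `¬f_x` (for
`v=0`) whose literals all lie in `L`. Minimal trap spaces are the maximal
supported consistent literal sets. They are enumerated by a depth-first
search over per-node decisions (0 / 1 / free) with two prunings — a fixed
literal must retain a viable witness, and a node that supports its own
literal is never left free in a maximal set — followed by an exact
maximality filter. Prime implicants come from a small Quine–McCluskey
routine; regulator in-degrees keep supports tiny. Constant update
functions are percolated first; this is exact because a node with constant
update is pinned in every minimal trap space.

An exhaustive oracle (`3^n` subcube scan) accompanies the production
routine and the test suite asserts equality on seeded random corpora
(100 networks at 10 nodes). The same holds for intervention enumeration:
breadth-first search over signed gene subsets by cardinality, skipping
supersets of recorded solutions — exact without any monotonicity
assumption, because every strict subset of a hit was already tested at a
smaller cardinality — versus exhaustive signed-subset enumeration.

### GDict and gMIS enumeration

Per reaction, the minimal intervention rows (`K` knockouts, `N` knock-ins,
size ≤ `kmax`) that silence the marker in *every* minimal trap space are
catalogued. Reactions without a gene association produce no rows (they can
never be blocked genetically); reactions whose marker is unattainable even
unperturbed get an empty row list and a log entry. Rows render as binary
matrices G/F for the optimization stage. Reaction processing is
embarrassingly parallel; the output contract is identity across worker
counts, enforced by canonical ordering.

gMIS enumeration runs a lazy cover-cut loop: a master MILP (HiGHS through
`scipy.optimize.milp`) selects a minimum-cardinality signed intervention
set subject to accumulated cuts; a candidate failing the LP feasibility
check contributes a cover cut (at least one GDict row among the reactions
carrying flux in the witness optimum must be fully selected — valid
because otherwise that flux pattern survives); a succeeding candidate is
greedily trimmed to minimality (blocking *is* monotone in the intervention
set, so single-removal trimming suffices) and excluded by a no-superset
cut. Every cut removes the current selection, so the loop terminates; any
surviving minimal solution stays feasible until found, giving
completeness. Equality with a brute-force signed-subset + LP oracle is
asserted on all fixtures.

## Parameters

| parameter | default | units / meaning |
|---|---|---|
| `layers` | 1 | regulatory expansion depth; 0 = pure GPR (classical gMCS behavior) |
| `kmax` | 3 | max interventions per GDict row; search is exponential in it, and 3 covers typical cut-set lengths |
| `max_size` | 3 | max gMIS cardinality |
| `max_solutions` | 100 | enumeration cap |
| `flux_tol` | 1e-6 | infeasibility threshold on the LP optimum after normalizing by the target's upper bound (scale-free) |
| `expr_high_threshold` | 1.0 | expression units of the input matrix (e.g. TPM); "highly expressed" = strictly above |
| DepMap cutoff | −0.6 | essential iff score ≤ −0.6 (boundary essential) |
| Project Score cutoff | 0 | essential iff score > 0 (boundary non-essential) |

## Screening semantics

A knockout member `g` of a gMIS is called essential in a sample when it is
the unique highly expressed gene among that gMIS's knockouts and every
knock-in member is highly expressed. The call set is *not* monotone in the
expression threshold: raising it relaxes the "other knockouts silent"
clause while tightening the "called gene expressed" clause. The property
the suite verifies is the correct directional one: a call survives a
threshold raise whenever the called gene and the knock-in context still
exceed the higher threshold.

The adaptation check applies each knockout member singly and requires a
minimal trap space in which no other knockout member is fixed on and no
knock-in member fixed off; any failure flags the whole gMIS and its calls
are discarded. The converse reading (perturb knock-ins too) is available
behind `perturb_each_ko=False`. In the command-line pipeline the check
runs on a Boolean network assembled from the regulation internal to the
gMIS gene set.

Evaluation counts confusion classes per sample over the universe of
knockout-member genes present in the screen, excluding missing labels, and
reports per-sample and pooled Matthews correlation with the standard
zero-denominator → 0 convention. The per-sample table is emitted so that
downstream significance modeling (e.g. mixed-effects comparisons across
network configurations) can consume it; such modeling is out of scope
here.

## Synthetic data

The fixture generators define the study conditions:

* **toggle** — one reaction gated by a gene downstream of a two-gene
  mutual-repression switch; the smallest case where cyclic integration
  changes the catalogue (knock-in of the opposing switch gene becomes a
  valid intervention).
* **toy GEM** — two parallel routes to biomass (`g1 and g2` vs `g3`) in
  plain / activator / repressor regulatory variants; 2, 4 and 6 gMISs of
  size ≤ 2 respectively.
* **random Boolean networks** — seeded, up to 10 nodes and in-degree 2
  (in-degree drawn uniformly from 0..max), sized so the `3^n` oracles run
  in seconds; used for oracle-equality corpora.
* **screen fixture** — per sample, each context gene is independently on
  (5.0) or silent (0.0) around a threshold of 1.0; dependency scores are
  −1.0 for genes truly essential under the planted gMIS rule and 0.0
  otherwise, with a seeded fraction `noise` of labels flipped. Two
  deterministic control samples keep the pooled confusion non-degenerate,
  so noise 0 yields pooled MCC exactly 1.0 and noise 1 exactly −1.0.

What these fixtures do **not** emulate: genome-scale topology (thousands
of reactions, nested isozyme/complex GPRs), dosage effects, partial
expression, measurement noise in screens, or identifier mismatches.
Passing tests certify the algorithms' correctness contracts, not
predictive performance on real cell-line data.

## Numerical and design choices

* LP/MILP via HiGHS (`scipy.optimize`); fluxes at fixture scale are exact
  integers, so the `1e-6` normalized tolerance is far from any real
  optimum.
* Ties everywhere broken lexicographically on gene ids; intervention sets
  ordered by (size, knockouts, knock-ins); all serializations use sorted
  keys, so identical configurations give byte-identical artifacts.
* Reversible reactions are handled by negative lower bounds directly; no
  forward/backward splitting.
* Per-gene (not per-layer) rollback on reachability failure, in
  lexicographic order: maximizes retained regulation deterministically.
* Degenerate inputs: empty regulatory network → every layer is a no-op;
  reactions with constant GPR are skipped; an unblockable target yields an
  empty gMIS list, not an error.

## Limitations

* Attractors are minimal trap spaces; update schemes whose attractors are
  not captured by trap spaces (e.g. some synchronous limit cycles) are out
  of scope.
* GDict enumeration is exponential in `kmax`, and the supported-set search
  is worst-case exponential in network size; the intended regime is many
  small per-reaction networks, not one global network.
* Knock-in predictions cannot be validated against current screens (no
  activation assays; single perturbations only) — the evaluation layer
  therefore scores knockout members only.
* Regulatory edge confidence values are ignored; an edge is an edge.
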