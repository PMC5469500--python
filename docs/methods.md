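# Methods

This note documents the models and procedures `ambigem` implements, the
defaults that matter, the numerical choices, and what the synthetic test
fixtures do and do not establish.

## Models and containers

A metabolic model is a stoichiometric matrix *S* (metabolites × reactions)
with per-reaction flux bounds (arbitrary flux units, conventionally
mmol·gDW⁻¹·h⁻¹), gene-protein-reaction (GPR) rules and subsystem labels.
Steady-state fluxes live in the cone *F* = {v : Sv = 0, lb ≤ v ≤ ub}.
Reversibility is defined by the bounds (reversible ⇔ lb < 0); when an SBML
reversibility flag disagrees with the bounds, the bounds win, because they
are what defines the feasible cone.  Infinite bounds are replaced by
±1000 flux units (the conventional COBRA default, configurable), which
also serve as big-M constants in the integer programs.

All integer and linear programs run on SciPy's bundled HiGHS through a
small symbolic layer (`ambigem.optcore`).  Variables are created in model
column order and HiGHS is deterministic on a fixed layout with one thread,
so every solve is reproducible.  Two named parameterizations exist:
`NETWORK_SPEC` (tight feasibility contract, used by the network MILPs) and
`AOS_SPEC` (1 % relative MIP gap, used by the alternative-optima sampler,
where certified optimality of every iterate is unnecessary).

## Expression mapping

Per replicate, gene values are scaled to the replicate maximum, mapped
through the GPR rule, and replicate means are taken as the reaction value
*d*.  GPR evaluation uses the standard enzyme-complex/isoenzyme semantics
— minimum over AND, maximum over OR — with both operators configurable,
since published datasets do not always agree on the aggregation.  Genes
missing from a partially measured rule are dropped from the expression
tree; a rule that is empty or references only unmeasured genes makes the
reaction *data-orphan*.  One value per gene id is required (probe-level
disambiguation is upstream of this package).

## LAD flux fitting

The fit minimizes `wᵀ(ε⁺+ε⁻) + λ‖v‖₁` over split non-negative fluxes,
where ε⁺−ε⁻ = d − |v| on the data-bounded set.  Reversible reactions get
forward/backward columns and one binary x per reaction (x = 1 selects the
backward direction); big-M constraints make the directions mutually
exclusive, so `‖v‖₁` is simply the sum of the split fluxes.  The error
weights *w* default to ones and are configurable per reaction.  λ is
selected on a user grid by maximizing the Pearson correlation between *d*
and |v| on the data-bounded set; a λ whose flux vector is constant there
(e.g. all-zero after full shrinkage) has undefined correlation and is
scored −∞, with ties resolved toward the smallest λ.  With data scaled to
a maximum of 1, λ = 1 shrinks every flux to zero whenever each unit of
fitted flux must traverse more reactions than it has data terms to
improve, which holds for any network path containing at least one
data-orphan step.

## Alternative-optima sampling

Each iteration draws `v_rand` coordinate-wise uniformly inside the FVA box
(FVA uses mass balance and bounds only — no fraction-of-optimum locking),
then solves a MILP for the feasible flux vector closest in ℓ₁ distance to
the draw subject to two face constraints: the weighted data distance and
the ℓ₁ norm both equal their values at the previously computed optimum.
Reversible reactions drawn negative are handled by exchanging the roles of
their forward/backward columns for that iteration (equivalent to negating
the stoichiometric column and the draw), so the draw is always non-negative
in its own frame; the distance splits into a signed forward part and a
non-negative backward part toggled by the same direction binary.  The
published formulation writes the direction selector with one convention in
the direction-exclusivity constraints and the opposite one in the distance
constraints; this implementation uses the single consistent convention
under which the objective measures the actual ℓ₁ distance in every branch.

Two numerical choices matter here.  First, the face constraints are
enforced as two-sided inequalities with slack
`max(feasibility_tol, 1e-7) · max(1, |rhs|)` — strict equalities on solver
floats are brittle, and the previous optimum must always remain feasible
(an infeasible iterate is a hard error, not a retry).  Second, identical
optima returned for different draws are kept: the entropy estimator needs
the empirical distribution over the face, not a set of distinct points.

An important consequence of the ℓ₁-norm face constraint: coordinates vary
across samples only insofar as the network can trade flux between routes
of equal ℓ₁ cost (or flip the sign of a reversible reaction at fixed
magnitude).  On a linear chain the face is a single point even when the
data conflict; genuine variation requires degenerate routes, which the
test fixtures construct explicitly.

The flux-cone sampler provides the no-data baseline: the same uniform
draws are projected onto the cone by minimizing ½‖v − v_rand‖₂², solved as
a QP with SciPy's trust-constr (exact gradient and identity Hessian,
gtol 1e-10); residuals are checked against the feasibility tolerance and a
failed projection is retried once with a fresh draw.

## Entropy and direction statistics

Per reaction, sampled fluxes are binned into n = 20 equal-width intervals
spanning the reaction's sampled min/max, and H = −Σ f ln f is reported in
nats (0·ln 0 = 0; maximum ln 20 ≈ 3.0).  Binning over externally supplied
(e.g. FVA) ranges is a switch; the sampled range is the default because it
makes H a statement about the observed alternative-optima distribution
rather than the whole cone.  Columns whose sampled range is below 1e-6 —
the same threshold used for flux activity and binarization — count as
constant (H = 0): variation at that scale is solver noise (MIP gap and
feasibility slack), not alternative optima.  Group sums over the
data-bounded and data-orphan partition and their mean summarize a whole
integration problem.  The fixed-direction fraction restricts to reversible
reactions whose maximum |v| across the sample reaches 1e-6 and calls a
reaction fixed when all its above-threshold values share one sign; with no
qualifying reaction the fraction is undefined (reported as None), not zero.

## Network extraction and alternative networks

Given core *C* and non-core *P*, the extraction MILP minimizes ‖x‖₁ over
binary selectors x on *P* subject to: mass balance on the split model;
every core reaction active at ε (forward + backward ≥ ε for reversibles);
selected non-core reactions active at ε and unselected ones at zero
(big-M pairs); and one direction per reversible reaction (binary y).
Defaults: ε = 1e-4 — large enough to dominate solver feasibility noise,
small against the ±1000 default bounds — and per-column big-M constants
(the split upper bounds) rather than one global constant, for tighter LP
relaxations.  An optional `‖x‖₁ ≥ Z_lb` relaxes parsimony when a larger
model is wanted.  An infeasible core is diagnosed by FVA: the blocked core
reactions are named in the error.

The dissimilarity MILP maximizes the number of selection mismatches
`Σ(δ⁺+δ⁻)` against an anchor x_opt at conserved cardinality `‖x‖₁ = Z`,
with binary mismatch indicators satisfying x + δ⁺ − δ⁻ = x_opt and
δ⁺ + δ⁻ ≤ 1.  For four-way confidence classifications (core HC plus
MC/NC/OT non-core groups) the cardinality is conserved per group, so an
alternative network keeps the same number of medium-confidence,
negative-confidence and unannotated additions as the anchor.  Because many
networks can tie at the maximal mismatch count and a deterministic solver
would always return the same one, the iterated search adds a seeded jitter
below 1e-4 to each mismatch coefficient; the total jitter is below one
unit, so the attained mismatch count is provably unchanged while the
returned maximizer varies across iterations.

The enumeration procedure feeds each newly found network back as the next
anchor; on stagnation — a duplicate or a zero-mismatch result — it flips
the state of ⌈0.01·|P|⌉ (at least one) uniformly chosen non-core entries
of the last network and continues, stopping after `max_iter` total steps
or stagnations.  Perturbed vectors serve only as anchors and are never
stored, so every returned network is feasible and the ensemble is
duplicate-free (binary equality after rounding at the integrality
tolerance).  The procedure does not guarantee exhaustive enumeration; on
fixtures small enough for brute force it recovers the full optimal set
(see the test suite), which is evidence, not proof, for larger models.
Externally reconstructed networks are converted to anchors by fixing x to
their inclusion vector and solving the same constraint system; failures
are diagnosed by FVA on the induced submodel.

## Ensemble statistics and tasks

Flux vectors are binarized at |v| ≥ 1e-6 (duplicates dropped when building
network sets).  Pairwise Hamming distances are summarized by maximum (also
as % of |P|), mean, and coefficient of variation; two ensembles'
distance distributions are compared with a one-sided rank-sum test.
Non-core reactions are classified by inclusion frequency into active
(always), inactive (never) and variable (sometimes) sets.  Pathway scores
are emitted under both normalizations — group count over the total
non-core size, and over the pathway's own non-core size — because the two
answer different questions (global share of ambiguity vs. within-pathway
consistency) and published usage is ambiguous between them; unlabeled
reactions are grouped under "unassigned".

A metabolic task asks whether the network can drive a product exchange at
a required minimum flux given stated uptake bounds.  The harness closes
the uptake direction of every exchange (secretion stays open), opens the
task's uptakes, and maximizes the product exchange by LP; a task passes
when the maximum reaches the required flux.  Ensemble filtering keeps
networks passing every task; since it only removes networks, it can only
shrink the variable non-core set.  Task suites are user-supplied
YAML/JSON; small demonstration suites are generated in the tests rather
than shipping any published task collection.

## Synthetic fixtures and oracles

The fixture generator builds consistent-by-construction models: chains,
parallel-path toys, a three-reaction toy with a data-orphan boundary
reaction, and random topologies composed of a backbone chain plus
branch pairs and duplicated parallel steps, with a seeded fraction of
reactions made reversible.  Expression values are uniform on [0.05, 1]
over a seeded subset of reactions (single-gene GPRs), and the core is the
top fraction of reactions by data value.  Defaults (12–30 reactions, 50 %
data coverage, 30 % core fraction, 15–25 % reversible) are chosen so that
data-bounded and orphan sets, and core and non-core sets, are all
non-trivial at sizes where exhaustive enumeration is possible.

Two brute-force oracles validate the MILP machinery through independent
code paths (plain `scipy.optimize.linprog`, no shared constraint builder):
subset enumeration over *P* with per-pattern direction LPs for the minimal
consistent subnetwork and all its optima (capped at |P| ≤ 14), and
direction-pattern enumeration for the exact per-reaction flux span of the
fitted optimum face.  Oracles receive the same ε and tolerances as the
system under test, so threshold mismatches cannot fake disagreements.

What the fixtures do not emulate: genome-scale dimensions, realistic
pathway structure, thermodynamic or exchange-medium constraints, and
noisy many-gene GPRs.  Passing tests therefore establish correctness of
the optimization machinery and the statistics, not biological validity of
any particular reconstruction.

## Problem sizes in the shipped analyses

The acceptance script runs the full workflow on a 30-reaction random
model with 150 alternative-optima samples per λ and 150 cone samples, and
enumerates alternative networks for up to 30 iterations; the test suite
uses 10–14-reaction fixtures with 200-sample runs where spans are checked
against the exhaustive oracle.  These sizes keep every quantity
recomputable from scratch in seconds while leaving all sets (data-bounded
vs orphan, core vs non-core, fixed vs variable) populated.

## Known limitations

* One solver backend (HiGHS via SciPy); the solver-layer contract is
  written so another backend could be added, but interchangeability is
  untested.  The HiGHS MILP interface does not expose a primal
  feasibility tolerance, so the tight feasibility contract is enforced
  through the package's own slack construction and post-checks rather
  than a solver parameter.
* Alternative-network enumeration is heuristic (anchored dissimilarity
  search with random restarts); completeness is verified only on
  brute-forceable fixtures.
* The cone sampler's QP projection uses a general-purpose NLP method,
  adequate for the model sizes above but not tuned for genome-scale
  models.
* The per-draw frame flip assumes bounds are symmetric in sign handling
  (a reversible reaction with ub < 0 is clamped to a zero-width forward
  column).
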