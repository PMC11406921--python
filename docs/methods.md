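# Methods

## Scope and model

`crossfeed` operates on stoichiometric models: a metabolite set, a
reaction set with flux bounds (mmol·gDW⁻¹·h⁻¹ by convention), and a
linear biomass objective. It consumes finished models (SBML L3 + fbc, or
a tabular fixture dialect) and does not attempt reconstruction, gap
filling, mass/charge rebalancing, or GPR evaluation. Sign conventions
are the community standard: negative stoichiometric coefficients
consume; an exchange reaction is written `M → ∅` so negative flux is
uptake.

All solving assumes steady state (`S·v = 0`). This is the central
modeling assumption and the main caveat: predictions are time-invariant
flux patterns, not dynamics; transient or regulatory effects (and any
extra metabolic burden of, say, biofilm formation) are outside the model.

## Community construction

Two two-compartment species models are merged around a shared
extracellular compartment `e`, giving five compartments: `r`/`t`
(cytoplasm/extracellular of species A) and `z`/`s` (species B) plus `e`.
Choices made here, and why:

* **Transfer reactions inherit the source exchange bounds** instead of
  being opened to ±1000, so curated uptake limits in the input models
  survive the merge.
* **Community exchanges start closed to uptake** (bounds `(0, +1000)`):
  nothing enters the system unless the medium grants it via
  `apply_medium`, which sets each listed metabolite's lower bound to
  `-max_uptake` and closes all others. Uptake magnitudes must be
  non-negative by contract.
* **Community objective = unweighted sum of the two biomass reactions**
  (weights configurable via `set_community_objective`), mirroring an
  equal-inoculum coculture. A fixed biomass-ratio constraint was
  considered and deliberately left out of the default: it changes the
  LP class of questions being asked and none of the package's guarantees
  depend on it; the weighted-sum knob covers the asymmetric cases.
* **Topologies with more than two compartments per species are
  rejected**, not guessed at. The extracellular compartment is inferred
  as the one whose metabolites sit on exchange reactions.
* Species tags are carried on reactions, and reaction ids are prefixed
  with the tag at tagging time, which makes merging a model with itself
  (under different tags) well-defined and makes provenance
  (community reaction → source model/reaction) total over all
  non-community-exchange reactions.
* Community models serialize as SBML plus a sidecar
  `<name>.meta.json` holding what SBML cannot express (tags, provenance,
  transfer/exchange maps); reloading without the sidecar is an error
  rather than a silent re-inference.

On read, a reaction is classified as an exchange when it touches exactly
one metabolite and either follows the `EX_`/`DM_`/`SK_` naming
convention or drains compartment `e`; a single-metabolite *internal*
drain (a toy biomass) is therefore not an exchange. SBML files that are
not L3+fbc are reported via a warning and read with default bounds
(±1000, lower 0 for irreversible reactions), never silently coerced.

## Solving

FBA, pFBA and FVA are LPs solved with scipy's HiGHS backend
(deterministic, single-threaded). pFBA is the standard linearization:
every reaction is split into non-negative forward/backward halves and
`Σ(v⁺+v⁻)` is minimized subject to the growth objective held at
`opt_fraction` × optimum. Numerical choices:

* `feas_tol = 1e-9` (primal/dual tolerance passed to HiGHS, and the
  slack allowed on the held-objective constraint). The steady-state
  residual `max|S·v|` of every optimal solution is held to 1e-9 in the
  test suite.
* `opt_fraction = 1.0` by default — exactness plus an explicit
  tolerance, rather than a hidden 0.999; the knob is exposed everywhere
  and recorded in every output header.
* `zero_cut = 1e-6`: fluxes below this magnitude are reported as 0 in
  downstream tables and an exchange must exceed it to be called;
  suppresses solver noise without touching the raw solution object.
* Infeasibility and unboundedness are reported as statuses, never as
  silent zeros.

Degeneracy policy: pFBA returns one of possibly many optima, so
exchange calls carry a `robust` flag computed by FVA at `opt_fraction`
on the two transfer reactions — robust means the optimal face admits no
solution where either transfer drops to zero or flips sign. Degeneracy
is surfaced, not hidden by solver-seed juggling.

## Exchange calls

For each shared metabolite, the donor is the species whose transfer flux
into `e` exceeds `zero_cut` and the receiver the one pulling it out. The
reported flux is `min(secretion, uptake)`: the `e`-row of `S·v = 0`
guarantees these agree up to the community-exchange term, and the
minimum is the amount that actually moved between species rather than
leaking to the environment. Bidirectional exchange of one metabolite
would yield two records (one per direction), and the category summary
reports both the unique-metabolite and the directed-transfer tallies,
since either could be the quantity of interest. Calls are made from a
single pFBA solution under a single medium; unioning over media is left
to the caller by re-running with different medium files.

Metabolite categories (cofactor, amino_acid, nucleotide, carbohydrate,
lipid, other) come from a curated annotation TSV, never inferred from
names; uncovered metabolites fall into `other` and are logged.

## Phenotype validation

For each candidate sole carbon source, only that source's exchange is
opened (`-uptake_bound`, default 10) on a carbon-free base medium and
growth is called when the FBA optimum exceeds `growth_threshold`
(default 1e-6). Both knobs are recorded in output headers, because
accuracy against a plate is threshold-sensitive. A base medium that
already supports growth is rejected outright (it would make every call
positive). Sources with no matching exchange are excluded from scoring
and logged, as are sources present on only one side of the comparison;
accuracy is `(TP+TN)/n` over the scored intersection. The shipped
Biolog PM1 well→metabolite mapping is an editable TSV, not a hard-coded
truth.

## Synthetic scenarios: what they emulate, and what a green test means

The generator builds the *pattern* the pipeline must detect, not real
chemistry: a degrader (A) that consumes the primary substrate, secretes
a byproduct, and is auxotrophic for a compound only the helper (B) can
make from that byproduct. Styles: `cofactor` (B returns a trace
cofactor), `amino_acid` (B returns a bulk amino acid), `bidirectional`
(trace cofactor one way, bulk amino acid the other, the amino acid made
jointly with the catabolic step so no allocation degeneracy is
introduced). Trace-vs-bulk separation is encoded in biomass
coefficients: the cofactor coefficient is `trace/bulk` (default
0.01/10 = 0.001), so cofactor exchange fluxes come out ~1000× below
amino-acid fluxes — the qualitative pattern by which cofactor exchange
is small yet obligate. The substrate uptake bound is drawn per seed in
`bulk × U(0.5, 1.5)`; everything else is fixed, and identical seeds give
byte-identical scenarios. Obligate invariants (alone: optimum 0;
together: optimum > 0) are asserted at generation time.

These fixtures have realistic *interfaces* (compartment suffixes,
exchange conventions, SBML round-trips) but toy *topology*: linear
pathways, unit yields, no cycles, no redundancy beyond what a test
constructs. A green truth-recovery test therefore establishes that the
pipeline's bookkeeping and LP machinery are correct on networks where
the answer is known — not that predictions on a genome-scale model are
biologically right, which additionally depends on that model's curation
and medium.

Phenotype truth tables are generated from a model's own growth calls
with each call independently flipped at a known rate, so scoring
calibration (accuracy ≈ 1 − flip rate) is checkable exactly.

## Verification

* FBA is checked against an independent brute-force vertex-enumeration
  oracle on 50 random small LPs (all bounds finite, so the optimum is
  attained at an enumerable vertex), and pFBA's total |flux| is checked
  to be ≤ that of every enumerated optimal vertex.
* An independent constraint-based implementation (cobrapy) is used as a
  cross-check oracle on fixture models — agreement of FBA optima and
  pFBA totals — never as the solver.
* Designed cross-feeding truth is recovered, with no spurious robust
  records, across 20 seeds × 3 styles.

## Known limitations

* Exactly two species; no N-species communities or biomass-ratio
  dynamics over time.
* LP only: no MILP variants, quadratic pFBA, or thermodynamic
  constraints.
* Exchange classification of deposited genome-scale models depends on
  their exchange-naming conventions matching the `EX_`/`DM_`/`SK_`
  heuristic (or an `e` compartment); unusual conventions would need the
  flags set on the in-memory model.
* The vertex-enumeration oracle is exponential and only valid for the
  small, fully-bounded fixtures it is applied to.
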