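# crossfeed

Constraint-based modeling of two-species microbial consortia: merge two
single-species genome-scale metabolic models (GEMs) into a five-compartment
community model, predict which metabolites the species exchange using
parsimonious flux balance analysis (pFBA), classify the exchanged
metabolites (cofactors, amino acids, ...), and validate single-species
models against phenotype-array growth data.

It is aimed at microbiologists and modelers studying cross-feeding in
synthetic consortia — e.g. a pollutant degrader paired with a helper
species that relieves its stress by returning trace cofactors — who want
the exchange-prediction step of that workflow as a reproducible, tested
pipeline rather than a notebook.

## The model

A stoichiometric model is a matrix `S` (metabolites × reactions), flux
bounds `lb ≤ v ≤ ub`, and a biomass objective `c`. Flux balance analysis
(FBA) solves

```
max  cᵀv   s.t.  S·v = 0,   lb ≤ v ≤ ub
```

Parsimonious FBA then fixes the achieved growth and minimizes total
enzyme commitment `Σ|v|` over the optimal face (linearized by splitting
reversible reactions), selecting a biologically parsimonious flux
distribution. Flux variability analysis (FVA) reports each reaction's
attainable flux range over that face, making degenerate alternative
optima explicit.

For a two-species community, each species keeps its own cytoplasm and
extracellular space (compartments `r`/`t` for species A, `z`/`s` for
species B) and both border a shared extracellular space `e`. Every
original exchange reaction `M_t → ∅` becomes a transfer `M_t ↔ M_e`; each
shared metabolite gets one community exchange `M_e → ∅` whose uptake
bound is set by the growth medium. A metabolite is called *exchanged*
when one species' transfer pushes it into `e` while the other pulls it
out in the same pFBA solution; the transferred flux is
`min(secretion, uptake)`, and an FVA-based `robust` flag marks calls that
survive solution degeneracy.

Phenotype validation mimics a Biolog PM1 plate: for each sole carbon
source, open only that exchange on a carbon-free base medium, call growth
if the FBA optimum clears a threshold, and score the calls against the
observed plate as TP/FP/TN/FN with accuracy `(TP+TN)/n`.

Because real deposited GEMs are large downloads, the package ships a
synthetic generator (`crossfeed.synthetic`) that builds small models with
*designed* auxotrophies — obligate cross-feeding pairs whose true
exchanges are known by construction — so every stage of the pipeline is
testable offline.

## Worked example

Generate an obligate cross-feeding scenario in which species A degrades
the primary substrate and feeds B its byproduct plus a bulk amino acid,
while B returns a trace cofactor A cannot synthesize:

```
$ crossfeed --seed 1 generate --style bidirectional -o demo
bidirectional scenario (seed 1) written to demo

$ crossfeed build-community demo/species_a.xml demo/species_b.xml -o community.xml
community written to community.xml: 20 metabolites, 22 reactions, compartments ['e', 'r', 's', 't', 'z']

$ crossfeed exchanges community.xml --medium demo/medium.yaml \
    --annotation demo/categories.tsv -o reports
objective 20.236; 3 exchanged metabolites (3 directed transfers); reports in reports

$ cat reports/exchanges.tsv
# crossfeed 0.1.0 seed=0
# solver: feas_tol=1e-09 opt_fraction=1 zero_cut=1e-06
metabolite_base_id  name               donor  receiver  flux      category      robust
ala                 bulk amino acid    A      B         10.118    amino_acid    true
byp                 secreted byproduct A      B         10.118    carbohydrate  true
cof                 trace cofactor     B      A         0.010118  cofactor      true
```

Reading the output: the community grows at a combined rate of 20.236
(both species at ~10.118, i.e. the substrate uptake bound drawn for seed
1); the bulk amino-acid and byproduct exchanges carry three orders of
magnitude more flux than the trace cofactor exchange — the designed
trace/bulk separation — and all three calls are `robust`, meaning FVA
confirms no alternative optimum removes them. Alone on the same medium,
either species' growth is exactly 0 (`crossfeed solve demo/species_a.xml
--medium demo/medium.yaml`): the cross-feeding is obligate.

Single-species models can be validated against a phenotype truth table
with `crossfeed validate-phenotypes MODEL --truth truth.tsv -o cmp.tsv`,
which prints the confusion tallies and accuracy. An editable Biolog
PM1 well→metabolite mapping and an example DEHP minimal-salt medium ship
under `src/crossfeed/data/`.

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline's core computation from
scratch: for each scenario style it generates an obligate pair, builds
and solves the five-compartment community by pFBA, extracts and
classifies the interspecies exchanges, checks the designed truth is
recovered, and runs the phenotype-scoring calibration (accuracy vs a
truth table flipped at a known rate). Run it as

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Progress is logged to stderr; the JSON result object is written to
`--out`.
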