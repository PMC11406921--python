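"""Toy-model generators with built-in ground truth.

These stand in for deposited genome-scale models so the whole pipeline —
tagging, merging, pFBA, exchange calling, phenotype scoring — can be
exercised with known answers.  The cross-feeding scenarios encode the
biological pattern the pipeline is built to detect: a degrader species
that consumes the primary substrate but is auxotrophic for a trace
cofactor-like compound, and a helper species that synthesizes that
compound from the degrader's secreted byproduct.  Trace-vs-bulk flux
separation is encoded in biomass stoichiometric coefficients (a cofactor
coefficient of trace/bulk versus 1 for an amino-acid-like requirement),
which is why cofactor exchange fluxes come out orders of magnitude below
amino-acid exchange fluxes.

Generated ids follow the same compartment-suffix convention as real
models, so fixtures exercise identical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .community import apply_medium, apply_medium_to_model, merge_community, tag_model
from .core import Metabolite, Reaction, StoichiometricModel
from .phenotype import simulate_carbon_sources
from .solver import SolverConfig, fba

__all__ = [
    "CrossFeedScenario",
    "make_core_model",
    "make_crossfeeding_pair",
    "make_phenotype_truth",
    "make_multi_source_model",
    "make_random_lp_fixture",
    "STYLES",
]

STYLES = ("cofactor", "amino_acid", "bidirectional")


@dataclass
class CrossFeedScenario:
    """A generated two-species scenario with designed ground truth.

    ``truth_exchanges`` lists every designed interspecies transfer as
    (metabolite base id, donor tag, receiver tag); ``categories`` is the
    matching curated annotation table.  Invariants (each species alone
    cannot grow on the shared medium, the community can) are asserted at
    generation time.
    """

    model_a: StoichiometricModel
    model_b: StoichiometricModel
    shared_medium: Dict[str, float]
    truth_exchanges: List[Tuple[str, str, str]]
    seed: int
    style: str = "cofactor"
    categories: Dict[str, str] = field(default_factory=dict)
    tag_a: str = "A"
    tag_b: str = "B"


def make_core_model(
    n_intermediates: int, seed: int = 0, uptake: float = 10.0
) -> StoichiometricModel:
    """A linear substrate-to-biomass chain with unit yield.

    Layout: substrate exchange (uptake bound), transport into the cytosol,
    ``n_intermediates`` conversion steps, biomass drain.  The FBA optimum
    equals the uptake bound; every reaction carries that same flux, so the
    pFBA total is ``uptake * (n_intermediates + 3)``.
    """
    if n_intermediates < 1:
        raise ValueError("n_intermediates must be >= 1")
    mets = [
        Metabolite(id="sub_e", compartment="e", name="primary substrate"),
        Metabolite(id="sub_c", compartment="c", name="primary substrate"),
    ]
    rxns = [
        Reaction(id="EX_sub", stoichiometry={"sub_e": -1.0},
                 lower_bound=-uptake, upper_bound=1000.0, is_exchange=True),
        Reaction(id="T_sub", stoichiometry={"sub_e": -1.0, "sub_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
    ]
    prev = "sub_c"
    for i in range(1, n_intermediates + 1):
        mid = f"int{i}_c"
        mets.append(Metabolite(id=mid, compartment="c", name=f"intermediate {i}"))
        rxns.append(Reaction(id=f"C{i}", stoichiometry={prev: -1.0, mid: 1.0},
                             lower_bound=0.0, upper_bound=1000.0))
        prev = mid
    rxns.append(Reaction(id="BIOMASS", stoichiometry={prev: -1.0},
                         lower_bound=0.0, upper_bound=1000.0))
    model = StoichiometricModel(
        id=f"core_n{n_intermediates}_s{seed}", metabolites=mets, reactions=rxns,
        objective={"BIOMASS": 1.0},
    )
    model.validate()
    return model


def _species_a(style: str, trace_coef: float) -> StoichiometricModel:
    """Degrader: eats the substrate, secretes a byproduct, needs help to grow."""
    mets = [
        Metabolite("sub_e", "e", "primary substrate", category="other"),
        Metabolite("sub_c", "c", "primary substrate", category="other"),
        Metabolite("prec_c", "c", "biomass precursor", category="other"),
        Metabolite("byp_c", "c", "secreted byproduct", category="carbohydrate"),
        Metabolite("byp_e", "e", "secreted byproduct", category="carbohydrate"),
    ]
    rxns = [
        Reaction("EX_sub", {"sub_e": -1.0}, -10.0, 1000.0, is_exchange=True),
        Reaction("T_sub", {"sub_e": -1.0, "sub_c": 1.0}, 0.0, 1000.0),
        Reaction("CAT", {"sub_c": -1.0, "prec_c": 1.0, "byp_c": 1.0}, 0.0, 1000.0),
        Reaction("T_byp", {"byp_c": -1.0, "byp_e": 1.0}, 0.0, 1000.0),
        Reaction("EX_byp", {"byp_e": -1.0}, 0.0, 1000.0, is_exchange=True),
    ]
    biomass: Dict[str, float] = {"prec_c": -1.0}
    if style in ("cofactor", "bidirectional"):
        mets += [
            Metabolite("cof_c", "c", "trace cofactor", category="cofactor"),
            Metabolite("cof_e", "e", "trace cofactor", category="cofactor"),
        ]
        rxns += [
            Reaction("T_cof", {"cof_e": -1.0, "cof_c": 1.0}, 0.0, 1000.0),
            Reaction("EX_cof", {"cof_e": -1.0}, -1000.0, 1000.0, is_exchange=True),
        ]
        biomass["cof_c"] = -trace_coef
    if style == "amino_acid":
        mets += [
            Metabolite("ala_c", "c", "bulk amino acid", category="amino_acid"),
            Metabolite("ala_e", "e", "bulk amino acid", category="amino_acid"),
        ]
        rxns += [
            Reaction("T_ala", {"ala_e": -1.0, "ala_c": 1.0}, 0.0, 1000.0),
            Reaction("EX_ala", {"ala_e": -1.0}, -1000.0, 1000.0, is_exchange=True),
        ]
        biomass["ala_c"] = -1.0
    if style == "bidirectional":
        # the degrader pays the helper back in a bulk amino-acid-like compound,
        # made jointly with the catabolic step so there is no allocation tradeoff
        mets += [
            Metabolite("ala_c", "c", "bulk amino acid", category="amino_acid"),
            Metabolite("ala_e", "e", "bulk amino acid", category="amino_acid"),
        ]
        rxns[2] = Reaction(
            "CAT", {"sub_c": -1.0, "prec_c": 1.0, "byp_c": 1.0, "ala_c": 1.0},
            0.0, 1000.0,
        )
        rxns += [
            Reaction("T_ala", {"ala_c": -1.0, "ala_e": 1.0}, 0.0, 1000.0),
            Reaction("EX_ala", {"ala_e": -1.0}, 0.0, 1000.0, is_exchange=True),
        ]
    rxns.append(Reaction("BIOMASS_A", biomass, 0.0, 1000.0))
    model = StoichiometricModel("species_a", mets, rxns, {"BIOMASS_A": 1.0})
    model.validate()
    return model


def _species_b(style: str) -> StoichiometricModel:
    """Helper: grows on the degrader's byproduct, returns the needed compound."""
    mets = [
        Metabolite("byp_e", "e", "secreted byproduct", category="carbohydrate"),
        Metabolite("byp_c", "c", "secreted byproduct", category="carbohydrate"),
        Metabolite("qint_c", "c", "helper precursor", category="other"),
    ]
    rxns = [
        Reaction("EX_byp", {"byp_e": -1.0}, -1000.0, 1000.0, is_exchange=True),
        Reaction("T_byp", {"byp_e": -1.0, "byp_c": 1.0}, 0.0, 1000.0),
    ]
    conv: Dict[str, float] = {"byp_c": -1.0, "qint_c": 1.0}
    biomass: Dict[str, float] = {"qint_c": -1.0}
    if style in ("cofactor", "bidirectional"):
        mets += [
            Metabolite("cof_c", "c", "trace cofactor", category="cofactor"),
            Metabolite("cof_e", "e", "trace cofactor", category="cofactor"),
        ]
        conv["cof_c"] = 1.0
        rxns += [
            Reaction("T_cof", {"cof_c": -1.0, "cof_e": 1.0}, 0.0, 1000.0),
            Reaction("EX_cof", {"cof_e": -1.0}, 0.0, 1000.0, is_exchange=True),
        ]
    if style == "amino_acid":
        mets += [
            Metabolite("ala_c", "c", "bulk amino acid", category="amino_acid"),
            Metabolite("ala_e", "e", "bulk amino acid", category="amino_acid"),
        ]
        conv["ala_c"] = 1.0
        rxns += [
            Reaction("T_ala", {"ala_c": -1.0, "ala_e": 1.0}, 0.0, 1000.0),
            Reaction("EX_ala", {"ala_e": -1.0}, 0.0, 1000.0, is_exchange=True),
        ]
    if style == "bidirectional":
        mets += [
            Metabolite("ala_c", "c", "bulk amino acid", category="amino_acid"),
            Metabolite("ala_e", "e", "bulk amino acid", category="amino_acid"),
        ]
        rxns += [
            Reaction("T_ala", {"ala_e": -1.0, "ala_c": 1.0}, 0.0, 1000.0),
            Reaction("EX_ala", {"ala_e": -1.0}, -1000.0, 1000.0, is_exchange=True),
        ]
        biomass["ala_c"] = -1.0
    rxns.append(Reaction("CONV", conv, 0.0, 1000.0))
    rxns.append(Reaction("BIOMASS_B", biomass, 0.0, 1000.0))
    model = StoichiometricModel("species_b", mets, rxns, {"BIOMASS_B": 1.0})
    model.validate()
    return model


def make_crossfeeding_pair(
    style: str = "cofactor",
    flux_scale: Tuple[float, float] = (10.0, 0.01),
    seed: int = 0,
    check: bool = True,
) -> CrossFeedScenario:
    """Generate an obligate cross-feeding pair with known exchanged metabolites.

    ``flux_scale = (bulk, trace)``: the substrate uptake bound is drawn
    near ``bulk`` and the cofactor biomass coefficient is ``trace/bulk``,
    so designed cofactor exchange fluxes sit ~bulk/trace below amino-acid
    ones.  Styles:

    * ``cofactor``       -- helper returns a trace cofactor,
    * ``amino_acid``     -- helper returns a bulk amino acid,
    * ``bidirectional``  -- trace cofactor one way, bulk amino acid the other.

    The obligate invariants (alone: optimum 0; together: optimum > 0) are
    asserted at generation time unless ``check=False``.
    """
    if style not in STYLES:
        raise ValueError(f"style must be one of {STYLES}, got {style!r}")
    bulk, trace = flux_scale
    if not bulk > trace > 0:
        raise ValueError("flux_scale requires bulk > trace > 0")
    rng = np.random.default_rng(seed)
    uptake = float(np.round(bulk * rng.uniform(0.5, 1.5), 3))
    trace_coef = trace / bulk

    model_a = _species_a(style, trace_coef)
    model_a.reaction("EX_sub").lower_bound = -uptake
    model_b = _species_b(style)

    medium = {"sub": uptake}
    truth: List[Tuple[str, str, str]] = [("byp", "A", "B")]
    if style in ("cofactor", "bidirectional"):
        truth.append(("cof", "B", "A"))
    if style in ("amino_acid",):
        truth.append(("ala", "B", "A"))
    if style == "bidirectional":
        truth.append(("ala", "A", "B"))

    categories = {"byp": "carbohydrate", "cof": "cofactor",
                  "ala": "amino_acid", "sub": "other"}
    scenario = CrossFeedScenario(
        model_a=model_a, model_b=model_b, shared_medium=medium,
        truth_exchanges=truth, seed=seed, style=style, categories=categories,
    )

    if check:
        cfg = SolverConfig()
        for m in (model_a, model_b):
            alone = fba(apply_medium_to_model(m, medium), cfg)
            assert alone.optimal and abs(alone.objective_value) <= 1e-6, (
                f"{m.id} must not grow alone (got {alone.objective_value})"
            )
        community = apply_medium(
            merge_community(
                tag_model(model_a, scenario.tag_a, "r", "t"),
                tag_model(model_b, scenario.tag_b, "z", "s"),
            ),
            medium,
        )
        together = fba(community.base, cfg)
        assert together.optimal and together.objective_value > 1e-3, (
            f"community must grow (got {together.status}, "
            f"{together.objective_value})"
        )
    return scenario


def make_phenotype_truth(
    model: StoichiometricModel,
    sources: Sequence[str],
    flip_rate: float = 0.0,
    seed: int = 0,
    base_medium: Optional[Dict[str, float]] = None,
    uptake_bound: float = 10.0,
    growth_threshold: float = 1e-6,
) -> Dict[str, bool]:
    """Synthetic phenotype-array truth: the model's own calls, noisily flipped.

    Each in-silico growth call is independently flipped with probability
    ``flip_rate`` (0 <= flip_rate < 0.5), emulating plate/model
    disagreement at a known rate.
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    predictions = simulate_carbon_sources(
        model, sources, base_medium or {}, uptake_bound=uptake_bound,
        growth_threshold=growth_threshold,
    )
    rng = np.random.default_rng(seed)
    truth: Dict[str, bool] = {}
    for source in predictions:  # insertion order: deterministic
        flip = bool(rng.random() < flip_rate)
        truth[source] = (not predictions[source]) if flip else predictions[source]
    return truth


def make_multi_source_model(
    n_sources: int, grow_fraction: float = 0.5, seed: int = 0
) -> StoichiometricModel:
    """A model offering many candidate carbon sources, a known subset usable.

    Each source has an exchange and a transporter; only a random
    ``grow_fraction`` of sources connect onward to biomass, so the true
    growth call per source is known by construction.
    """
    rng = np.random.default_rng(seed)
    growers = rng.random(n_sources) < grow_fraction
    mets = [Metabolite("bm_c", "c", "biomass precursor")]
    rxns = [Reaction("BIOMASS", {"bm_c": -1.0}, 0.0, 1000.0)]
    for i in range(n_sources):
        sid = f"c{i:03d}"
        mets += [
            Metabolite(f"{sid}_e", "e", f"carbon source {i}"),
            Metabolite(f"{sid}_c", "c", f"carbon source {i}"),
        ]
        rxns += [
            Reaction(f"EX_{sid}", {f"{sid}_e": -1.0}, 0.0, 1000.0, is_exchange=True),
            Reaction(f"T_{sid}", {f"{sid}_e": -1.0, f"{sid}_c": 1.0}, 0.0, 1000.0),
        ]
        if growers[i]:
            rxns.append(
                Reaction(f"USE_{sid}", {f"{sid}_c": -1.0, "bm_c": 1.0}, 0.0, 1000.0)
            )
    model = StoichiometricModel(
        id=f"multisource_n{n_sources}_s{seed}", metabolites=mets, reactions=rxns,
        objective={"BIOMASS": 1.0},
    )
    model.validate()
    return model


def make_random_lp_fixture(seed: int, max_reactions: int = 8) -> StoichiometricModel:
    """A small random flux network for brute-force LP oracle comparisons.

    Bounds always straddle zero so v=0 is feasible and the polytope is
    bounded: the LP optimum is then attained at an enumerable vertex.
    """
    rng = np.random.default_rng(seed)
    n_r = int(rng.integers(3, max_reactions + 1))
    n_m = int(rng.integers(2, max(3, n_r)))
    mets = [Metabolite(f"m{i}_c", "c") for i in range(n_m)]
    rxns: List[Reaction] = []
    for j in range(n_r):
        k = int(rng.integers(1, min(3, n_m) + 1))
        rows = rng.choice(n_m, size=k, replace=False)
        coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
        stoich = {f"m{int(i)}_c": float(c) for i, c in zip(rows, coefs)}
        lb = float(rng.choice([-10.0, -5.0, 0.0]))
        ub = float(rng.choice([0.0, 5.0, 10.0]))
        rxns.append(Reaction(f"r{j}", stoich, lb, ub))
    n_obj = int(rng.integers(1, 3))
    objective = {
        f"r{int(j)}": float(rng.choice([1.0, 2.0]))
        for j in rng.choice(n_r, size=n_obj, replace=False)
    }
    model = StoichiometricModel(f"random_s{seed}", mets, rxns, objective)
    model.validate()
    return model
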