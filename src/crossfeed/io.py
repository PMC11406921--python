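"""Readers and writers: SBML L3+fbc, a tabular fixture dialect, media, annotations.

SBML is the interchange format genome-scale models are deposited in; the
tabular dialect is a human-writable TSV used for fixtures and small
models.  Both produce identical in-memory semantics.

Tabular dialect (UTF-8 TSV)::

    #METABOLITES
    <id>  [<name>]  [<formula>]  [<category>]
    #REACTIONS
    <id>  <equation>  [<lb>  <ub>]
    #OBJECTIVE
    <reaction id>  <weight>

Equations use ``->`` (irreversible, default bounds 0..1000) or ``<=>``
(reversible, default -1000..1000); an empty side marks an exchange
reaction, e.g. ``S_e <=>``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import libsbml
import yaml

from .core import (
    CATEGORIES,
    DEFAULT_BOUND,
    Metabolite,
    Reaction,
    StoichiometricModel,
    ValidationError,
)

__all__ = [
    "ParseError",
    "ModelFormatWarning",
    "read_sbml",
    "write_sbml",
    "read_tabular",
    "write_tabular",
    "write_community",
    "read_community",
    "load_medium",
    "load_categories",
    "apply_categories",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Input file could not be parsed; message names the offending line."""


class ModelFormatWarning(UserWarning):
    """The SBML file deviates from the targeted L3+fbc flavor."""


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

#: Reaction-id tokens marking boundary reactions (exchange/demand/sink).
_BOUNDARY_TOKENS = ("EX_", "DM_", "SK_")


def infer_exchange(rxn_id: str, n_mets: int, compartment: str) -> bool:
    """Heuristic for boundary reactions on read.

    A reaction is an exchange when it touches exactly one metabolite and
    either follows the EX_/DM_/SK_ naming convention or drains the shared
    extracellular compartment ``e``.  Single-metabolite *internal* drains
    (e.g. a toy biomass ``B_c -> ∅``) are deliberately not classified as
    exchanges.
    """
    if n_mets != 1:
        return False
    if any(tok in rxn_id for tok in _BOUNDARY_TOKENS):
        return True
    return compartment == "e"


def _compartment_from_id(met_id: str, declared: str) -> str:
    """The id suffix is authoritative; fall back to the declared compartment."""
    if "_" in met_id:
        tail = met_id.rsplit("_", 1)[1]
        if tail == declared or (declared == "" and tail):
            return tail
    return declared or met_id.rsplit("_", 1)[-1]


def read_sbml(path: PathLike) -> StoichiometricModel:
    """Read an SBML Level 3 (+fbc) model.

    Flux bounds default to ±1000 when the file omits them (0 lower bound
    for reactions flagged irreversible).  Files that are not L3+fbc are
    reported via :class:`ModelFormatWarning`, never silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        fatal = []
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                fatal.append(f"line {err.getLine()}: {err.getMessage().strip()}")
        if fatal:
            raise ParseError(f"malformed SBML in {path.name}: " + "; ".join(fatal))
    sb = doc.getModel()
    if sb is None:
        raise ParseError(f"{path.name}: no <model> element")
    if doc.getLevel() != 3:
        warnings.warn(
            f"{path.name}: SBML level {doc.getLevel()} (targeting level 3); "
            "reading with default bound conventions",
            ModelFormatWarning,
        )
    fbc = sb.getPlugin("fbc")
    if fbc is None:
        warnings.warn(
            f"{path.name}: no fbc package; bounds default to ±{DEFAULT_BOUND:g} "
            "and the objective will be empty unless annotated",
            ModelFormatWarning,
        )

    mets: List[Metabolite] = []
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        sfbc = sp.getPlugin("fbc")
        formula = None
        if sfbc is not None and sfbc.isSetChemicalFormula():
            formula = sfbc.getChemicalFormula()
        mets.append(
            Metabolite(
                id=sp.getId(),
                compartment=_compartment_from_id(sp.getId(), sp.getCompartment()),
                name=sp.getName() or "",
                formula=formula,
            )
        )
    met_set = {m.id for m in mets}

    def _bound(rxn, which: str, default: float) -> float:
        rf = rxn.getPlugin("fbc")
        if rf is not None:
            pid = rf.getLowerFluxBound() if which == "lb" else rf.getUpperFluxBound()
            if pid:
                param = sb.getParameter(pid)
                if param is not None and param.isSetValue():
                    return param.getValue()
        return default

    rxns: List[Reaction] = []
    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        stoich: Dict[str, float] = {}
        unknown: List[str] = []
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            sid = ref.getSpecies()
            if sid in met_set:
                stoich[sid] = stoich.get(sid, 0.0) - (ref.getStoichiometry() or 1.0)
            else:
                unknown.append(sid)
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            sid = ref.getSpecies()
            if sid in met_set:
                stoich[sid] = stoich.get(sid, 0.0) + (ref.getStoichiometry() or 1.0)
            else:
                unknown.append(sid)
        if unknown:
            raise ValidationError(
                f"reaction {rx.getId()!r} references unknown species: {sorted(set(unknown))}"
            )
        default_lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
        comp = ""
        if len(stoich) == 1:
            (only_met,) = stoich
            comp = next(m.compartment for m in mets if m.id == only_met)
        rxns.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                lower_bound=_bound(rx, "lb", default_lb),
                upper_bound=_bound(rx, "ub", DEFAULT_BOUND),
                is_exchange=infer_exchange(rx.getId(), len(stoich), comp),
            )
        )

    objective: Dict[str, float] = {}
    if fbc is not None:
        active = fbc.getActiveObjective()
        if active is not None:
            for k in range(active.getNumFluxObjectives()):
                fo = active.getFluxObjective(k)
                objective[fo.getReaction()] = fo.getCoefficient()

    model = StoichiometricModel(id=sb.getId() or path.stem, metabolites=mets,
                                reactions=rxns, objective=objective)
    model.validate()
    return model


def write_sbml(model: StoichiometricModel, path: PathLike) -> None:
    """Write SBML L3V1 with the fbc v2 package (bounds + objective)."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(model.id)
    fbc = sb.getPlugin("fbc")
    fbc.setStrict(False)

    for label in model.compartments:
        comp = sb.createCompartment()
        comp.setId(label)
        comp.setConstant(True)

    met_comp = {}
    for m in model.metabolites:
        sp = sb.createSpecies()
        sp.setId(m.id)
        if m.name:
            sp.setName(m.name)
        # id suffix is authoritative for the compartment on write
        comp = _compartment_from_id(m.id, m.compartment)
        if comp not in model.compartments:
            comp = m.compartment
        sp.setCompartment(comp)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if m.formula:
            sp.getPlugin("fbc").setChemicalFormula(m.formula)
        met_comp[m.id] = comp

    def _param(value: float, stem: str) -> str:
        pid = f"{stem}"
        if sb.getParameter(pid) is None:
            p = sb.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
        return pid

    for r in model.reactions:
        rx = sb.createReaction()
        rx.setId(r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for met_id, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rf = rx.getPlugin("fbc")
        rf.setLowerFluxBound(_param(r.lower_bound, f"{r.id}_lb"))
        rf.setUpperFluxBound(_param(r.upper_bound, f"{r.id}_ub"))

    if model.objective:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, w in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(w)
        fbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Tabular fixture dialect
# ---------------------------------------------------------------------------

def _parse_side(text: str, lineno: int, line: str) -> Dict[str, float]:
    stoich: Dict[str, float] = {}
    text = text.strip()
    if not text:
        return stoich
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ParseError(f"line {lineno}: empty term in equation: {line!r}")
        parts = term.split()
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: bad coefficient {parts[0]!r} in {line!r}"
                ) from None
            met = parts[1]
        else:
            raise ParseError(f"line {lineno}: cannot parse term {term!r} in {line!r}")
        stoich[met] = stoich.get(met, 0.0) + coef
    return stoich


def parse_equation(
    equation: str, lineno: int = 0
) -> Tuple[Dict[str, float], bool]:
    """Parse ``"2 A_c + B_c -> C_c"`` into (stoichiometry, reversible)."""
    if "<=>" in equation:
        arrow, reversible = "<=>", True
    elif "->" in equation:
        arrow, reversible = "->", False
    else:
        raise ParseError(f"line {lineno}: no arrow in equation: {equation!r}")
    left, right = equation.split(arrow, 1)
    stoich: Dict[str, float] = {}
    for met, coef in _parse_side(left, lineno, equation).items():
        stoich[met] = stoich.get(met, 0.0) - coef
    for met, coef in _parse_side(right, lineno, equation).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ParseError(f"line {lineno}: equation has no net stoichiometry: {equation!r}")
    return stoich, reversible


def read_tabular(path: PathLike) -> StoichiometricModel:
    """Read the TSV fixture dialect; semantics identical to :func:`read_sbml`."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    section = None
    mets: List[Metabolite] = []
    rxns: List[Reaction] = []
    objective: Dict[str, float] = {}
    seen_rxn_ids: set = set()

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or (stripped.startswith("#") and not stripped.startswith("#METAB")
                            and not stripped.startswith("#REACT")
                            and not stripped.startswith("#OBJECT")):
            continue
        if stripped.startswith("#METABOLITES"):
            section = "met"
            continue
        if stripped.startswith("#REACTIONS"):
            section = "rxn"
            continue
        if stripped.startswith("#OBJECTIVE"):
            section = "obj"
            continue
        cols = line.split("\t")
        if section == "met":
            mid = cols[0].strip()
            name = cols[1].strip() if len(cols) > 1 else ""
            formula = cols[2].strip() or None if len(cols) > 2 else None
            category = cols[3].strip() or None if len(cols) > 3 else None
            comp = mid.rsplit("_", 1)[1] if "_" in mid else mid
            mets.append(Metabolite(id=mid, compartment=comp, name=name,
                                   formula=formula, category=category))
        elif section == "rxn":
            if len(cols) < 2:
                raise ParseError(f"line {lineno}: reaction needs id and equation: {line!r}")
            rid = cols[0].strip()
            if rid in seen_rxn_ids:
                raise ValidationError(f"line {lineno}: duplicate reaction id {rid!r}")
            seen_rxn_ids.add(rid)
            stoich, reversible = parse_equation(cols[1], lineno)
            lb = float(cols[2]) if len(cols) > 2 and cols[2].strip() else (
                -DEFAULT_BOUND if reversible else 0.0)
            ub = float(cols[3]) if len(cols) > 3 and cols[3].strip() else DEFAULT_BOUND
            comp = ""
            if len(stoich) == 1:
                (only_met,) = stoich
                comp = next((m.compartment for m in mets if m.id == only_met),
                            only_met.rsplit("_", 1)[-1])
            rxns.append(Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                                 upper_bound=ub,
                                 is_exchange=infer_exchange(rid, len(stoich), comp)))
        elif section == "obj":
            if len(cols) < 2:
                raise ParseError(f"line {lineno}: objective needs id and weight: {line!r}")
            objective[cols[0].strip()] = float(cols[1])
        else:
            raise ParseError(f"line {lineno}: content before any section header: {line!r}")

    model = StoichiometricModel(id=path.stem, metabolites=mets, reactions=rxns,
                                objective=objective)
    model.validate()
    return model


def write_tabular(model: StoichiometricModel, path: PathLike) -> None:
    out: List[str] = ["#METABOLITES"]
    for m in model.metabolites:
        out.append("\t".join([m.id, m.name, m.formula or "", m.category or ""]).rstrip("\t"))
    out.append("#REACTIONS")
    for r in model.reactions:
        arrow = "<=>" if r.lower_bound < 0 else "->"
        lhs = " + ".join(
            (f"{-c:g} {m}" if c != -1 else m)
            for m, c in r.stoichiometry.items() if c < 0
        )
        rhs = " + ".join(
            (f"{c:g} {m}" if c != 1 else m)
            for m, c in r.stoichiometry.items() if c > 0
        )
        out.append("\t".join([r.id, f"{lhs} {arrow} {rhs}".strip(),
                              f"{r.lower_bound:g}", f"{r.upper_bound:g}"]))
    out.append("#OBJECTIVE")
    for rid, w in model.objective.items():
        out.append(f"{rid}\t{w:g}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Community models: SBML plus a sidecar metadata JSON
# ---------------------------------------------------------------------------

def write_community(community, path: PathLike) -> None:
    """Write a community model as SBML plus ``<path>.meta.json``.

    SBML carries the stoichiometry/bounds/objective; the sidecar carries
    what SBML cannot: species tags, provenance, and the transfer/exchange
    bookkeeping needed to call interspecies exchanges after a reload.
    """
    path = Path(path)
    write_sbml(community.base, path)
    meta = {
        "species_a_id": community.species_a_id,
        "species_b_id": community.species_b_id,
        "species_a_tag": community.species_a_tag,
        "species_b_tag": community.species_b_tag,
        "compartment_map": community.compartment_map,
        "provenance": {k: list(v) for k, v in community.provenance.items()},
        "transfer_map": community.transfer_map,
        "exchange_map": community.exchange_map,
        "biomass_ids": community.biomass_ids,
        "species_tags": {
            r.id: r.species_tag for r in community.base.reactions if r.species_tag
        },
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8"
    )


def read_community(path: PathLike):
    """Reload a community model written by :func:`write_community`."""
    from .community import CommunityModel  # local import: io must not depend on solving

    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(
            f"{meta_path} missing: community models need their sidecar metadata"
        )
    base = read_sbml(path)
    meta = json.loads(meta_path.read_text(encoding="utf-8"))
    tags = meta.get("species_tags", {})
    for r in base.reactions:
        r.species_tag = tags.get(r.id)
        if r.id in meta["exchange_map"].values():
            r.is_exchange = True
            r.species_tag = "shared"
    return CommunityModel(
        base=base,
        species_a_id=meta["species_a_id"],
        species_b_id=meta["species_b_id"],
        species_a_tag=meta["species_a_tag"],
        species_b_tag=meta["species_b_tag"],
        compartment_map=meta["compartment_map"],
        provenance={k: tuple(v) for k, v in meta["provenance"].items()},
        transfer_map=meta["transfer_map"],
        exchange_map=meta["exchange_map"],
        biomass_ids=meta["biomass_ids"],
    )


# ---------------------------------------------------------------------------
# Media and category annotations
# ---------------------------------------------------------------------------

def load_medium(path: PathLike) -> Dict[str, float]:
    """Load a medium (metabolite base-id -> max uptake) from YAML or TSV."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{path.name}: medium YAML must be a mapping")
        medium = {str(k): float(v) for k, v in data.items()}
    else:
        medium = {}
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "metabolite_id":
                continue
            if len(cols) < 2:
                raise ParseError(f"{path.name} line {lineno}: expected id<TAB>max_uptake")
            medium[cols[0]] = float(cols[1])
    bad = {k: v for k, v in medium.items() if v < 0}
    if bad:
        raise ValidationError(f"negative max-uptake values in medium: {bad}")
    return medium


def load_categories(path: PathLike) -> Dict[str, str]:
    """Load a metabolite category annotation TSV (metabolite_id, category)."""
    table: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if cols[0] == "metabolite_id":
            continue
        if len(cols) < 2:
            raise ParseError(f"{path} line {lineno}: expected metabolite_id<TAB>category")
        cat = cols[1].strip()
        if cat not in CATEGORIES:
            raise ValidationError(
                f"{path} line {lineno}: unknown category {cat!r} "
                f"(allowed: {sorted(CATEGORIES)})"
            )
        table[cols[0].strip()] = cat
    return table


def apply_categories(model: StoichiometricModel, table: Dict[str, str]) -> None:
    """Stamp curated categories onto metabolites, matched by base id."""
    for m in model.metabolites:
        cat = table.get(m.base_id, table.get(m.id))
        if cat is not None:
            m.category = cat
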