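"""Core data model for constraint-based stoichiometric networks.

A :class:`StoichiometricModel` is the unit everything else operates on:
an ordered set of metabolites, an ordered set of reactions with flux
bounds, and a linear objective over reaction fluxes.  Sign conventions
follow the constraint-based modeling community: negative stoichiometric
coefficients consume, positive produce; an exchange reaction is written
``M -> (nothing)`` so that negative flux is uptake into the system and
positive flux is secretion.

Compartments are encoded both in the metabolite's ``compartment`` field
and as an ``_<label>`` suffix on its id; the suffix is authoritative when
serializing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

__all__ = [
    "CATEGORIES",
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "ValidationError",
    "Finding",
    "stoichiometric_matrix",
    "validate_model",
    "base_id",
]

#: Default flux bound magnitude (mmol gDW^-1 h^-1) used when a model
#: omits explicit bounds; the community convention for genome-scale models.
DEFAULT_BOUND = 1000.0

#: Allowed metabolite category labels (curated annotation, never inferred).
CATEGORIES = frozenset(
    {"cofactor", "amino_acid", "nucleotide", "carbohydrate", "lipid", "other"}
)


class ValidationError(ValueError):
    """A model violates a structural invariant."""


@dataclass
class Metabolite:
    """A chemical species localized to one compartment.

    The id carries the compartment as a suffix (``glc_e`` lives in ``e``);
    ``category`` is a curated class label used when tallying exchanged
    metabolites (cofactor, amino_acid, ...), not something inferred from
    the name.
    """

    id: str
    compartment: str
    name: str = ""
    formula: Optional[str] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be non-empty")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValidationError(
                f"metabolite {self.id!r}: unknown category {self.category!r}"
            )

    @property
    def base_id(self) -> str:
        """Id with the compartment suffix stripped."""
        return base_id(self.id, self.compartment)


def base_id(met_id: str, compartment: str) -> str:
    suffix = "_" + compartment
    if met_id.endswith(suffix):
        return met_id[: -len(suffix)]
    return met_id


@dataclass
class Reaction:
    """A flux-carrying conversion: stoichiometry plus bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  ``is_exchange`` marks boundary reactions,
    which by invariant touch exactly one metabolite.  ``species_tag``
    records which organism a reaction belongs to in a community model.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    species_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ValidationError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite, "
                f"touches {len(self.stoichiometry)}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def metabolite_ids(self) -> List[str]:
        return list(self.stoichiometry)


@dataclass
class StoichiometricModel:
    """An ordered stoichiometric network with bounds and a linear objective."""

    id: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    objective: Dict[str, float] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def compartments(self) -> List[str]:
        seen: Dict[str, None] = {}
        for m in self.metabolites:
            seen.setdefault(m.compartment)
        return list(seen)

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any structural invariant breach."""
        met_ids = self.metabolite_ids
        met_set = set(met_ids)
        if len(met_set) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids: {dupes}")
        for r in self.reactions:
            unknown = [m for m in r.stoichiometry if m not in met_set]
            if unknown:
                raise ValidationError(
                    f"reaction {r.id!r} references unknown metabolites: {unknown}"
                )
        missing = [rid for rid in self.objective if rid not in set(rxn_ids)]
        if missing:
            raise ValidationError(f"objective references unknown reactions: {missing}")

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions
            ],
            objective=dict(self.objective),
        )


def stoichiometric_matrix(model: StoichiometricModel) -> np.ndarray:
    """Dense S-matrix: rows = metabolites, columns = reactions.

    Entry ``(i, j)`` is reaction *j*'s signed coefficient for metabolite
    *i*, zero where the reaction does not touch the metabolite.
    """
    n_m, n_r = len(model.metabolites), len(model.reactions)
    S = np.zeros((n_m, n_r))
    row = {m.id: i for i, m in enumerate(model.metabolites)}
    for j, r in enumerate(model.reactions):
        for met_id, coef in r.stoichiometry.items():
            S[row[met_id], j] = coef
    return S


@dataclass(frozen=True)
class Finding:
    """One structural issue flagged by :func:`validate_model`."""

    kind: str  # orphan | dead_end | bound | no_objective
    subject: str
    detail: str = ""


def validate_model(model: StoichiometricModel) -> List[Finding]:
    """Report-only structural screen: orphans, dead ends, bad bounds, no objective.

    A *dead-end* metabolite can only ever be produced or only ever be
    consumed (accounting for reaction reversibility), so it blocks any
    steady-state flux through its neighborhood.
    """
    findings: List[Finding] = []
    producers: Dict[str, bool] = {m.id: False for m in model.metabolites}
    consumers: Dict[str, bool] = {m.id: False for m in model.metabolites}
    touched: Dict[str, bool] = {m.id: False for m in model.metabolites}

    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            findings.append(
                Finding("bound", r.id, f"lower {r.lower_bound} > upper {r.upper_bound}")
            )
        fwd = r.upper_bound > 0
        rev = r.lower_bound < 0
        for met_id, coef in r.stoichiometry.items():
            if met_id not in touched:
                continue  # unknown refs are validate()'s job
            touched[met_id] = True
            if (coef > 0 and fwd) or (coef < 0 and rev):
                producers[met_id] = True
            if (coef < 0 and fwd) or (coef > 0 and rev):
                consumers[met_id] = True

    for m in model.metabolites:
        if not touched[m.id]:
            findings.append(Finding("orphan", m.id, "metabolite used by no reaction"))
        elif producers[m.id] != consumers[m.id]:
            side = "produced" if producers[m.id] else "consumed"
            findings.append(Finding("dead_end", m.id, f"only ever {side}"))

    if not model.objective:
        findings.append(Finding("no_objective", model.id, "model has no objective"))
    return findings
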