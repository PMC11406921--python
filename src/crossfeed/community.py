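"""Build a five-compartment two-species community model.

Two single-species models, each with a cytoplasm and an extracellular
compartment, are merged around a shared extracellular space ``e``:

* species A keeps its own cytoplasm (``r``) and extracellular space (``t``),
* species B likewise (``z`` and ``s``),
* every original boundary (exchange) reaction ``M_t -> (nothing)`` becomes a
  transfer reaction ``M_t <-> M_e`` into the shared space, inheriting its
  bounds, and
* each shared metabolite gets exactly one community exchange
  ``M_e -> (nothing)``, closed to uptake until a medium opens it.

With this topology a metabolite can only pass between species through
``e``, so interspecies exchange is read directly off the transfer fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

from .core import (
    DEFAULT_BOUND,
    Metabolite,
    Reaction,
    StoichiometricModel,
    ValidationError,
    base_id,
)

__all__ = [
    "SHARED_COMPARTMENT",
    "CommunityModel",
    "tag_model",
    "merge_community",
    "apply_medium",
    "apply_medium_to_model",
    "set_community_objective",
    "community_exchange_id",
]

SHARED_COMPARTMENT = "e"


def community_exchange_id(met_base: str) -> str:
    return f"EX_{met_base}_{SHARED_COMPARTMENT}"


@dataclass
class CommunityModel:
    """A merged two-species model plus the bookkeeping to unmerge it.

    ``provenance`` maps each community reaction id (except community
    exchanges) back to (source model id, source reaction id).
    ``transfer_map`` maps each shared metabolite id to the per-species
    transfer reaction carrying it into/out of ``e``.
    """

    base: StoichiometricModel
    species_a_id: str
    species_b_id: str
    species_a_tag: str
    species_b_tag: str
    compartment_map: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    transfer_map: Dict[str, Dict[str, str]] = field(default_factory=dict)
    exchange_map: Dict[str, str] = field(default_factory=dict)
    biomass_ids: Dict[str, str] = field(default_factory=dict)

    @property
    def tags(self) -> Tuple[str, str]:
        return (self.species_a_tag, self.species_b_tag)

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            base=self.base.copy(),
            species_a_id=self.species_a_id,
            species_b_id=self.species_b_id,
            species_a_tag=self.species_a_tag,
            species_b_tag=self.species_b_tag,
            compartment_map=dict(self.compartment_map),
            provenance=dict(self.provenance),
            transfer_map={k: dict(v) for k, v in self.transfer_map.items()},
            exchange_map=dict(self.exchange_map),
            biomass_ids=dict(self.biomass_ids),
        )


def _extracellular_compartment(model: StoichiometricModel) -> Optional[str]:
    """The compartment whose metabolites sit on exchange reactions."""
    comps = set()
    for r in model.exchanges:
        (met_id,) = r.stoichiometry
        comps.add(model.metabolite(met_id).compartment)
    if len(comps) > 1:
        raise ValidationError(
            f"model {model.id!r}: exchange metabolites span several compartments: "
            f"{sorted(comps)}"
        )
    return comps.pop() if comps else None


def tag_model(
    model: StoichiometricModel,
    species_tag: str,
    cytoplasm_label: str,
    extracellular_label: str,
) -> StoichiometricModel:
    """Relabel a single-species model's compartments and stamp its reactions.

    Metabolite ids are re-suffixed (``glc_e`` -> ``glc_t``), reaction ids
    are prefixed with the species tag, and every reaction carries
    ``species_tag``.  Idempotent: tagging an already-tagged model with
    the same labels is the identity.
    """
    if cytoplasm_label == extracellular_label:
        raise ValidationError("cytoplasm and extracellular labels must differ")
    for label in (cytoplasm_label, extracellular_label):
        if label == SHARED_COMPARTMENT:
            raise ValidationError(
                f"label {label!r} collides with the shared compartment "
                f"{SHARED_COMPARTMENT!r}"
            )
    comps = model.compartments
    if len(comps) > 2:
        raise ValidationError(
            f"model {model.id!r} has {len(comps)} compartments {comps}; "
            "only two-compartment (cytoplasm + extracellular) topologies are supported"
        )

    ext = _extracellular_compartment(model)
    comp_rename: Dict[str, str] = {}
    for comp in comps:
        comp_rename[comp] = extracellular_label if comp == ext else cytoplasm_label
    if len(set(comp_rename.values())) < len(comp_rename):
        raise ValidationError(
            f"model {model.id!r}: compartments {comps} cannot be mapped onto "
            f"({cytoplasm_label}, {extracellular_label}) unambiguously"
        )

    met_rename: Dict[str, str] = {}
    new_mets: List[Metabolite] = []
    for m in model.metabolites:
        new_comp = comp_rename[m.compartment]
        new_id = base_id(m.id, m.compartment) + "_" + new_comp
        met_rename[m.id] = new_id
        new_mets.append(replace(m, id=new_id, compartment=new_comp))

    prefix = f"{species_tag}__"
    new_rxns: List[Reaction] = []
    for r in model.reactions:
        rid = r.id if r.id.startswith(prefix) else prefix + r.id
        new_rxns.append(
            replace(
                r,
                id=rid,
                stoichiometry={met_rename[m]: c for m, c in r.stoichiometry.items()},
                species_tag=species_tag,
            )
        )
    rid_rename = {r.id: nr.id for r, nr in zip(model.reactions, new_rxns)}

    tagged = StoichiometricModel(
        id=model.id,
        metabolites=new_mets,
        reactions=new_rxns,
        objective={rid_rename[rid]: w for rid, w in model.objective.items()},
    )
    tagged.validate()
    return tagged


def _biomass_reaction(model: StoichiometricModel) -> str:
    """The growth reaction: the objective if unambiguous, else by name."""
    if len(model.objective) == 1:
        return next(iter(model.objective))
    named = [r.id for r in model.reactions if "biomass" in r.id.lower()]
    if len(named) == 1:
        return named[0]
    raise ValidationError(
        f"model {model.id!r}: cannot identify a unique biomass reaction "
        f"(objective={list(model.objective)}, name matches={named}); "
        "set the objective to the biomass reaction explicitly"
    )


def merge_community(
    model_a: StoichiometricModel, model_b: StoichiometricModel
) -> CommunityModel:
    """Merge two tagged models around the shared compartment ``e``.

    Each original exchange reaction becomes a transfer into ``e`` with the
    same bounds; each shared metabolite gets one community exchange with
    default bounds (0, +1000) — nothing enters the system until
    :func:`apply_medium` opens it.  The community objective is the
    unweighted sum of the two biomass reactions.
    """
    tags_a = {r.species_tag for r in model_a.reactions}
    tags_b = {r.species_tag for r in model_b.reactions}
    if len(tags_a) != 1 or None in tags_a or len(tags_b) != 1 or None in tags_b:
        raise ValidationError("both models must be tagged (run tag_model first)")
    tag_a, tag_b = tags_a.pop(), tags_b.pop()
    if tag_a == tag_b:
        raise ValidationError(f"species tags must differ, both are {tag_a!r}")
    comps_a, comps_b = set(model_a.compartments), set(model_b.compartments)
    overlap = comps_a & comps_b
    if overlap:
        raise ValidationError(f"models share compartment labels: {sorted(overlap)}")
    if SHARED_COMPARTMENT in comps_a | comps_b:
        raise ValidationError(
            f"neither input may already use compartment {SHARED_COMPARTMENT!r}"
        )
    collisions = set(model_a.reaction_ids) & set(model_b.reaction_ids)
    if collisions:
        raise ValidationError(
            f"duplicate reaction ids across species: {sorted(collisions)}"
        )

    bio_a = _biomass_reaction(model_a)
    bio_b = _biomass_reaction(model_b)

    metabolites: List[Metabolite] = []
    reactions: List[Reaction] = []
    provenance: Dict[str, Tuple[str, str]] = {}
    transfer_map: Dict[str, Dict[str, str]] = {}
    shared: Dict[str, Metabolite] = {}

    for model, tag in ((model_a, tag_a), (model_b, tag_b)):
        metabolites.extend(replace(m) for m in model.metabolites)
        prefix = f"{tag}__"
        for r in model.reactions:
            src_id = r.id[len(prefix):] if r.id.startswith(prefix) else r.id
            if r.is_exchange:
                (met_id,) = r.stoichiometry
                met = model.metabolite(met_id)
                e_id = met.base_id + "_" + SHARED_COMPARTMENT
                if e_id not in shared:
                    shared[e_id] = replace(
                        met, id=e_id, compartment=SHARED_COMPARTMENT, category=met.category
                    )
                # M_x -> M_e : positive flux secretes into the shared space
                new = replace(
                    r,
                    stoichiometry={met_id: r.stoichiometry[met_id], e_id: -r.stoichiometry[met_id]},
                    is_exchange=False,
                )
                transfer_map.setdefault(e_id, {})[tag] = new.id
            else:
                new = replace(r, stoichiometry=dict(r.stoichiometry))
            reactions.append(new)
            provenance[new.id] = (model.id, src_id)

    metabolites.extend(shared.values())
    for e_id in shared:
        rid = community_exchange_id(base_id(e_id, SHARED_COMPARTMENT))
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry={e_id: -1.0},
                lower_bound=0.0,  # closed to uptake until a medium opens it
                upper_bound=DEFAULT_BOUND,
                is_exchange=True,
                species_tag="shared",
            )
        )

    base = StoichiometricModel(
        id=f"community_{model_a.id}_{model_b.id}",
        metabolites=metabolites,
        reactions=reactions,
        objective={bio_a: 1.0, bio_b: 1.0},
    )
    base.validate()

    compartment_map = {}
    for comp in model_a.compartments:
        role = "extracellular" if comp == _extracellular_compartment(model_a) else "cytoplasm"
        compartment_map[comp] = f"{role}-{tag_a}"
    for comp in model_b.compartments:
        role = "extracellular" if comp == _extracellular_compartment(model_b) else "cytoplasm"
        compartment_map[comp] = f"{role}-{tag_b}"
    compartment_map[SHARED_COMPARTMENT] = "shared"

    return CommunityModel(
        base=base,
        species_a_id=model_a.id,
        species_b_id=model_b.id,
        species_a_tag=tag_a,
        species_b_tag=tag_b,
        compartment_map=compartment_map,
        provenance=provenance,
        transfer_map=transfer_map,
        exchange_map={
            e_id: community_exchange_id(base_id(e_id, SHARED_COMPARTMENT))
            for e_id in shared
        },
        biomass_ids={tag_a: bio_a, tag_b: bio_b},
    )


def apply_medium_to_model(
    model: StoichiometricModel, medium: Mapping[str, float]
) -> StoichiometricModel:
    """Set exchange uptake bounds from a medium on a plain model.

    Listed metabolites (matched by base id) get lower bound -max_uptake;
    every other exchange is closed to uptake (lower bound 0).  Secretion
    bounds are untouched.  Returns a new model; raises on negative uptake
    values.
    """
    bad = {k: v for k, v in medium.items() if v < 0}
    if bad:
        raise ValidationError(f"uptake magnitudes must be non-negative: {bad}")
    out = model.copy()
    matched = set()
    for r in out.reactions:
        if not r.is_exchange:
            continue
        (met_id,) = r.stoichiometry
        met = out.metabolite(met_id)
        key = met.base_id
        if key in medium:
            r.lower_bound = -float(medium[key])
            matched.add(key)
        else:
            r.lower_bound = 0.0
        if r.lower_bound > r.upper_bound:
            r.upper_bound = max(r.upper_bound, 0.0)
    missing = sorted(set(medium) - matched)
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "medium components with no matching exchange: %s", missing
        )
    return out


def apply_medium(
    community: CommunityModel, medium: Mapping[str, float]
) -> CommunityModel:
    """Open community exchanges per the medium; all others closed to uptake."""
    bad = {k: v for k, v in medium.items() if v < 0}
    if bad:
        raise ValidationError(f"uptake magnitudes must be non-negative: {bad}")
    out = community.copy()
    ex_ids = set(out.exchange_map.values())
    matched = set()
    for r in out.base.reactions:
        if r.id not in ex_ids:
            continue
        (met_id,) = r.stoichiometry
        key = base_id(met_id, SHARED_COMPARTMENT)
        if key in medium:
            r.lower_bound = -float(medium[key])
            matched.add(key)
        else:
            r.lower_bound = 0.0
    missing = sorted(set(medium) - matched)
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "medium components with no community exchange: %s", missing
        )
    return out


def set_community_objective(
    community: CommunityModel, weights: Optional[Mapping[str, float]] = None
) -> CommunityModel:
    """Set the objective to a weighted sum of the two biomass reactions.

    ``weights`` maps species tag -> weight; default 1:1, mirroring an
    equal-inoculum coculture.
    """
    weights = dict(weights) if weights else {t: 1.0 for t in community.tags}
    unknown = sorted(set(weights) - set(community.tags))
    if unknown:
        raise ValidationError(f"unknown species tags in weights: {unknown}")
    out = community.copy()
    objective = {}
    for tag, w in weights.items():
        bio = community.biomass_ids.get(tag)
        if bio is None:
            raise ValidationError(f"species {tag!r} has no identified biomass reaction")
        objective[bio] = float(w)
    out.base.objective = objective
    return out
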