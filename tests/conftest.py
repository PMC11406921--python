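from dataclasses import replace

import pytest

from crossfeed.community import apply_medium, merge_community, tag_model
from crossfeed.core import Metabolite, Reaction, StoichiometricModel
from crossfeed.synthetic import make_core_model, make_crossfeeding_pair


@pytest.fixture
def chain_model():
    """Substrate -> biomass chain: EX_sub (lb -10), transport, one step, biomass."""
    return make_core_model(1)


@pytest.fixture
def parallel_model():
    """Two routes to the same precursor: one step vs two steps."""
    mets = [
        Metabolite("sub_e", "e"),
        Metabolite("sub_c", "c"),
        Metabolite("mid_c", "c"),
        Metabolite("prec_c", "c"),
    ]
    rxns = [
        Reaction("EX_sub", {"sub_e": -1.0}, -10.0, 1000.0, is_exchange=True),
        Reaction("T_sub", {"sub_e": -1.0, "sub_c": 1.0}, 0.0, 1000.0),
        Reaction("SHORT", {"sub_c": -1.0, "prec_c": 1.0}, 0.0, 1000.0),
        Reaction("LONG1", {"sub_c": -1.0, "mid_c": 1.0}, 0.0, 1000.0),
        Reaction("LONG2", {"mid_c": -1.0, "prec_c": 1.0}, 0.0, 1000.0),
        Reaction("BIOMASS", {"prec_c": -1.0}, 0.0, 1000.0),
    ]
    m = StoichiometricModel("parallel", mets, rxns, {"BIOMASS": 1.0})
    m.validate()
    return m


def rename_base_ids(model: StoichiometricModel, mapping) -> StoichiometricModel:
    """Copy with metabolite base ids renamed (compartment suffixes kept)."""

    def rn(met_id, comp):
        base = met_id[: -len("_" + comp)] if met_id.endswith("_" + comp) else met_id
        return mapping.get(base, base) + "_" + comp

    met_rename = {m.id: rn(m.id, m.compartment) for m in model.metabolites}
    return StoichiometricModel(
        id=model.id + "_renamed",
        metabolites=[replace(m, id=met_rename[m.id]) for m in model.metabolites],
        reactions=[
            replace(r, stoichiometry={met_rename[k]: v for k, v in r.stoichiometry.items()})
            for r in model.reactions
        ],
        objective=dict(model.objective),
    )


def build_community(scenario, tag_a=None, tag_b=None):
    """Tag, merge, and apply the scenario medium; returns the CommunityModel."""
    tag_a = tag_a or scenario.tag_a
    tag_b = tag_b or scenario.tag_b
    community = merge_community(
        tag_model(scenario.model_a, tag_a, "r", "t"),
        tag_model(scenario.model_b, tag_b, "z", "s"),
    )
    return apply_medium(community, scenario.shared_medium)


@pytest.fixture
def cofactor_scenario():
    return make_crossfeeding_pair("cofactor", seed=7)
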