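import numpy as np
import pytest

from conftest import build_community, rename_base_ids

from crossfeed.community import (
    apply_medium,
    apply_medium_to_model,
    merge_community,
    set_community_objective,
    tag_model,
)
from crossfeed.core import (
    Metabolite,
    Reaction,
    StoichiometricModel,
    ValidationError,
    stoichiometric_matrix,
)
from crossfeed.solver import fba, pfba
from crossfeed.synthetic import make_core_model, make_crossfeeding_pair


class TestTagModel:
    def test_extracellular_resuffixed(self, chain_model):
        tagged = tag_model(chain_model, "A", "r", "t")
        assert "sub_t" in tagged.metabolite_ids
        assert set(tagged.compartments) == {"r", "t"}
        assert all(r.species_tag == "A" for r in tagged.reactions)

    def test_second_species_labels(self, chain_model):
        tagged = tag_model(chain_model, "B", "z", "s")
        assert set(tagged.compartments) == {"z", "s"}

    def test_idempotent(self, chain_model):
        once = tag_model(chain_model, "A", "r", "t")
        twice = tag_model(once, "A", "r", "t")
        assert twice.metabolite_ids == once.metabolite_ids
        assert twice.reaction_ids == once.reaction_ids
        assert twice.objective == once.objective

    def test_objective_preserved(self, chain_model):
        tagged = tag_model(chain_model, "A", "r", "t")
        assert fba(tagged).objective_value == pytest.approx(
            fba(chain_model).objective_value
        )

    def test_shared_label_rejected(self, chain_model):
        with pytest.raises(ValidationError, match="collides"):
            tag_model(chain_model, "A", "r", "e")

    def test_three_compartments_rejected(self, chain_model):
        chain_model.metabolites.append(Metabolite("x_p", "p"))
        chain_model.reactions.append(
            Reaction("P", {"sub_c": -1.0, "x_p": 1.0}, 0.0, 10.0)
        )
        with pytest.raises(ValidationError, match="compartments"):
            tag_model(chain_model, "A", "r", "t")


class TestMerge:
    def test_five_compartments(self, cofactor_scenario):
        community = build_community(cofactor_scenario)
        assert set(community.base.compartments) == {"r", "t", "z", "s", "e"}
        assert set(community.compartment_map) == {"r", "t", "z", "s", "e"}

    def test_counts_bookkeeping(self, cofactor_scenario):
        a = tag_model(cofactor_scenario.model_a, "A", "r", "t")
        b = tag_model(cofactor_scenario.model_b, "B", "z", "s")
        community = merge_community(a, b)
        ext_a = {m.base_id for m in a.metabolites if m.compartment == "t"}
        ext_b = {m.base_id for m in b.metabolites if m.compartment == "s"}
        n_shared = len(ext_a | ext_b)
        assert len(community.base.reactions) == len(a.reactions) + len(b.reactions) + n_shared
        assert len(community.base.metabolites) == (
            len(a.metabolites) + len(b.metabolites) + n_shared
        )

    def test_disjoint_extracellular_union(self, chain_model):
        other = rename_base_ids(chain_model, {"sub": "oth", "int1": "oint"})
        a = tag_model(chain_model, "A", "r", "t")
        b = tag_model(other, "B", "z", "s")
        community = merge_community(a, b)
        e_mets = [m for m in community.base.metabolites if m.compartment == "e"]
        assert len(e_mets) == 2  # zero overlap: |ext_a| + |ext_b|

    def test_untagged_rejected(self, chain_model):
        with pytest.raises(ValidationError, match="tagged"):
            merge_community(chain_model, chain_model)

    def test_reaction_id_collision_listed(self):
        mets = [Metabolite("a_r", "r")]
        r1 = Reaction("SAME", {"a_r": -1.0}, 0.0, 1.0, species_tag="A")
        m1 = StoichiometricModel("m1", mets, [r1], {"SAME": 1.0})
        mets2 = [Metabolite("a_z", "z")]
        r2 = Reaction("SAME", {"a_z": -1.0}, 0.0, 1.0, species_tag="B")
        m2 = StoichiometricModel("m2", mets2, [r2], {"SAME": 1.0})
        with pytest.raises(ValidationError, match="SAME"):
            merge_community(m1, m2)

    def test_self_merge_doubles_optimum(self, chain_model):
        """Symmetric duplication under a non-limiting shared medium."""
        single = fba(chain_model).objective_value
        community = merge_community(
            tag_model(chain_model, "A", "r", "t"),
            tag_model(chain_model, "B", "z", "s"),
        )
        community = apply_medium(community, {"sub": 1000.0})
        assert fba(community.base).objective_value == pytest.approx(
            2 * single, abs=1e-6
        )

    def test_merge_order_symmetry(self, cofactor_scenario):
        a = tag_model(cofactor_scenario.model_a, "A", "r", "t")
        b = tag_model(cofactor_scenario.model_b, "B", "z", "s")
        med = cofactor_scenario.shared_medium
        ab = fba(apply_medium(merge_community(a, b), med).base).objective_value
        ba = fba(apply_medium(merge_community(b, a), med).base).objective_value
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_provenance_round_trip(self, cofactor_scenario):
        a = tag_model(cofactor_scenario.model_a, "A", "r", "t")
        b = tag_model(cofactor_scenario.model_b, "B", "z", "s")
        sources = {m.id: m for m in (a, b)}
        community = merge_community(a, b)
        ex_ids = set(community.exchange_map.values())
        for r in community.base.reactions:
            if r.id in ex_ids:
                assert r.id not in community.provenance
                continue
            model_id, src_id = community.provenance[r.id]
            tag = community.species_a_tag if model_id == a.id else community.species_b_tag
            src = sources[model_id].reaction(f"{tag}__{src_id}"
                                            if not src_id.startswith(f"{tag}__")
                                            else src_id)
            assert (r.lower_bound, r.upper_bound) == (src.lower_bound, src.upper_bound)
            # stoichiometry identical up to the added shared-compartment term
            for met_id, coef in src.stoichiometry.items():
                assert r.stoichiometry[met_id] == coef

    def test_no_hidden_coupling(self, chain_model):
        """Cutting one species off the shared space leaves the other's optimum."""
        other = rename_base_ids(chain_model, {"sub": "oth", "int1": "oint"})
        community = merge_community(
            tag_model(chain_model, "A", "r", "t"),
            tag_model(other, "B", "z", "s"),
        )
        community = apply_medium(community, {"sub": 10.0, "oth": 10.0})
        full = fba(community.base).objective_value
        assert full == pytest.approx(20.0, abs=1e-6)
        cut = community.copy()
        b_transfers = {
            rid for per in cut.transfer_map.values()
            for tag, rid in per.items() if tag == "B"
        }
        cut.base.reactions = [r for r in cut.base.reactions if r.id not in b_transfers]
        assert fba(cut.base).objective_value == pytest.approx(10.0, abs=1e-6)

    def test_shared_metabolite_balance_rows(self, cofactor_scenario):
        """Transfer fluxes in plus community exchange flux sum to zero at e."""
        community = build_community(cofactor_scenario)
        sol = pfba(community.base)
        S = stoichiometric_matrix(community.base)
        v = np.array([sol.fluxes[rid] for rid in community.base.reaction_ids])
        e_rows = [
            i for i, m in enumerate(community.base.metabolites) if m.compartment == "e"
        ]
        assert np.abs(S[e_rows] @ v).max() <= 1e-9


class TestMediumAndObjective:
    def test_apply_medium_sets_uptake_bounds(self, cofactor_scenario):
        community = build_community(cofactor_scenario)
        sub_ex = community.base.reaction(community.exchange_map["sub_e"])
        assert sub_ex.lower_bound == -cofactor_scenario.shared_medium["sub"]
        for e_id, rid in community.exchange_map.items():
            if e_id != "sub_e":
                assert community.base.reaction(rid).lower_bound == 0.0

    def test_empty_medium_starves(self, cofactor_scenario):
        community = build_community(cofactor_scenario)
        starved = apply_medium(community, {})
        assert fba(starved.base).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_negative_uptake_rejected(self, cofactor_scenario):
        community = build_community(cofactor_scenario)
        with pytest.raises(ValidationError, match="non-negative"):
            apply_medium(community, {"sub": -1.0})

    def test_medium_on_plain_model(self, chain_model):
        fed = apply_medium_to_model(chain_model, {"sub": 4.0})
        assert fed.reaction("EX_sub").lower_bound == -4.0
        assert fba(fed).objective_value == pytest.approx(4.0, abs=1e-6)

    def test_objective_weights(self, chain_model):
        other = rename_base_ids(chain_model, {"sub": "oth", "int1": "oint"})
        community = merge_community(
            tag_model(chain_model, "A", "r", "t"),
            tag_model(other, "B", "z", "s"),
        )
        community = apply_medium(community, {"sub": 10.0, "oth": 10.0})
        both = set_community_objective(community, {"A": 1.0, "B": 1.0})
        assert len(both.base.objective) == 2
        only_a = set_community_objective(community, {"A": 1.0, "B": 0.0})
        # B secretes nothing A needs, so the optimum equals A alone
        assert fba(only_a.base).objective_value == pytest.approx(10.0, abs=1e-6)

    def test_unknown_tag_rejected(self, cofactor_scenario):
        community = build_community(cofactor_scenario)
        with pytest.raises(ValidationError, match="unknown species tags"):
            set_community_objective(community, {"C": 1.0})
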