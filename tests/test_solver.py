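import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lp_oracle import oracle_fba

from crossfeed.core import Metabolite, Reaction, StoichiometricModel, stoichiometric_matrix
from crossfeed.solver import SolverConfig, fba, fva, pfba
from crossfeed.synthetic import make_core_model, make_random_lp_fixture


class TestFba:
    def test_chain_throughput_limited_by_uptake(self, chain_model):
        sol = fba(chain_model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_starvation(self, chain_model):
        chain_model.reaction("EX_sub").lower_bound = 0.0
        sol = fba(chain_model)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_empty_objective_rejected(self, chain_model):
        chain_model.objective = {}
        with pytest.raises(ValueError, match="objective"):
            fba(chain_model)

    def test_infeasible_reported(self):
        # forced flux with no steady-state support
        m = StoichiometricModel(
            "inf",
            [Metabolite("a_c", "c")],
            [Reaction("R", {"a_c": -1.0}, 1.0, 10.0)],
            {"R": 1.0},
        )
        assert fba(m).status == "infeasible"

    def test_unbounded_reported(self):
        m = StoichiometricModel(
            "unb",
            [Metabolite("a_c", "c"), Metabolite("b_c", "c")],
            [
                Reaction("F", {"a_c": -1.0, "b_c": 1.0}, 0.0, np.inf),
                Reaction("B", {"b_c": -1.0, "a_c": 1.0}, 0.0, np.inf),
            ],
            {"F": 1.0},
        )
        assert fba(m).status == "unbounded"

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        model = make_random_lp_fixture(seed)
        expected, _ = oracle_fba(model)
        sol = fba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_uptake_relaxation_monotone(self, seed):
        """Opening an uptake bound wider can never hurt the optimum."""
        model = make_random_lp_fixture(seed)
        base = fba(model).objective_value
        relaxed = model.copy()
        for r in relaxed.reactions:
            if r.lower_bound < 0:
                r.lower_bound *= 2.0
        assert fba(relaxed).objective_value >= base - 1e-6

    @pytest.mark.parametrize("k", [0.5, 2.0, 7.0])
    def test_scale_equivariance(self, chain_model, k):
        scaled = chain_model.copy()
        for r in scaled.reactions:
            r.lower_bound *= k
            r.upper_bound *= k
        assert fba(scaled).objective_value == pytest.approx(
            k * fba(chain_model).objective_value, rel=1e-6
        )


class TestChainScalingProperty:
    @given(uptake=st.floats(0.01, 1000.0, allow_nan=False))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_optimum_tracks_uptake_bound(self, uptake):
        """On a unit-yield chain the optimum equals the uptake bound exactly."""
        model = make_core_model(2, uptake=uptake)
        sol = fba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(uptake, rel=1e-7, abs=1e-9)


class TestPfba:
    def test_chain_unique_pathway(self, chain_model):
        sol = pfba(chain_model)
        expected = {"EX_sub": -10.0, "T_sub": 10.0, "C1": 10.0, "BIOMASS": 10.0}
        for rid, v in expected.items():
            assert sol.fluxes[rid] == pytest.approx(v, abs=1e-6)
        assert sol.total_abs_flux == pytest.approx(40.0, abs=1e-6)

    def test_prefers_short_route(self, parallel_model):
        """Of two routes to the same product, pFBA takes the one-step route."""
        sol = pfba(parallel_model)
        assert sol.fluxes["SHORT"] == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["LONG1"] == pytest.approx(0.0, abs=1e-6)
        assert sol.fluxes["LONG2"] == pytest.approx(0.0, abs=1e-6)

    def test_objective_retained(self, parallel_model):
        cfg = SolverConfig()
        first = fba(parallel_model, cfg)
        second = pfba(parallel_model, cfg)
        assert second.objective_value >= cfg.opt_fraction * first.objective_value - 1e-6

    def test_infeasible_propagates(self):
        m = StoichiometricModel(
            "inf",
            [Metabolite("a_c", "c")],
            [Reaction("R", {"a_c": -1.0}, 1.0, 10.0)],
            {"R": 1.0},
        )
        assert pfba(m).status == "infeasible"

    @pytest.mark.parametrize("seed", range(8))
    def test_minimality_against_optimal_vertices(self, seed):
        """pFBA total |flux| is <= that of every enumerated optimal vertex."""
        model = make_random_lp_fixture(seed)
        expected, optimal_vertices = oracle_fba(model)
        sol = pfba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)
        for v in optimal_vertices:
            assert sol.total_abs_flux <= np.abs(v).sum() + 1e-6


class TestFva:
    def test_unique_optimum_gives_point_ranges(self, chain_model):
        ranges = fva(chain_model)
        for rid, (lo, hi) in ranges.items():
            assert hi - lo == pytest.approx(0.0, abs=1e-6), rid

    def test_degenerate_routes_admit_zero(self, parallel_model):
        ranges = fva(parallel_model, ["SHORT", "LONG1"])
        for rid in ("SHORT", "LONG1"):
            lo, hi = ranges[rid]
            assert lo <= 1e-6 and hi >= 10.0 - 1e-6  # either route can carry all flux

    def test_full_feasible_range_at_zero_fraction(self, chain_model):
        ranges = fva(chain_model, ["EX_sub"], opt_fraction=0.0)
        lo, hi = ranges["EX_sub"]
        assert lo == pytest.approx(-10.0, abs=1e-6)
        assert hi == pytest.approx(0.0, abs=1e-6)

    def test_pfba_flux_inside_fva_range(self, parallel_model):
        sol = pfba(parallel_model)
        ranges = fva(parallel_model)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_unknown_reaction_listed(self, chain_model):
        with pytest.raises(KeyError, match="ghost"):
            fva(chain_model, ["ghost"])


class TestSteadyState:
    @pytest.mark.parametrize("seed", range(5))
    def test_solutions_are_mass_balanced(self, seed):
        model = make_random_lp_fixture(seed)
        S = stoichiometric_matrix(model)
        for solve in (fba, pfba):
            sol = solve(model)
            v = np.array([sol.fluxes[rid] for rid in model.reaction_ids])
            assert np.abs(S @ v).max() <= 1e-9


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs", [dict(feas_tol=0), dict(opt_fraction=0), dict(opt_fraction=1.5),
                   dict(zero_cut=-1)]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)


def test_cobra_cross_check(chain_model, parallel_model, tmp_path):
    """Independent implementation agreement on FBA optimum and pFBA total flux."""
    cobra = pytest.importorskip("cobra")
    from cobra.flux_analysis import pfba as cobra_pfba

    from crossfeed.io import write_sbml

    for model in (chain_model, parallel_model):
        path = tmp_path / f"{model.id}.xml"
        write_sbml(model, path)
        ref = cobra.io.read_sbml_model(str(path))
        assert ref.slim_optimize() == pytest.approx(
            fba(model).objective_value, abs=1e-6
        )
        ref_total = cobra_pfba(ref).fluxes.abs().sum()
        assert pfba(model).total_abs_flux == pytest.approx(ref_total, abs=1e-4)
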