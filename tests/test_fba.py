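import numpy as np
import pytest

from oracles import enumerate_vertices

from metaboflux.flux import (
    FBAError,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    constrain_from_concentrations,
    problem_from_network,
    solve_fba,
)
from metaboflux.synthetic import generate_toy_network


def solve(network):
    return solve_fba(problem_from_network(network))


class TestToyOptima:
    def test_chain_objective_forced_by_stoichiometry(self):
        sol = solve(generate_toy_network("chain"))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(20.0, abs=1e-8)

    def test_blocked_zero(self):
        sol = solve(generate_toy_network("blocked"))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_branched_routes_through_high_yield(self):
        sol = solve(generate_toy_network("branched"))
        assert sol.objective == pytest.approx(30.0, abs=1e-8)
        assert sol.flux("conv_high") == pytest.approx(10.0, abs=1e-8)
        assert sol.flux("conv_low") == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("kind", ["chain", "branched"])
    def test_matches_vertex_enumeration(self, kind):
        network = generate_toy_network(kind)
        problem = problem_from_network(network)
        sol = solve_fba(problem)
        vertices = enumerate_vertices(problem.S, problem.bounds)
        assert len(vertices)
        i = problem.objective_index
        best = vertices[:, i].max()
        assert sol.objective == pytest.approx(best, abs=1e-8)
        # among optimal vertices, the returned one has minimal L1 norm and
        # the same support
        optimal = vertices[np.isclose(vertices[:, i], best, atol=1e-7)]
        l1 = np.abs(optimal).sum(axis=1)
        chosen = optimal[np.argmin(l1)]
        v = np.array([sol.fluxes[r] for r in problem.reaction_ids])
        assert np.abs(v).sum() == pytest.approx(l1.min(), abs=1e-6)
        np.testing.assert_allclose(v, chosen, atol=1e-6)

    def test_objective_beats_random_feasible_points(self):
        for kind in ("chain", "branched"):
            problem = problem_from_network(generate_toy_network(kind))
            sol = solve_fba(problem)
            vertices = enumerate_vertices(problem.S, problem.bounds)
            rng = np.random.default_rng(0)
            weights = rng.dirichlet(np.ones(len(vertices)), size=1000)
            points = weights @ vertices  # convex combinations stay feasible
            objectives = points[:, problem.objective_index]
            assert (objectives <= sol.objective + 1e-9).all()

    def test_mass_balance(self):
        for kind in ("chain", "branched", "blocked"):
            problem = problem_from_network(generate_toy_network(kind))
            sol = solve_fba(problem)
            v = np.array([sol.fluxes[r] for r in problem.reaction_ids])
            assert np.max(np.abs(problem.S @ v)) <= 1e-9


class TestStatuses:
    def test_infeasible(self):
        network = generate_toy_network("blocked")
        reactions = [
            r if "atp_demand" not in r.tags else Reaction(
                id=r.id, stoich=r.stoich, reversible=False, lb=5.0, ub=10.0,
                subsystem=r.subsystem, tags=r.tags)
            for r in network.reactions
        ]
        bad = MetabolicNetwork(metabolites=network.metabolites, reactions=reactions)
        sol = solve(bad)
        assert sol.status == "infeasible"
        assert sol.fluxes is None

    def test_unbounded(self):
        mets = [Metabolite("atp", "ATP", "cytosol"), Metabolite("adp", "ADP", "cytosol")]
        reactions = [
            Reaction(id="magic", stoich={"adp": -1.0, "atp": 1.0},
                     reversible=False, lb=0.0, ub=np.inf, subsystem="s"),
            Reaction(id="dm", stoich={"atp": -1.0, "adp": 1.0},
                     reversible=False, lb=0.0, ub=np.inf, subsystem="d",
                     tags=frozenset({"atp_demand"})),
        ]
        sol = solve(MetabolicNetwork(metabolites=mets, reactions=reactions))
        assert sol.status == "unbounded"


class TestConstraints:
    def test_reference_sample_gives_vmax(self, reduced_network):
        conc = {"glucose": 2.0, "lactate": 5.0}
        problem = constrain_from_concentrations(reduced_network, conc, conc, v_max=7.0)
        for met in conc:
            idx = problem.reaction_ids.index(reduced_network.exchange_for(met).id)
            assert problem.bounds[idx][1] == pytest.approx(7.0)

    def test_half_reference_halves_bound(self, reduced_network):
        problem = constrain_from_concentrations(
            reduced_network, {"glucose": 1.0}, {"glucose": 2.0}, v_max=10.0)
        idx = problem.reaction_ids.index("EX_glc")
        assert problem.bounds[idx][1] == pytest.approx(5.0)

    def test_chain_fba_halves_with_substrate(self):
        network = generate_toy_network("chain")
        ref = {"substrate": 4.0}
        full = solve_fba(constrain_from_concentrations(network, ref, ref, v_max=10.0))
        half = solve_fba(constrain_from_concentrations(
            network, {"substrate": 2.0}, ref, v_max=10.0))
        assert half.objective == pytest.approx(full.objective / 2, rel=1e-9)

    def test_unmapped_metabolite_skipped(self, reduced_network, caplog):
        problem = constrain_from_concentrations(
            reduced_network, {"taurine": 1.0}, {"taurine": 1.0}, v_max=10.0)
        defaults = problem_from_network(reduced_network)
        assert problem.bounds == defaults.bounds

    def test_non_positive_reference_rejected(self, reduced_network):
        with pytest.raises(FBAError, match="glucose"):
            constrain_from_concentrations(
                reduced_network, {"glucose": 1.0}, {"glucose": 0.0}, v_max=10.0)


class TestInvariants:
    def test_uptake_relaxation_monotone(self, reduced_network):
        base = solve(reduced_network)
        for exchange in reduced_network.exchanges:
            problem = problem_from_network(reduced_network)
            idx = problem.reaction_ids.index(exchange.id)
            lo, hi = problem.bounds[idx]
            problem.bounds[idx] = (lo, hi * 2 if hi > 0 else hi + 1.0)
            relaxed = solve_fba(problem)
            assert relaxed.objective >= base.objective - 1e-7

    @pytest.mark.parametrize("k", [0.25, 0.5, 2.0, 7.3])
    def test_bound_scaling_scales_optimum(self, k):
        problem = problem_from_network(generate_toy_network("branched"))
        base = solve_fba(problem)
        scaled_problem = problem_from_network(generate_toy_network("branched"))
        scaled_problem.bounds = [
            (lo * k if np.isfinite(lo) else lo, hi * k if np.isfinite(hi) else hi)
            for lo, hi in scaled_problem.bounds
        ]
        scaled = solve_fba(scaled_problem)
        assert scaled.objective == pytest.approx(k * base.objective, rel=1e-9)

    def test_bundled_network_mass_balance(self, reduced_network):
        sol = solve(reduced_network)
        problem = problem_from_network(reduced_network)
        v = np.array([sol.fluxes[r] for r in problem.reaction_ids])
        assert np.max(np.abs(problem.S @ v)) <= 1e-9
        assert sol.mass_balance_residual <= 1e-9
        for (lo, hi), flux in zip(problem.bounds, v):
            assert lo - 1e-9 <= flux <= hi + 1e-9

    def test_deterministic(self, reduced_network):
        a, b = solve(reduced_network), solve(reduced_network)
        assert a.fluxes == b.fluxes
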