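import itertools

import numpy as np
import pytest
from cobra import Metabolite, Model, Reaction
from hypothesis import given, settings, strategies as st

from levogut.network import (
    AMINO_ACIDS,
    NetworkError,
    StoichiometricNetwork,
    TransporterCatalog,
    add_levodopa_module,
    apply_competition_bounds,
    build_reduced_siec,
    extend_brain_kidney,
    fba,
    load_network,
    write_network,
)


def _flux_balance_residual(net, fluxes):
    """Max |S v| over metabolites, computed from raw stoichiometry."""
    residual = {m.id: 0.0 for m in net.model.metabolites}
    for rxn in net.model.reactions:
        v = fluxes[rxn.id]
        for met, coeff in rxn.metabolites.items():
            residual[met.id] += coeff * v
    return max(abs(r) for r in residual.values())


def enumerate_lp_optimum(S, lb, ub, c):
    """Brute-force LP oracle: max c'v s.t. S v = 0, lb <= v <= ub.

    Enumerates candidate vertices by fixing n - rank(S) variables at their
    bounds and solving the remaining square system.  Only valid for tiny
    networks (n <= 6).
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    n_fix = n - rank
    best = None
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(bounds_choice) if fixed else np.zeros(m)
            A = S[:, free]
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.zeros(n)
            for j, val in zip(fixed, bounds_choice):
                v[j] = val
            for j, val in zip(free, sol):
                v[j] = val
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < np.array(lb) - 1e-8) or np.any(v > np.array(ub) + 1e-8):
                continue
            val = float(np.dot(c, v))
            if best is None or val > best:
                best = val
    return best


def _chain_model(bounds):
    """A -> B -> C chain with exchange at both ends."""
    model = Model("chain")
    a = Metabolite("A", compartment="c")
    b = Metabolite("B", compartment="c")
    rxns = []
    r_in = Reaction("R_in", lower_bound=bounds["R_in"][0], upper_bound=bounds["R_in"][1])
    r_in.add_metabolites({a: 1.0})
    r_ab = Reaction("R_ab", lower_bound=bounds["R_ab"][0], upper_bound=bounds["R_ab"][1])
    r_ab.add_metabolites({a: -1.0, b: 1.0})
    r_out = Reaction("R_out", lower_bound=bounds["R_out"][0], upper_bound=bounds["R_out"][1])
    r_out.add_metabolites({b: -1.0})
    model.add_reactions([r_in, r_ab, r_out])
    return StoichiometricNetwork(model=model)


class TestReducedNetwork:
    def test_deterministic_build(self):
        n1, n2 = build_reduced_siec(), build_reduced_siec()
        ids1 = [(r.id, r.lower_bound, r.upper_bound) for r in n1.model.reactions]
        ids2 = [(r.id, r.lower_bound, r.upper_bound) for r in n2.model.reactions]
        assert ids1 == ids2

    def test_biomass_feasible(self):
        net = build_reduced_siec()
        sol = fba(net, "BIOMASS_maintenance", minimize_total_flux=False)
        assert sol.optimal and sol.objective_value > 0

    def test_closed_network_admits_only_zero_flux(self):
        net = build_reduced_siec()
        closed = {r.id: (0.0, 0.0) for r in net.model.reactions
                  if r.id.startswith("EX_")}
        sol = fba(net, "BIOMASS_maintenance", extra_bounds=closed)
        assert sol.optimal
        assert max(abs(v) for v in sol.fluxes) <= 1e-9


class TestLevodopaModule:
    def test_adds_exactly_36_reactions(self):
        net = build_reduced_siec()
        n0 = net.n_reactions
        add_levodopa_module(net)
        assert net.n_reactions - n0 == 36

    def test_antiport_reactions_are_one_to_one(self, siec_with_module):
        for rxn in siec_with_module.model.reactions:
            if "ANTIPORT" in rxn.id:
                coeffs = sorted(rxn.metabolites.values())
                assert coeffs == [-1.0, -1.0, 1.0, 1.0]

    def test_duplicate_application_rejected(self, siec_with_module):
        with pytest.raises(NetworkError, match="already"):
            add_levodopa_module(siec_with_module)

    def test_catalog_anchor_invariants(self):
        ranks = dict(TransporterCatalog().luminal_affinity)
        ranks["cystine"], ranks["ala"] = ranks["ala"], ranks["cystine"]
        with pytest.raises(NetworkError, match="cystine"):
            TransporterCatalog(luminal_affinity=ranks).validate()


class TestFBA:
    def test_bottleneck_chain(self):
        net = _chain_model({"R_in": (0, 5), "R_ab": (0, 100), "R_out": (0, 100)})
        sol = fba(net, "R_out")
        assert sol.objective_value == pytest.approx(5.0)

    def test_secretion_equals_uptake_bound(self, siec_with_module):
        u = 3.0
        bounds = apply_competition_bounds(siec_with_module, {}, 1.0)
        bounds["EX_levodopa_l"] = (-u, 0.0)
        sol = fba(siec_with_module, "EX_levodopa_b", extra_bounds=bounds)
        # no internal loss path: everything taken up is secreted
        assert sol.objective_value == pytest.approx(u, abs=1e-9)

    def test_infeasible_bounds_reported(self):
        net = _chain_model({"R_in": (0, 5), "R_ab": (10, 100), "R_out": (0, 100)})
        sol = fba(net, "R_out")
        assert sol.status == "infeasible"

    def test_unknown_objective(self, siec_with_module):
        with pytest.raises(NetworkError):
            fba(siec_with_module, "NOPE")

    def test_steady_state_and_bounds_respected(self, siec_with_module):
        bounds = apply_competition_bounds(siec_with_module, {"leu": 2.0}, 1.0)
        bounds["EX_levodopa_l"] = (-4.0, 0.0)
        sol = fba(siec_with_module, "EX_levodopa_b", extra_bounds=bounds)
        assert _flux_balance_residual(siec_with_module, sol.fluxes) <= 1e-9
        with siec_with_module.model as m:
            for rid, (lb, ub) in bounds.items():
                if rid in m.reactions:
                    v = sol.fluxes[rid]
                    assert lb - 1e-9 <= v <= ub + 1e-9

    def test_uniporter_split_four_fifths(self, siec_with_module):
        bounds = {"EX_levodopa_l": (-5.0, 0.0)}
        sol = fba(siec_with_module, "EX_levodopa_b", extra_bounds=bounds)
        uni = sol.fluxes["LDOPA_BASO_UNIPORT"]
        total = sol.objective_value
        assert total > 0
        assert uni / total == pytest.approx(0.8, abs=1e-6)

    def test_lp_matches_vertex_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ub_in = rng.uniform(1.0, 10.0)
            ub_ab = rng.uniform(1.0, 10.0)
            net = _chain_model({"R_in": (0, ub_in), "R_ab": (0, ub_ab),
                                "R_out": (0, 100)})
            sol = fba(net, "R_out")
            S = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
            oracle = enumerate_lp_optimum(S, [0, 0, 0], [ub_in, ub_ab, 100], [0, 0, 1])
            assert sol.objective_value == pytest.approx(oracle, abs=1e-9)


class TestCompetition:
    def test_sole_substrate_gets_full_capacity(self, siec_with_module):
        b = apply_competition_bounds(siec_with_module, {}, 1.0, v_t=15.0)
        assert b["luminal_carrier_cap"] == (0.0, 15.0)

    def test_saturating_cystine_blocks_levodopa(self, siec_with_module):
        b = apply_competition_bounds(siec_with_module, {"cystine": 1000.0}, 1.0,
                                     v_t=15.0)
        assert b["luminal_carrier_cap"][1] < 0.05 * 15.0

    def test_ornithine_competes_less_than_cystine(self, siec_with_module):
        b_orn = apply_competition_bounds(siec_with_module, {"orn": 1.0}, 1.0)
        b_cys = apply_competition_bounds(siec_with_module, {"cystine": 1.0}, 1.0)
        assert b_orn["luminal_carrier_cap"][1] > b_cys["luminal_carrier_cap"][1]

    def test_unknown_species_rejected(self, siec_with_module):
        with pytest.raises(NetworkError, match="selenocysteine"):
            apply_competition_bounds(siec_with_module, {"selenocysteine": 1.0}, 1.0)

    @given(st.floats(min_value=0.0, max_value=100.0),
           st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_competitor_amount(self, siec_with_module_session, a1, a2):
        lo, hi = sorted((a1, a2))
        b_lo = apply_competition_bounds(siec_with_module_session, {"leu": lo}, 1.0)
        b_hi = apply_competition_bounds(siec_with_module_session, {"leu": hi}, 1.0)
        assert b_hi["luminal_carrier_cap"][1] <= b_lo["luminal_carrier_cap"][1] + 1e-12


class TestTransStimulation:
    def test_basolateral_availability_raises_max_secretion(self, siec_with_module):
        fluxes = []
        for cap in (0.1, 0.5, 2.0):
            bounds = {"EX_levodopa_l": (-10.0, 0.0),
                      "baso_antiporter_cap": (0.0, cap)}
            sol = fba(siec_with_module, "EX_levodopa_b", extra_bounds=bounds)
            fluxes.append(sol.objective_value)
        assert fluxes[0] <= fluxes[1] <= fluxes[2]
        assert fluxes[0] < fluxes[2]


class TestBrainKidneyExtension:
    def test_requires_levodopa_module(self):
        with pytest.raises(NetworkError, match="module"):
            extend_brain_kidney(build_reduced_siec())

    def test_brain_delivery_objective_usable(self, siec_with_module):
        extend_brain_kidney(siec_with_module)
        bounds = {"EX_levodopa_l": (-5.0, 0.0),
                  "baso_antiporter_cap": (0.0, 1000.0)}
        sol = fba(siec_with_module, "LDOPA_BRAIN_UPTAKE", extra_bounds=bounds)
        assert sol.optimal and sol.objective_value > 0

    def test_zero_influx_zero_brain_delivery(self, siec_with_module):
        extend_brain_kidney(siec_with_module)
        sol = fba(siec_with_module, "LDOPA_BRAIN_UPTAKE",
                  extra_bounds={"EX_levodopa_l": (0.0, 0.0)})
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_route_fluxes_sum_to_absorbed(self, siec_with_module):
        extend_brain_kidney(siec_with_module)
        bounds = {"EX_levodopa_l": (-5.0, 0.0),
                  "EX_levodopa_b": (0.0, 0.0),
                  "baso_antiporter_cap": (0.0, 1000.0),
                  "LDOPA_GUTWALL_MET": (0.0, 1000.0)}
        sol = fba(siec_with_module, "LDOPA_BRAIN_UPTAKE", extra_bounds=bounds)
        absorbed = -sol.fluxes["EX_levodopa_l"]
        routed = (sol.fluxes["LDOPA_BRAIN_UPTAKE"]
                  + sol.fluxes["LDOPA_RENAL_ELIM"]
                  + sol.fluxes["SINK_levodopa_sys"]
                  + sol.fluxes["LDOPA_GUTWALL_MET"])
        assert routed == pytest.approx(absorbed, abs=1e-9)


class TestSBMLRoundTrip:
    def test_roundtrip_preserves_structure(self, siec_with_module, tmp_path):
        path = str(tmp_path / "net.xml")
        write_network(siec_with_module, path)
        loaded = load_network(path)
        assert loaded.n_reactions == siec_with_module.n_reactions
        assert loaded.n_metabolites == siec_with_module.n_metabolites
        for rxn in siec_with_module.model.reactions:
            other = loaded.model.reactions.get_by_id(rxn.id)
            assert other.bounds == rxn.bounds
            assert {m.id: c for m, c in other.metabolites.items()} == \
                {m.id: c for m, c in rxn.metabolites.items()}

    def test_coupling_constraints_reattached(self, siec_with_module, tmp_path):
        path = str(tmp_path / "net.xml")
        write_network(siec_with_module, path)
        loaded = load_network(path)
        assert "levodopa_secretion_split" in loaded.model.solver.constraints

    def test_malformed_sbml_reported(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<sbml>this is not valid</sbml>")
        with pytest.raises(NetworkError, match="parse"):
            load_network(str(path))
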