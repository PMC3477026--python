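"""The weighted-deviation fit, FVA direction assignment and centring."""

import numpy as np
import pytest

from conftest import BOUND, build_model, chain_model
from transflux.expression import ExpressionProfile, ReactionWeights, map_expression
from transflux.fit import (
    center_solution,
    fva_under_objective,
    initial_problem,
    iterative_fit,
    scale_to_glucose,
    solve_weighted_fit,
)
from transflux.lp import InfeasibleError


def chain_weights():
    return ReactionWeights(
        d={"R1": 2.0, "R2": 2.0}, sigma={"R1": 1.0, "R2": 1.0}, has_data={"R1", "R2"}
    )


def open_chain_model(cap_r1: float = BOUND):
    """A -> B -> C with exchanges on every metabolite (R1 and R2 decouple)."""
    return build_model(
        [
            ("EX_A", {"A": -1}, -BOUND, 0.0, None),
            ("R1", {"A": -1, "B": 1}, 0.0, cap_r1, "g1"),
            ("EX_B", {"B": -1}, -BOUND, BOUND, None),
            ("R2", {"B": -1, "C": 1}, 0.0, BOUND, "g2"),
            ("EX_C", {"C": -1}, 0.0, BOUND, None),
        ],
        ["A", "B", "C"],
    )


def grid_oracle_open_chain(cap: float) -> tuple[float, tuple[float, float]]:
    """Exhaustive grid minimiser of Z over (v_R1, v_R2) in {0, 0.1, ..., 4}^2.

    With an unbounded exchange at B the two internal fluxes are independent,
    so the full 2D grid is searched.
    """
    best = (np.inf, (None, None))
    for t1 in np.arange(0.0, 4.0001, 0.1):
        if t1 > cap + 1e-12:
            continue
        for t2 in np.arange(0.0, 4.0001, 0.1):
            z = abs(t1 - 2.0) + abs(t2 - 2.0)
            if z < best[0]:
                best = (z, (t1, t2))
    return best


@pytest.mark.parametrize(
    "cap, z_expected, v_expected", [(BOUND, 0.0, (2.0, 2.0)), (1.0, 1.0, (1.0, 2.0))]
)
def test_weighted_fit_matches_grid_oracle(cap, z_expected, v_expected):
    model = open_chain_model(cap_r1=cap)
    problem = initial_problem(model, chain_weights())
    zstar, v = solve_weighted_fit(problem)
    oracle_z, oracle_v = grid_oracle_open_chain(cap)
    assert zstar == pytest.approx(oracle_z, abs=1e-9)
    assert zstar == pytest.approx(z_expected, abs=1e-9)
    assert v[model.reaction_index("R1")] == pytest.approx(oracle_v[0], abs=1e-9)
    assert v[model.reaction_index("R2")] == pytest.approx(v_expected[1], abs=1e-9)


def test_weighted_fit_on_strict_chain_pays_double_deviation():
    """Without an exchange at B, steady state couples R1 = R2, so capping R1
    at 1 costs a deviation on both scored reactions (Z* = 2)."""
    model = chain_model(cap_r1=1.0)
    zstar, v = solve_weighted_fit(initial_problem(model, chain_weights()))
    grid = [2 * abs(t - 2.0) for t in np.arange(0.0, 4.0001, 0.1) if t <= 1.0 + 1e-12]
    assert zstar == pytest.approx(min(grid), abs=1e-9) == pytest.approx(2.0)
    assert v[model.reaction_index("R2")] == pytest.approx(1.0, abs=1e-9)


def test_empty_scored_set_returns_zero_flux():
    model = chain_model()
    problem = initial_problem(model, ReactionWeights())
    zstar, v = solve_weighted_fit(problem)
    assert zstar == 0.0
    assert np.allclose(v, 0.0)


def test_infeasible_bounds_raise():
    model = chain_model()
    # force the chain to run while capping its middle step to zero
    model.lower_bounds[model.reaction_index("EX_C")] = 5.0
    model.upper_bounds[model.reaction_index("R1")] = 0.0
    problem = initial_problem(model, chain_weights())
    with pytest.raises(InfeasibleError):
        solve_weighted_fit(problem)


# -- FVA under the optimal objective -------------------------------------------


def reversible_route_model(flip_r2: bool = False):
    """A scored demand reachable only through reversible reactions.

    R3 (irreversible, d = 5) forces flux through reversible R1 and R2; with
    ``flip_r2`` the R2 stoichiometry is written C -> B so the required net
    flux is negative.
    """
    r2 = ("R2", {"C": -1, "B": 1}, -BOUND, BOUND, "g2") if flip_r2 else (
        "R2",
        {"B": -1, "C": 1},
        -BOUND,
        BOUND,
        "g2",
    )
    return build_model(
        [
            ("EX_A", {"A": -1}, -BOUND, 0.0, None),
            ("R1", {"A": -1, "B": 1}, -BOUND, BOUND, "g1"),
            r2,
            ("R3", {"C": -1, "D": 1}, 0.0, BOUND, "g3"),
            ("EX_D", {"D": -1}, 0.0, BOUND, None),
        ],
        ["A", "B", "C", "D"],
    )


def route_weights():
    return ReactionWeights(
        d={"R1": 5.0, "R2": 5.0, "R3": 5.0},
        sigma={"R1": 1.0, "R2": 1.0, "R3": 1.0},
        has_data={"R1", "R2", "R3"},
    )


def test_fva_classifies_forced_reversible_reaction_forward():
    model = reversible_route_model()
    problem = initial_problem(model, route_weights())
    assert problem.scored_set == {"R3"}  # only the irreversible reaction scores
    zstar, _ = solve_weighted_fit(problem)
    ranges = fva_under_objective(problem, zstar, tol=1e-9)
    lo, hi = ranges["R1"]
    assert lo > 1e-6  # must run forward to satisfy the scored demand
    lo3, _ = ranges["R3"]
    assert lo3 >= -1e-9  # already-irreversible reaction trivially bounded

    # independent check: forcing R1 backward makes the demand unreachable
    forced = initial_problem(model, route_weights())
    forced.upper_bounds[model.reaction_index("R1")] = 0.0
    z_forced, _ = solve_weighted_fit(forced)
    assert z_forced > zstar + 1.0


def test_decoupled_reversible_cycle_stays_reversible():
    model = build_model(
        [
            ("L1", {"E": -1, "F": 1}, -BOUND, BOUND, None),
            ("L2", {"F": -1, "E": 1}, -BOUND, BOUND, None),
        ],
        ["E", "F"],
    )
    problem = initial_problem(model, ReactionWeights())
    zstar, _ = solve_weighted_fit(problem)
    ranges = fva_under_objective(problem, zstar)
    for rid in ("L1", "L2"):
        lo, hi = ranges[rid]
        assert lo < -1 and hi > 1


# -- the iterative direction assignment ------------------------------------------


def test_all_irreversible_model_terminates_in_one_pass():
    model = chain_model()
    result = iterative_fit(model, chain_weights())
    assert result.iterations == 1
    assert len(result.irreversible_trace) == 1


@pytest.mark.parametrize("flip_r2", [False, True])
def test_directions_forced_by_scored_demand_are_recovered(flip_r2):
    model = reversible_route_model(flip_r2=flip_r2)
    result = iterative_fit(model, route_weights())
    dirs = result.problem.direction_map
    assert dirs["R1"] == +1
    assert dirs["R2"] == (-1 if flip_r2 else +1)
    # trace grows monotonically, then repeats once at termination
    trace = result.irreversible_trace
    assert all(b >= a for a, b in zip(trace, trace[1:]))
    assert len(trace) >= 2 and trace[-1] == trace[-2]
    # newly committed reactions were added to the scored set with their sign
    assert result.scored_count == 3
    v = result.flux
    sign = -1 if flip_r2 else 1
    assert v[model.reaction_index("R2")] == pytest.approx(sign * 5.0, abs=1e-6)


def test_objective_is_reproduced_by_direct_recomputation(overflow):
    """Z* equals sum (1/sigma)|v_i - s_i d_i| evaluated at the returned flux."""
    from transflux.fit import ExpressionFluxModel

    res = ExpressionFluxModel(overflow["model"], profile=overflow["profile"]).fit()
    problem = res.fit_result.problem
    v = res.fit_result.flux
    z = sum(
        abs(v[overflow["model"].reaction_index(r)] - problem.direction_map[r] * problem.weights.d[r])
        / problem.weights.sigma[r]
        for r in problem.scored_set
    )
    assert z == pytest.approx(res.objective, abs=1e-6 + 1e-6 * abs(res.objective))


def test_steady_state_residual_of_all_outputs(overflow):
    from transflux.fit import ExpressionFluxModel

    res = ExpressionFluxModel(overflow["model"], profile=overflow["profile"]).fit()
    assert res.steady_state_residual() <= 1e-6
    N = overflow["model"].stoichiometry
    assert np.max(np.abs(N @ res.fit_result.flux)) <= 1e-6


# -- geometric centring ------------------------------------------------------------


def two_cycle_model(b1=(-3.0, 7.0), b2=(1.0, 5.0)):
    return build_model(
        [
            ("C1a", {"D": -1, "E": 1}, b1[0], b1[1], None),
            ("C1b", {"E": -1, "D": 1}, -BOUND, BOUND, None),
            ("C2a", {"F": -1, "G": 1}, b2[0], b2[1], None),
            ("C2b", {"G": -1, "F": 1}, -BOUND, BOUND, None),
        ],
        ["D", "E", "F", "G"],
    )


def test_center_of_box_shaped_face_is_the_midpoint():
    """Two independent cycles make the optimal set a 2D box; centre = midpoint."""
    model = two_cycle_model()
    problem = initial_problem(model, ReactionWeights())
    v = center_solution(problem, zstar=0.0)
    idx = {r: model.reaction_index(r) for r in model.reaction_ids}
    assert v[idx["C1a"]] == pytest.approx(2.0, abs=1e-5)
    assert v[idx["C1b"]] == pytest.approx(2.0, abs=1e-5)
    assert v[idx["C2a"]] == pytest.approx(3.0, abs=1e-5)
    assert v[idx["C2b"]] == pytest.approx(3.0, abs=1e-5)


def test_center_of_singleton_polytope_is_that_point():
    model = chain_model()
    i = model.reaction_index("EX_A")
    model.lower_bounds[i] = model.upper_bounds[i] = -2.0
    problem = initial_problem(model, ReactionWeights())
    v = center_solution(problem, zstar=0.0)
    expected = {"EX_A": -2.0, "R1": 2.0, "R2": 2.0, "EX_C": 2.0}
    for rid, val in expected.items():
        assert v[model.reaction_index(rid)] == pytest.approx(val, abs=1e-5)


def test_center_of_symmetric_cycle_carries_no_net_flux():
    model = two_cycle_model(b1=(-5.0, 5.0), b2=(-8.0, 8.0))
    problem = initial_problem(model, ReactionWeights())
    v = center_solution(problem, zstar=0.0)
    assert np.allclose(v, 0.0, atol=1e-5)


def test_centring_is_deterministic(overflow):
    from transflux.fit import ExpressionFluxModel

    m = ExpressionFluxModel(overflow["model"], profile=overflow["profile"])
    v1 = m.fit().fluxes.to_numpy()
    v2 = m.fit().fluxes.to_numpy()
    assert np.array_equal(v1, v2)


# -- glucose rescaling -----------------------------------------------------------


def test_scale_doubles_when_uptake_half_of_measured(overflow):
    model = overflow["model"]
    v = overflow["v_star"].copy()
    scaled = scale_to_glucose(v, model, measured_uptake=20.0)
    assert np.allclose(scaled, 2.0 * v)
    assert scaled[model.reaction_index("EX_glc")] == pytest.approx(-20.0)


def test_scale_identity_when_predicted_equals_measured(overflow):
    model = overflow["model"]
    v = overflow["v_star"]
    assert np.allclose(scale_to_glucose(v, model, 10.0), v)


@pytest.mark.parametrize("c", [0.1, 3.7, 250.0])
def test_scaled_fluxes_invariant_to_prescaling(overflow, c):
    model = overflow["model"]
    v = overflow["v_star"]
    assert np.allclose(
        scale_to_glucose(c * v, model, 10.0), scale_to_glucose(v, model, 10.0)
    )


def test_scale_errors_on_zero_glucose_flux(overflow):
    model = overflow["model"]
    with pytest.raises(ValueError, match="zero"):
        scale_to_glucose(np.zeros(model.n_reactions), model, 10.0)
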