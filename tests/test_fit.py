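"""LAD fit: split system, LP solution against brute-force oracles, constraints."""

import numpy as np
import pytest

from fluxcordance.fit import (
    FitConstraints,
    RatioConstraint,
    build_split_system,
    linearize_ratio,
    solve_lad,
)
from fluxcordance.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionRole,
    steady_state_residual,
)

from conftest import reaction_data_from_dict


# ---------------------------------------------------------------------------
# split system
# ---------------------------------------------------------------------------


def test_split_identity_for_irreversible(chain):
    split = build_split_system(chain)
    assert split.n_vars == 3
    v = np.array([0.1, 0.2, 0.3])
    y = split.embed(v)
    assert np.allclose(split.net(y), v)
    assert np.allclose(split.activity(y), v)


def test_split_counts_and_reconstruction():
    mets = [Metabolite("A", "cytosol"), Metabolite("B", "cytosol")]
    rxns = [
        Reaction("r1", 1, {"A": 1.0}, 0, 10),
        Reaction("r2", 2, {"A": -1.0, "B": 1.0}, -10, 10),  # reversible
        Reaction("r3", 3, {"B": -1.0}, 0, 10),
    ]
    model = MetabolicModel(name="m", metabolites=mets, reactions=rxns)
    split = build_split_system(model)
    assert split.n_vars == 4  # 1 reversible -> 2 vars, plus 2 irreversible
    y = np.zeros(4)
    y[split.pos[1]] = 0.3
    y[split.neg[1]] = 0.1
    assert split.net(y)[1] == pytest.approx(0.2)
    assert split.activity(y)[1] == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# solve_lad against hand/brute-force results
# ---------------------------------------------------------------------------


def test_perfect_fit_chain(chain):
    data = reaction_data_from_dict(chain, {"R_in": 0.5, "R_conv": 0.5, "R_out": 0.5})
    fit = solve_lad(chain, data)
    assert fit.status == "optimal"
    assert fit.z_star == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(fit.v_star, 0.5, atol=1e-7)


def brute_force_chain_objective(d, w, ts):
    """Chain flux is one-dimensional: objective as a function of common flux t."""
    return sum(wi * np.abs(ts - di) for di, wi in zip(d, w))


def test_chain_partial_data_matches_scan(chain):
    """d=(1.0, 0.2) on reactions 1-2: z* = 0.8, argmin is t in [0.2, 1.0]."""
    data = reaction_data_from_dict(chain, {"R_in": 1.0, "R_conv": 0.2})
    fit = solve_lad(chain, data)
    ts = np.linspace(0, 10, 100001)
    obj = brute_force_chain_objective([1.0, 0.2], [1.0, 1.0], ts)
    assert fit.z_star == pytest.approx(obj.min(), abs=1e-6)
    assert fit.z_star == pytest.approx(0.8, abs=1e-8)
    t = fit.v_star[0]
    assert 0.2 - 1e-8 <= t <= 1.0 + 1e-8
    assert np.allclose(fit.v_star, t, atol=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_chain_random_data_matches_scan(chain, seed):
    """Optimality certificate: LP optimum equals a dense 1-D scan."""
    rng = np.random.default_rng(seed)
    d = rng.uniform(0, 1.2, size=3)
    w = rng.uniform(0.5, 2.0, size=3)
    data = reaction_data_from_dict(
        chain,
        dict(zip(chain.reaction_ids, d)),
        w=dict(zip(chain.reaction_ids, w)),
    )
    fit = solve_lad(chain, data)
    ts = np.linspace(0, 2, 200001)
    obj = brute_force_chain_objective(d, w, ts)
    assert fit.z_star == pytest.approx(obj.min(), abs=1e-5)


def test_solution_satisfies_all_constraints():
    from fluxcordance.synth import make_scenario
    from fluxcordance.model import reduce_model
    from fluxcordance.expression import reaction_data_from_expression

    sc = make_scenario(11)
    model = reduce_model(sc.model)
    data = reaction_data_from_expression(model, sc.expr_a)
    fit = solve_lad(model, data, sc.constraints)
    assert fit.status == "optimal"
    assert steady_state_residual(model, fit.v_star) <= 1e-6
    lb, ub = model.bounds()
    assert np.all(fit.v_star >= lb - 1e-6) and np.all(fit.v_star <= ub + 1e-6)
    for rid, minv in sc.constraints.min_flux_map(model).items():
        assert fit.v_star[model.reaction_position(rid)] >= minv - 1e-6


def test_infeasible_biomass_reported():
    mets = [Metabolite("A", "cytosol")]
    rxns = [
        Reaction("EX_in", 1, {"A": 1.0}, 0, 0.5, role=ReactionRole.EXCHANGE),
        Reaction("BIO", 2, {"A": -1.0}, 0, 0.5, role=ReactionRole.BIOMASS),
    ]
    model = MetabolicModel(name="m", metabolites=mets, reactions=rxns)
    data = reaction_data_from_dict(model, {"EX_in": 0.1})
    fit = solve_lad(model, data, FitConstraints(biomass_min=1.0))
    assert fit.status == "infeasible"
    assert fit.v_star is None


def test_weight_scaling_preserves_argmin(chain):
    data1 = reaction_data_from_dict(chain, {"R_in": 1.0, "R_conv": 0.2})
    data5 = reaction_data_from_dict(
        chain, {"R_in": 1.0, "R_conv": 0.2}, w={"R_in": 5.0, "R_conv": 5.0}
    )
    f1, f5 = solve_lad(chain, data1), solve_lad(chain, data5)
    assert f5.z_star == pytest.approx(5 * f1.z_star, rel=1e-9)


# ---------------------------------------------------------------------------
# ratio constraints
# ---------------------------------------------------------------------------


def test_linearize_ratio_rows():
    rc = RatioConstraint(numerator="vC", denominator="vO", r_lb=1.5, r_ub=4.0)
    rows = linearize_ratio(rc)
    # at vO = 1: feasible vC interval is exactly [1.5, 4]
    for vc, expect in ((1.4, False), (1.5, True), (4.0, True), (4.1, False)):
        ok = all(
            coeffs.get("vC", 0) * vc + coeffs.get("vO", 0) * 1.0 <= rhs + 1e-12
            for coeffs, rhs in rows
        )
        assert ok == expect
    # at vO = 0 both rows force vC = 0
    assert all(coeffs.get("vC", 0) * 0.0 <= rhs for coeffs, rhs in rows)
    lo_row, hi_row = rows
    assert lo_row[0] == {"vO": 1.5, "vC": -1.0}
    assert hi_row[0] == {"vC": 1.0, "vO": -4.0}


def test_ratio_equality_case(parallel_routes):
    """r_lb = r_ub = 2 pins vC = 2 vO exactly in the fit."""
    data = reaction_data_from_dict(parallel_routes, {"EX_in": 0.9, "R_C": 0.3, "R_O": 0.3})
    cons = FitConstraints(
        ratio_constraints=[RatioConstraint("R_C", "R_O", 2.0, 2.0)]
    )
    fit = solve_lad(parallel_routes, data, cons)
    assert fit.status == "optimal"
    vc = fit.v_star[parallel_routes.reaction_position("R_C")]
    vo = fit.v_star[parallel_routes.reaction_position("R_O")]
    assert vc == pytest.approx(2.0 * vo, abs=1e-8)


def test_ratio_validation():
    with pytest.raises(ValueError, match="r_lb"):
        RatioConstraint("vC", "vO", 4.0, 1.5)


def test_ratio_on_reversible_rejected():
    mets = [Metabolite("A", "cytosol"), Metabolite("B", "cytosol")]
    rxns = [
        Reaction("r1", 1, {"A": 1.0}, 0, 10),
        Reaction("r2", 2, {"A": -1.0, "B": 1.0}, -10, 10),
        Reaction("r3", 3, {"B": -1.0}, 0, 10),
    ]
    model = MetabolicModel(name="m", metabolites=mets, reactions=rxns)
    cons = FitConstraints(ratio_constraints=[RatioConstraint("r1", "r2", 1.5, 4.0)])
    with pytest.raises(ValueError, match="reversible"):
        cons.min_flux_map(model)
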