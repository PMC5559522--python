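"""FVA over the optimal face and hit-and-run sampling, against brute force."""

import numpy as np
import pytest
from scipy import stats as sps

from fluxcordance.fit import solve_lad
from fluxcordance.model import MetabolicModel, Metabolite, Reaction, ReactionRole
from fluxcordance.optima import (
    OptimalSpace,
    build_optimal_space,
    calibrate_min_bound,
    check_sample,
    fva_over_optima,
    sample_optima,
)

from conftest import reaction_data_from_dict


def chain_space(chain, d, w=None, **kw):
    data = reaction_data_from_dict(chain, d, w=w)
    return build_optimal_space(chain, data, **kw)


# ---------------------------------------------------------------------------
# FVA vs brute-force argmin-set oracles
# ---------------------------------------------------------------------------


def chain_argmin_interval(d, w, lo=0.0, hi=10.0, n=2_000_001, tol=1e-9):
    """Brute-force oracle: the chain's optimal set as an interval of t."""
    ts = np.linspace(lo, hi, n)
    obj = sum(wi * np.abs(ts - di) for di, wi in zip(d, w))
    zmin = obj.min()
    sel = ts[obj <= zmin + tol]
    return zmin, sel.min(), sel.max()


def test_fva_chain_interval(chain):
    space = chain_space(chain, {"R_in": 1.0, "R_conv": 0.2})
    rng = fva_over_optima(space)
    zmin, tmin, tmax = chain_argmin_interval([1.0, 0.2], [1.0, 1.0], hi=2.0)
    assert space.z_star == pytest.approx(zmin, abs=1e-6)
    assert np.allclose(rng.v_min, tmin, atol=1e-5)
    assert np.allclose(rng.v_max, tmax, atol=1e-5)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fva_chain_random_data_matches_oracle(chain, seed):
    rng_ = np.random.default_rng(seed)
    d = dict(zip(chain.reaction_ids, rng_.uniform(0, 1.5, 3)))
    w = dict(zip(chain.reaction_ids, rng_.uniform(0.5, 2.0, 3)))
    space = chain_space(chain, d, w=w)
    rng = fva_over_optima(space)
    zmin, tmin, tmax = chain_argmin_interval(
        [d[r] for r in chain.reaction_ids], [w[r] for r in chain.reaction_ids], hi=3.0
    )
    assert np.allclose(rng.v_min, tmin, atol=1e-4)
    assert np.allclose(rng.v_max, tmax, atol=1e-4)


def test_fva_singleton_polytope(chain):
    """Full data pins the chain: v_min = v_max = v* componentwise."""
    space = chain_space(chain, {"R_in": 0.5, "R_conv": 0.5, "R_out": 0.5})
    rng = fva_over_optima(space)
    assert np.allclose(rng.v_min, space.fit.v_star, atol=1e-6)
    assert np.allclose(rng.v_max, space.fit.v_star, atol=1e-6)
    assert np.all(rng.width() <= 1e-6)


def test_fva_free_cycle_spans_bounds(branched_cycle):
    """A data-free internal 2-cycle ranges over its full bounds."""
    data = reaction_data_from_dict(
        branched_cycle, {"R_in": 0.5, "R_conv": 0.5, "R_out": 0.5}
    )
    space = build_optimal_space(branched_cycle, data)
    rng = fva_over_optima(space)
    # brute force: backbone pinned at 0.5, cycle flux c free in [0, 10],
    # with v_bc = v_cb = c by the C-balance
    for rid in ("R_bc", "R_cb"):
        j = branched_cycle.reaction_position(rid)
        assert rng.v_min[j] == pytest.approx(0.0, abs=1e-6)
        assert rng.v_max[j] == pytest.approx(10.0, abs=1e-5)
    for rid in ("R_in", "R_conv", "R_out"):
        j = branched_cycle.reaction_position(rid)
        assert rng.width()[j] <= 1e-6


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def test_sample_singleton_returns_copies(chain):
    space = chain_space(chain, {"R_in": 0.5, "R_conv": 0.5, "R_out": 0.5})
    sample = sample_optima(space, n=50, seed=3, warmup=100, thin=2)
    assert sample.values.shape == (50, 3)
    assert np.allclose(sample.values, space.fit.v_star, atol=1e-6)


def test_sample_covers_interval(chain):
    space = chain_space(chain, {"R_in": 1.0, "R_conv": 0.2})
    sample = sample_optima(space, n=5000, seed=11, warmup=500, thin=2)
    v1 = sample.column("R_in")
    assert v1.min() == pytest.approx(0.2, abs=0.02)
    assert v1.max() == pytest.approx(1.0, abs=0.02)


def test_sample_uniform_on_interval(chain):
    """KS distance to the uniform law on the 1-D optimal interval < 0.05."""
    space = chain_space(chain, {"R_in": 1.0, "R_conv": 0.2})
    sample = sample_optima(space, n=5000, seed=7, warmup=1000, thin=2)
    v1 = sample.column("R_in")
    ks = sps.kstest(v1, "uniform", args=(0.2, 0.8)).statistic
    assert ks < 0.05


def test_seed_determinism(chain):
    space = chain_space(chain, {"R_in": 1.0, "R_conv": 0.2})
    s1 = sample_optima(space, n=200, seed=5, warmup=100, thin=3)
    s2 = sample_optima(space, n=200, seed=5, warmup=100, thin=3)
    s3 = sample_optima(space, n=200, seed=6, warmup=100, thin=3)
    assert np.array_equal(s1.values, s2.values)
    assert not np.array_equal(s1.values, s3.values)


def test_sample_n_equals_one(chain):
    space = chain_space(chain, {"R_in": 1.0, "R_conv": 0.2})
    s = sample_optima(space, n=1, seed=0, warmup=10, thin=1)
    assert s.values.shape == (1, 3)
    diag = check_sample(space, s)
    assert diag["max_steady_state_residual"] <= 1e-6


def test_sample_within_fva_and_diagnostics(branched_cycle):
    data = reaction_data_from_dict(branched_cycle, {"R_in": 1.0, "R_conv": 0.2})
    space = build_optimal_space(branched_cycle, data)
    sample = sample_optima(space, n=1000, seed=2, warmup=300, thin=2)
    rng = fva_over_optima(space)
    assert np.all(sample.values >= rng.v_min[None, :] - 1e-6)
    assert np.all(sample.values <= rng.v_max[None, :] + 1e-6)
    diag = check_sample(space, sample)
    assert diag["max_steady_state_residual"] <= 1e-6
    assert diag["max_bound_violation"] <= 1e-6
    assert diag["max_objective_excess"] <= 1e-6
    assert diag["fraction_outside_fva"] == 0.0


def test_check_sample_flags_corruption(chain):
    space = chain_space(chain, {"R_in": 1.0, "R_conv": 0.2})
    sample = sample_optima(space, n=100, seed=1, warmup=100, thin=1)
    sample.values[0, 0] = 50.0  # above ub = 10
    diag = check_sample(space, sample)
    assert diag["max_bound_violation"] > 1.0
    assert diag["fraction_outside_fva"] > 0.0


def test_check_sample_other_space_outside_fva(chain):
    space_a = chain_space(chain, {"R_in": 1.0, "R_conv": 0.9})
    space_b = chain_space(chain, {"R_in": 0.1, "R_conv": 0.1, "R_out": 0.1})
    sample_b = sample_optima(space_b, n=100, seed=1, warmup=100, thin=1)
    diag = check_sample(space_a, sample_b)
    assert diag["fraction_outside_fva"] == 1.0


# ---------------------------------------------------------------------------
# calibrated minimum bounds
# ---------------------------------------------------------------------------


def test_calibrate_min_bound_fraction(chain):
    space = chain_space(chain, {"R_in": 1.0, "R_conv": 0.2})
    # FVA max of every chain reaction is 1.0 (oracle above)
    assert calibrate_min_bound(space, "R_out", 0.2) == pytest.approx(0.2, abs=1e-5)
    assert calibrate_min_bound(space, "R_out", 1.0) == pytest.approx(1.0, abs=1e-5)


def test_calibrate_min_bound_blocked_reaction():
    mets = [Metabolite("A", "cytosol"), Metabolite("B", "cytosol"), Metabolite("C", "cytosol")]
    rxns = [
        Reaction("R_in", 1, {"A": 1.0}, 0, 10, role=ReactionRole.EXCHANGE),
        Reaction("R_conv", 2, {"A": -1.0, "B": 1.0}, 0, 10),
        Reaction("R_out", 3, {"B": -1.0}, 0, 10, role=ReactionRole.EXCHANGE),
        Reaction("R_dead", 4, {"B": -1.0, "C": 1.0}, 0, 10),  # C has no outlet
    ]
    model = MetabolicModel(name="blocked", metabolites=mets, reactions=rxns)
    data = reaction_data_from_dict(model, {"R_in": 0.5})
    space = build_optimal_space(model, data)
    with pytest.warns(UserWarning, match="blocked"):
        assert calibrate_min_bound(space, "R_dead", 0.2) == 0.0
    with pytest.raises(ValueError, match="fraction"):
        calibrate_min_bound(space, "R_out", 0.0)
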