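"""Dual Mann-Whitney procedure against an exact permutation oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from fluxcordance.optima import FluxSample
from fluxcordance.stats import (
    DifferentialReport,
    differential_flux_report,
    differential_fluxsum_report,
    mw_compare,
    scenario_shift,
    significance_vector,
)
from fluxcordance.fluxsum import FluxSumSample


def permutation_oracle(a, b):
    """Independent oracle: exact one/two-sided p by enumerating assignments.

    Uses average ranks on the pooled sample and enumerates every way the
    pooled values could be split between the groups.
    """
    a, b = list(a), list(b)
    n1, n = len(a), len(a) + len(b)
    pooled = np.array(a + b, dtype=float)
    order = pooled.argsort(kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    r_obs = ranks[:n1].sum()
    ge = le = total = 0
    for idx in combinations(range(n), n1):
        r = sum(ranks[i] for i in idx)
        total += 1
        if r >= r_obs - 1e-9:
            ge += 1
        if r <= r_obs + 1e-9:
            le += 1
    p_a = ge / total
    p_b = le / total
    return p_a, p_b, min(1.0, 2 * min(p_a, p_b))


@pytest.mark.parametrize(
    "a,b",
    [
        ([1.0, 2.0, 3.0], [0.0, 0.5]),
        ([1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 5.0, 6.0]),
        ([1.0, 1.0, 2.0], [1.0, 2.0, 2.0]),  # heavy ties
        ([0.1, 0.2], [0.3, 0.4, 0.5, 0.6]),
        ([5.0], [1.0, 2.0, 3.0]),
        ([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 2.0]),
    ],
)
def test_exact_matches_permutation_oracle(a, b):
    res = mw_compare(a, b)
    p_a, p_b, p_two = permutation_oracle(a, b)
    assert res.p_right_a == pytest.approx(p_a, abs=1e-12)
    assert res.p_right_b == pytest.approx(p_b, abs=1e-12)
    assert res.p_two == pytest.approx(p_two, abs=1e-12)


def test_identical_samples_not_significant():
    a = [1.0, 2.0, 3.0, 4.0]
    res = mw_compare(a, list(a))
    assert not res.significant
    assert res.direction == "none"


def test_constant_samples_never_nan():
    res = mw_compare([2.0, 2.0, 2.0], [2.0, 2.0])
    assert res.p_two == 1.0 and res.p_right_a == 1.0
    assert not res.significant
    # also on the asymptotic branch
    res_big = mw_compare([1.0] * 50, [1.0] * 50)
    assert res_big.p_two == 1.0 and not res_big.significant


def test_shifted_sample_significant_a_greater():
    rng = np.random.default_rng(0)
    b = rng.normal(0, 1, size=5000)
    a = b + 1.0
    res = mw_compare(a, b)
    assert res.significant and res.direction == "A_greater"
    assert res.p_right_a < 1e-10


@pytest.mark.parametrize("seed", range(5))
def test_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.5, 1, size=40)
    b = rng.normal(0.0, 1, size=35)
    fwd = mw_compare(a, b)
    rev = mw_compare(b, a)
    assert fwd.p_two == pytest.approx(rev.p_two, rel=1e-12)
    assert fwd.p_right_a == pytest.approx(rev.p_right_b, rel=1e-12)
    if fwd.significant:
        assert rev.significant
        assert {fwd.direction, rev.direction} == {"A_greater", "B_greater"}


def test_empty_sample_rejected():
    with pytest.raises(ValueError, match="nonempty"):
        mw_compare([], [1.0])


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _flux_sample(values, ids):
    values = np.asarray(values, dtype=float)
    return FluxSample(values=values, reaction_ids=ids, n=values.shape[0], seed=0)


def test_identical_samples_yield_no_significance():
    rng = np.random.default_rng(1)
    vals = rng.uniform(0, 1, size=(100, 4))
    ids = ["r1", "r2", "r3", "r4"]
    rep = differential_flux_report(_flux_sample(vals, ids), _flux_sample(vals.copy(), ids))
    assert len(rep.table) == 4  # one row per reaction
    assert not rep.table["significant"].any()


def test_planted_interval_difference_detected():
    """r2's optimum interval [1, 2] in A vs [0, 0.1] in B -> significant A_greater."""
    rng = np.random.default_rng(2)
    n = 500
    ids = ["r1", "r2"]
    a = np.column_stack([rng.uniform(0, 1, n), rng.uniform(1, 2, n)])
    b = np.column_stack([rng.uniform(0, 1, n), rng.uniform(0, 0.1, n)])
    rep = differential_flux_report(_flux_sample(a, ids), _flux_sample(b, ids))
    row = rep.table.loc["r2"]
    assert row["significant"] and row["direction"] == "A_greater"
    assert row["mean_A"] == pytest.approx(1.5, abs=0.05)
    assert row["ratio_A_over_B"] > 10


def test_ratio_undefined_when_mean_b_zero():
    ids = ["r1"]
    a = np.full((20, 1), 0.5)
    b = np.zeros((20, 1))
    rep = differential_flux_report(_flux_sample(a, ids), _flux_sample(b, ids))
    assert np.isnan(rep.table.at["r1", "ratio_A_over_B"])


def test_index_mismatch_rejected():
    a = _flux_sample(np.zeros((5, 2)), ["r1", "r2"])
    b = _flux_sample(np.zeros((5, 2)), ["r1", "rX"])
    with pytest.raises(ValueError, match="index"):
        differential_flux_report(a, b)


def test_fluxsum_report_namespaces():
    fa = FluxSumSample(values=np.random.default_rng(3).uniform(0, 1, (50, 3)),
                       index=["m1[c]", "m1[h]", "m2[c]"], mode="compartmental")
    fb = FluxSumSample(values=fa.values.copy(), index=list(fa.index), mode="compartmental")
    rep = differential_fluxsum_report(fa, fb)
    assert list(rep.table.index) == ["m1[c]", "m1[h]", "m2[c]"]
    assert not rep.table["significant"].any()


# ---------------------------------------------------------------------------
# scenario shift
# ---------------------------------------------------------------------------


def report_with_pvalues(p_two, index=None, alpha=0.05):
    index = index or [f"r{i}" for i in range(len(p_two))]
    df = pd.DataFrame({"p_two": p_two}, index=index)
    df["p_right_A"] = df["p_two"]
    df["p_right_B"] = 1.0
    df["significant"] = df["p_two"] < alpha
    df["direction"] = "none"
    return DifferentialReport(table=df, alpha=alpha, kind="flux")


def test_scenario_shift_identical_is_zero():
    rep = report_with_pvalues([0.01, 0.5, 0.3])
    out = scenario_shift(rep, rep)
    assert out["hamming"] == 0 and out["fraction"] == 0.0


def test_scenario_shift_definition():
    """Bit vectors [0,1,0] vs [0,0,0]: distance 1, fraction 1/3."""
    x = report_with_pvalues([0.01, 0.5, 0.01])  # -> bits 0,1,0
    y = report_with_pvalues([0.01, 0.01, 0.01])  # -> bits 0,0,0
    assert list(significance_vector(x)) == [0, 1, 0]
    out = scenario_shift(x, y)
    assert out["hamming"] == 1
    assert out["fraction"] == pytest.approx(1 / 3)


def test_scenario_shift_exclusion_arithmetic():
    """5 changes over 20 items, 2 changed items excluded -> 3/18."""
    p_x = [0.5] * 20
    p_y = [0.5] * 20
    for i in range(5):
        p_y[i] = 0.01  # flip 5 bits
    x = report_with_pvalues(p_x)
    y = report_with_pvalues(p_y)
    out = scenario_shift(x, y, exclude=["r0", "r1"])
    assert out["hamming"] == 3
    assert out["n_items"] == 18
    assert out["fraction"] == pytest.approx(3 / 18)


def test_scenario_shift_is_a_metric():
    reps = [
        report_with_pvalues([0.01, 0.5, 0.01, 0.5]),
        report_with_pvalues([0.5, 0.5, 0.01, 0.01]),
        report_with_pvalues([0.01, 0.01, 0.01, 0.5]),
    ]
    d = lambda i, j: scenario_shift(reps[i], reps[j])["hamming"]
    for i in range(3):
        assert d(i, i) == 0
        for j in range(3):
            assert d(i, j) == d(j, i)
            for k in range(3):
                assert d(i, k) <= d(i, j) + d(j, k)
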