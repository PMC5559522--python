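"""Dual Mann-Whitney differential analysis of fluxes and flux-sums.

Two cell types are compared item by item (reaction fluxes or metabolite
flux-sums) over their alternative-optima samples. For each item both
right-tailed tests (A stochastically greater than B, and the reverse) and
a two-tailed test are computed; an item counts as *differential* only when
it passes both the two-tailed test and the right-tailed test of the
winning side at the same significance level alpha (default 0.05) — the
dual-pass rule prevents inconsistent calls. Mean values and their ratio
are reported for interpretability only; significance is decided on whole
distributions, not means.

Exact p-values are computed by enumerating all rank assignments when the
combined sample size is below 20 (midranks for ties); larger samples use
the normal approximation with continuity and tie correction. No multiple-
testing correction is applied by default (one raw alpha per item), with a
Benjamini-Hochberg option available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MWResult",
    "DifferentialReport",
    "mw_compare",
    "differential_flux_report",
    "differential_fluxsum_report",
    "significance_vector",
    "scenario_shift",
    "DEFAULT_ALPHA",
    "EXACT_MAX_COMBINED_N",
]

DEFAULT_ALPHA = 0.05
EXACT_MAX_COMBINED_N = 20  # exact enumeration strictly below this combined n
RATIO_EPS = 1e-12


@dataclass(frozen=True)
class MWResult:
    u_a: float  # Mann-Whitney U of sample a
    p_right_a: float  # H1: a stochastically greater than b
    p_right_b: float  # H1: b stochastically greater than a
    p_two: float
    direction: str  # "A_greater" | "B_greater" | "none"
    significant: bool


def _exact_mw(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    """Exact U and one/two-sided p by full enumeration of rank assignments."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    r_obs = float(ranks[:n1].sum())
    u_obs = r_obs - n1 * (n1 + 1) / 2.0
    total = comb(n1 + n2, n1)
    ge = le = 0
    tol = 1e-9
    for idx in combinations(range(n1 + n2), n1):
        r = ranks[list(idx)].sum()
        if r >= r_obs - tol:
            ge += 1
        if r <= r_obs + tol:
            le += 1
    p_right_a = ge / total  # large U_a <=> a greater
    p_right_b = le / total
    p_two = min(1.0, 2.0 * min(p_right_a, p_right_b))
    return u_obs, p_right_a, p_right_b, p_two


def _asymptotic_mw(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    res_g = sps.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    res_l = sps.mannwhitneyu(a, b, alternative="less", method="asymptotic")
    res_t = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res_g.statistic), float(res_g.pvalue), float(res_l.pvalue), float(res_t.pvalue)


def mw_compare(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> MWResult:
    """Dual Mann-Whitney comparison of two samples.

    Constant, identical pooled samples short-circuit to p = 1 (never NaN).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u_a = len(a) * len(b) / 2.0
        p_right_a = p_right_b = p_two = 1.0
    elif len(pooled) < EXACT_MAX_COMBINED_N:
        u_a, p_right_a, p_right_b, p_two = _exact_mw(a, b)
    else:
        u_a, p_right_a, p_right_b, p_two = _asymptotic_mw(a, b)
    winning = min(p_right_a, p_right_b)
    significant = bool(p_two < alpha and winning < alpha)
    if significant:
        direction = "A_greater" if p_right_a <= p_right_b else "B_greater"
    else:
        direction = "none"
    return MWResult(
        u_a=u_a,
        p_right_a=p_right_a,
        p_right_b=p_right_b,
        p_two=p_two,
        direction=direction,
        significant=significant,
    )


@dataclass
class DifferentialReport:
    """Per-item differential comparison between cell types A and B.

    ``table`` is indexed by item key with columns mean_A, mean_B,
    ratio_A_over_B (NaN when |mean_B| < 1e-12), p_right_A, p_right_B,
    p_two, direction, significant.
    """

    table: pd.DataFrame
    alpha: float
    kind: str  # "flux" | "fluxsum"

    @property
    def significant_items(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="item")


def _compare_matrices(
    values_a: np.ndarray,
    values_b: np.ndarray,
    index: list[str],
    alpha: float,
    kind: str,
    bh: bool = False,
) -> DifferentialReport:
    if values_a.shape[1] != values_b.shape[1]:
        raise ValueError("samples disagree on item count")
    rows = []
    for j in range(values_a.shape[1]):
        res = mw_compare(values_a[:, j], values_b[:, j], alpha)
        rows.append(res)
    mean_a = values_a.mean(axis=0)
    mean_b = values_b.mean(axis=0)
    ratio = np.where(np.abs(mean_b) < RATIO_EPS, np.nan, mean_a / np.where(mean_b == 0, 1, mean_b))
    df = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "ratio_A_over_B": ratio,
            "p_right_A": [r.p_right_a for r in rows],
            "p_right_B": [r.p_right_b for r in rows],
            "p_two": [r.p_two for r in rows],
        },
        index=index,
    )
    if bh:
        from statsmodels.stats.multitest import multipletests

        for col in ("p_right_A", "p_right_B", "p_two"):
            df[col] = multipletests(df[col].to_numpy(), method="fdr_bh")[1]
    winning = df[["p_right_A", "p_right_B"]].min(axis=1)
    df["significant"] = (df["p_two"] < alpha) & (winning < alpha)
    df["direction"] = np.where(
        ~df["significant"],
        "none",
        np.where(df["p_right_A"] <= df["p_right_B"], "A_greater", "B_greater"),
    )
    return DifferentialReport(table=df, alpha=alpha, kind=kind)


def differential_flux_report(sample_a, sample_b, alpha: float = DEFAULT_ALPHA, bh: bool = False) -> DifferentialReport:
    """Dual Mann-Whitney comparison per reaction over two FluxSamples."""
    if sample_a.reaction_ids != sample_b.reaction_ids:
        raise ValueError("flux samples disagree on reaction index")
    return _compare_matrices(
        sample_a.values, sample_b.values, list(sample_a.reaction_ids), alpha, "flux", bh
    )


def differential_fluxsum_report(fs_a, fs_b, alpha: float = DEFAULT_ALPHA, bh: bool = False) -> DifferentialReport:
    """Dual Mann-Whitney comparison per metabolite key over two FluxSumSamples."""
    if fs_a.index != fs_b.index:
        raise ValueError("flux-sum samples disagree on metabolite index")
    return _compare_matrices(fs_a.values, fs_b.values, list(fs_a.index), alpha, "fluxsum", bh)


def significance_vector(report: DifferentialReport, which: str = "two") -> pd.Series:
    """Binary encoding of a report: p < alpha -> 0, else 1.

    ``which="two"`` binarizes the two-tailed p-value; ``which="dual"``
    encodes the dual-pass significance flag instead.
    """
    if which == "two":
        bits = (report.table["p_two"] >= report.alpha).astype(int)
    elif which == "dual":
        bits = (~report.table["significant"]).astype(int)
    else:
        raise ValueError(f"which must be 'two' or 'dual', got {which!r}")
    return bits


def scenario_shift(
    report_x: DifferentialReport,
    report_y: DifferentialReport,
    which: str = "two",
    exclude: Optional[Sequence[str]] = None,
) -> dict:
    """Hamming distance between two scenarios' binarized significance vectors.

    Quantifies how many items change test status when constraints change.
    ``exclude`` drops items (e.g. reactions directly hit by the added
    constraints) before computing the distance and fraction.
    """
    if list(report_x.table.index) != list(report_y.table.index):
        raise ValueError("reports disagree on item index")
    bits_x = significance_vector(report_x, which)
    bits_y = significance_vector(report_y, which)
    keep = ~bits_x.index.isin(set(exclude or ()))
    changed = (bits_x != bits_y) & keep
    n_kept = int(keep.sum())
    hamming = int(changed.sum())
    return {
        "hamming": hamming,
        "n_items": n_kept,
        "fraction": hamming / n_kept if n_kept else float("nan"),
        "changed": changed,
    }
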