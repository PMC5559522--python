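"""The alternative-optima space of the LAD fit.

Because expression maps to only part of the network, the flux distribution
minimizing the weighted LAD objective is rarely unique: a whole polytope of
steady-state flux distributions is *equally concordant* with the data.
This module characterizes that set two ways:

* :func:`fva_over_optima` — per-reaction minimum and maximum net flux over
  the polytope obtained by fixing the objective at its optimum (a flux
  variability analysis restricted to the optimal face);
* :func:`sample_optima` — a hit-and-run Markov chain producing an
  asymptotically uniform sample of the polytope, in the split-variable
  space, mapped back to net fluxes.

The objective is fixed with a small relative tolerance (default 1e-6,
plus 1e-9 absolute) rather than exact equality so the polytope stays
numerically full-dimensional on its optimal face.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.linalg import null_space

from .expression import ReactionData
from .fit import FitConstraints, FitResult, LadProgram, solve_lad, solve_lp
from .model import MetabolicModel

__all__ = [
    "OptimalSpace",
    "FluxRange",
    "FluxSample",
    "build_optimal_space",
    "fva_over_optima",
    "sample_optima",
    "check_sample",
    "calibrate_min_bound",
]

DEFAULT_OPT_TOL = 1e-6
DEFAULT_ABS_TOL = 1e-9
FEAS_TOL = 1e-6


@dataclass
class FluxRange:
    """Per-reaction (v_min, v_max) over the optimal space."""

    reaction_ids: list[str]
    v_min: np.ndarray
    v_max: np.ndarray

    def width(self) -> np.ndarray:
        return self.v_max - self.v_min

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"v_min": self.v_min, "v_max": self.v_max}, index=self.reaction_ids
        )


@dataclass
class FluxSample:
    """n x N_R matrix of alternative-optimal net flux distributions."""

    values: np.ndarray
    reaction_ids: list[str]
    n: int
    seed: int
    activities: Optional[np.ndarray] = None  # n x N_R split activities

    def column(self, rxn_id: str) -> np.ndarray:
        return self.values[:, self.reaction_ids.index(rxn_id)]


@dataclass
class OptimalSpace:
    """Fixed-objective polytope of a solved LAD fit.

    The polytope lives in the split-variable space y >= 0:
    {S_split y = 0, var bounds, extra rows, phi(y) <= budget} with
    phi the weighted LAD objective and budget = z*(1+opt_tol) + abs_tol.
    """

    model: MetabolicModel
    data: ReactionData
    fit: FitResult
    opt_tol: float = DEFAULT_OPT_TOL
    abs_tol: float = DEFAULT_ABS_TOL
    _fva_cache: Optional[FluxRange] = field(default=None, repr=False)
    _warm_points: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.fit.status != "optimal":
            raise ValueError(f"cannot build an optimal space from a {self.fit.status} fit")

    @property
    def program(self) -> LadProgram:
        return self.fit.program

    @property
    def z_star(self) -> float:
        return self.fit.z_star

    @property
    def budget(self) -> float:
        return self.z_star * (1.0 + self.opt_tol) + self.abs_tol

    def budget_row(self) -> tuple[sparse.csr_matrix, np.ndarray]:
        """Objective <= budget as an extra <=-row over (y, e)."""
        row = sparse.csr_matrix(self.program.objective.reshape(1, -1))
        return row, np.array([self.budget])


def build_optimal_space(
    model: MetabolicModel,
    data: ReactionData,
    constraints: Optional[FitConstraints] = None,
    lam: float = 0.0,
    opt_tol: float = DEFAULT_OPT_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
) -> OptimalSpace:
    """Solve the LAD fit and wrap its optimal face as an OptimalSpace."""
    fit = solve_lad(model, data, constraints, lam)
    if fit.status != "optimal":
        raise ValueError(f"LAD fit ended {fit.status}; no optimal space to explore")
    return OptimalSpace(model=model, data=data, fit=fit, opt_tol=opt_tol, abs_tol=abs_tol)


def fva_over_optima(space: OptimalSpace) -> FluxRange:
    """Min and max net flux per reaction over the fixed-objective polytope."""
    if space._fva_cache is not None:
        return space._fva_cache
    prog = space.program
    model = space.model
    row, rhs = space.budget_row()
    n_r = model.n_reactions
    n_e = len(prog.mapped_ids)
    v_min = np.empty(n_r)
    v_max = np.empty(n_r)
    warm: list[np.ndarray] = []
    for j in range(n_r):
        net_row = prog.split.net_map[j].toarray().ravel()
        c = np.concatenate([net_row, np.zeros(n_e)])
        for sign, target in ((1.0, v_min), (-1.0, v_max)):
            res = solve_lp(prog, sign * c, extra_rows=row, extra_rhs=rhs)
            if res.status != 0:
                raise RuntimeError(
                    f"FVA sub-LP for reaction {model.reactions[j].id!r} "
                    f"ended with status {res.status}: stale or inconsistent z*"
                )
            target[j] = sign * res.fun
            warm.append(res.x[: prog.n_y])
    rng = FluxRange(reaction_ids=model.reaction_ids, v_min=v_min, v_max=v_max)
    space._fva_cache = rng
    space._warm_points = warm
    return rng


def calibrate_min_bound(space: OptimalSpace, rxn_id: str, fraction: float) -> float:
    """fraction x (max flux of the reaction over the alternative-optima space).

    Used to place minimum-flux bounds at e.g. ~20% of a reaction's
    theoretically maximal data-concordant flux.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = fva_over_optima(space)
    vmax = float(rng.v_max[space.model.reaction_position(rxn_id)])
    if vmax <= FEAS_TOL:
        warnings.warn(f"reaction {rxn_id!r} is blocked over the optimal space; min bound 0")
        return 0.0
    return fraction * vmax


def _interior_point(space: OptimalSpace) -> np.ndarray:
    """Average of the LAD optimum and all FVA vertex solutions (convexity)."""
    fva_over_optima(space)  # populates warm points
    pts = [space.fit.y_star, *space._warm_points]
    return np.mean(pts, axis=0)


def _pl_crossing(
    alpha: np.ndarray,
    beta: np.ndarray,
    w: np.ndarray,
    val0: float,
    slope0: float,
    c1: float,
    budget: float,
    t_end: float,
) -> float:
    """Largest t in [0, t_end] with sum w|alpha + beta t| + c1 t <= budget.

    Assumes the value at t=0 is within budget. The function is convex
    piecewise linear with breakpoints at -alpha/beta; its slope jumps by
    2 w |beta| at each, so the boundary crossing is located exactly by a
    cumulative walk over the sorted breakpoints.
    """
    if t_end <= 0.0:
        return 0.0
    nz = beta != 0.0
    tb = -alpha[nz] / beta[nz]
    keep = (tb > 0.0) & (tb < t_end)
    tb = tb[keep]
    inc = 2.0 * w[nz][keep] * np.abs(beta[nz][keep])
    order = np.argsort(tb)
    tb, inc = tb[order], inc[order]
    seg_start = np.concatenate(([0.0], tb))
    seg_end = np.concatenate((tb, [t_end]))
    slopes = slope0 + np.concatenate(([0.0], np.cumsum(inc)))
    deltas = seg_end - seg_start
    start_vals = val0 + np.concatenate(([0.0], np.cumsum(slopes[:-1] * deltas[:-1])))
    end_vals = start_vals + slopes * deltas
    over = end_vals > budget
    if not over.any():
        return t_end
    k = int(np.argmax(over))
    if slopes[k] <= 0.0:  # numerically flat: stop at the segment start
        return float(seg_start[k])
    t_star = seg_start[k] + (budget - start_vals[k]) / slopes[k]
    return float(min(max(t_star, seg_start[k]), seg_end[k]))


def sample_optima(
    space: OptimalSpace,
    n: int = 20_000,
    seed: int = 0,
    warmup: int = 1000,
    thin: int = 10,
) -> FluxSample:
    """Hit-and-run sample of the fixed-objective polytope.

    The chain moves in the null space of the split stoichiometric matrix
    (steady state is preserved exactly). Directions mix isotropic null-space
    draws with differences of the FVA vertex solutions, which span the
    optimal face's affine hull — without the latter the chain freezes in
    the directions left free by the data whenever the objective budget pins
    the mapped activities. Each step computes the feasible chord against
    variable bounds and linear rows in closed form, shrinks it against the
    convex objective budget (an exact piecewise-linear crossing), and jumps
    to a uniform point of the chord.
    Deterministic given (space, n, seed, warmup, thin).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prog = space.program
    split = prog.split
    model = space.model
    rng = np.random.default_rng(seed)
    budget = space.budget

    y0 = _interior_point(space)
    N = null_space(split.S_split.toarray()) if model.n_metabolites else np.eye(split.n_vars)
    k = N.shape[1]
    out = np.empty((n, split.n_vars))
    if k == 0:
        out[:] = y0
        return _finalize_sample(space, out, n, seed)
    # Direction pool spanning the optimal face: the FVA vertex solutions all
    # lie in the polytope, so their pairwise differences live exactly in its
    # affine hull. Isotropic null-space directions alone are almost
    # orthogonal to that hull when the budget pins mapped activities (the
    # face is thin in the pinned coordinates), which freezes the chain;
    # vertex-difference directions restore mixing along the free directions.
    verts = np.asarray([space.fit.y_star, *space._warm_points])
    n_verts = verts.shape[0]

    G = prog.G.toarray() if prog.G.shape[0] else np.zeros((0, split.n_vars))
    h = prog.h
    lo, hi = split.var_lb, split.var_ub
    A_map = split.act_map[prog.mapped_pos]
    w, d, lam = prog.w, prog.d, prog.lam

    def chord_linear(y, u):
        """Feasible [t_lo, t_hi] against bounds and G-rows."""
        t_lo, t_hi = -np.inf, np.inf
        eps = 1e-13
        mask = np.abs(u) > eps
        if mask.any():
            um, ym = u[mask], y[mask]
            lo_t = (lo[mask] - ym) / um
            hi_t = (hi[mask] - ym) / um
            lo_all = np.where(um > 0, lo_t, hi_t)
            hi_all = np.where(um > 0, hi_t, lo_t)
            t_lo = max(t_lo, lo_all.max())
            t_hi = min(t_hi, hi_all.min())
        if G.shape[0]:
            gu = G @ u
            slack = h - G @ y
            for gui, si in zip(gu, slack):
                if gui > eps:
                    t_hi = min(t_hi, si / gui)
                elif gui < -eps:
                    t_lo = max(t_lo, si / gui)
        return t_lo, t_hi

    def shrink_budget(y, u, t_lo, t_hi):
        """Intersect the chord with {phi <= budget} (convex: an interval).

        Along the chord phi(t) = sum_i w_i |alpha_i + beta_i t| + c0 + c1 t
        is piecewise linear and convex, so each boundary crossing is found
        exactly by walking its breakpoints.
        """
        alpha = (A_map @ y) - d
        beta = A_map @ u
        c1 = lam * float(np.sum(u)) if lam else 0.0
        b_eff = budget - (lam * float(np.sum(y)) if lam else 0.0)
        val0 = float(np.sum(w * np.abs(alpha)))
        if val0 > b_eff:  # tiny numerical drift: stay put
            return 0.0, 0.0
        sign0 = np.where(alpha > 0, 1.0, np.where(alpha < 0, -1.0, np.sign(beta)))
        slope0 = float(np.sum(w * beta * sign0)) + c1
        hi = _pl_crossing(alpha, beta, w, val0, slope0, c1, b_eff, t_hi)
        # mirror the chord for the left crossing
        sign0m = np.where(alpha > 0, 1.0, np.where(alpha < 0, -1.0, np.sign(-beta)))
        slope0m = float(np.sum(w * (-beta) * sign0m)) - c1
        lo = -_pl_crossing(alpha, -beta, w, val0, slope0m, -c1, b_eff, -t_lo)
        return lo, hi

    y = y0.copy()
    total = warmup + n * thin
    stored = 0
    degenerate = 0
    step = 0
    while stored < n:
        # 80% vertex-difference (affine-hull) moves, 20% isotropic null-space
        if rng.random() < 0.8 and n_verts >= 2:
            i, j = rng.integers(n_verts), rng.integers(n_verts)
            u = verts[i] - verts[j]
        else:
            u = N @ rng.standard_normal(k)
        norm = np.linalg.norm(u)
        if norm < 1e-14:
            step += 1
            continue
        u /= norm
        t_lo, t_hi = chord_linear(y, u)
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi < t_lo:
            t_lo = t_hi = 0.0
        else:
            t_lo, t_hi = shrink_budget(y, u, t_lo, t_hi)
        if t_hi - t_lo < 1e-12:
            degenerate += 1
        else:
            t = rng.uniform(t_lo, t_hi)
            y = np.clip(y + t * u, lo, hi)
        step += 1
        if step > warmup and (step - warmup) % thin == 0:
            out[stored] = y
            stored += 1
    if degenerate == total:
        warnings.warn(
            "optimal polytope has numerically empty interior; "
            "sample collapsed to the warm-start point"
        )
    return _finalize_sample(space, out, n, seed)


def _finalize_sample(space: OptimalSpace, ys: np.ndarray, n: int, seed: int) -> FluxSample:
    split = space.program.split
    return FluxSample(
        values=ys @ split.net_map.T.toarray(),
        activities=ys @ split.act_map.T.toarray(),
        reaction_ids=space.model.reaction_ids,
        n=n,
        seed=seed,
    )


def check_sample(space: OptimalSpace, sample: FluxSample) -> dict[str, float]:
    """Diagnostics: residuals, bound/objective violations, FVA containment.

    All metrics should be ~0 (<= 1e-6) for a valid sample of the space.
    """
    model = space.model
    if sample.values.shape[1] != model.n_reactions:
        raise ValueError("sample and model disagree on reaction count")
    S = model.stoichiometric_matrix().toarray()
    resid = float(np.max(np.abs(sample.values @ S.T))) if model.n_metabolites else 0.0
    lb, ub = model.bounds()
    bound_viol = float(
        max(np.max(lb - sample.values, initial=0.0), np.max(sample.values - ub, initial=0.0))
    )
    prog = space.program
    # objective excess at minimal slack: phi(row) - budget, clipped at 0
    mapped_cols = prog.mapped_pos
    acts = sample.activities if sample.activities is not None else np.abs(sample.values)
    phi_vals = np.abs(acts[:, mapped_cols] - prog.d) @ prog.w
    if prog.lam:
        phi_vals = phi_vals + prog.lam * acts.sum(axis=1)
    obj_excess = float(max(np.max(phi_vals) - space.budget, 0.0))
    rng = fva_over_optima(space)
    tol = FEAS_TOL
    outside = np.any(
        (sample.values < rng.v_min[None, :] - tol) | (sample.values > rng.v_max[None, :] + tol),
        axis=1,
    )
    return {
        "max_steady_state_residual": resid,
        "max_bound_violation": bound_viol,
        "max_objective_excess": obj_excess,
        "fraction_outside_fva": float(np.mean(outside)),
    }
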