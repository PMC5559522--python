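"""Weighted least-absolute-deviations (LAD) flux fitting.

The data-integration program finds a steady-state flux distribution most
concordant with reaction-mapped expression:

    minimize    sum_i  w_i * | a_i(v) - d_i |   ( + lambda * sum_j a_j )
    subject to  S v = 0,  lb <= v <= ub,
                v_bio >= biomass_min,  v_maint >= maintenance_min,
                extra minimum-flux bounds, carboxylation/oxygenation
                ratio constraints.

a_j is the *activity* of reaction j: |v_j| for irreversible reactions and
v+ + v- after splitting reversible reactions into two nonnegative
half-fluxes — expression is signless evidence of enzyme activity, and the
split keeps the program linear. The absolute residuals are linearized with
one slack e_i >= |a_i - d_i| per mapped reaction, giving a single LP solved
with HiGHS (scipy front-end).

The optional L1 flux penalty lambda (default 0: pure weighted LAD) mildly
discourages loops through reactions carrying no data; it is off by default
so that the optimal set is exactly the set of equally data-concordant flux
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .expression import ReactionData
from .model import MetabolicModel, ReactionRole

__all__ = [
    "RatioConstraint",
    "FitConstraints",
    "FitResult",
    "SplitSystem",
    "build_split_system",
    "linearize_ratio",
    "LadProgram",
    "build_lad_program",
    "solve_lad",
    "DEFAULT_BIOMASS_MIN",
    "DEFAULT_MAINTENANCE_MIN",
]

DEFAULT_BIOMASS_MIN = 1e-6
DEFAULT_MAINTENANCE_MIN = 1e-3
SOLVER_FEAS_TOL = 1e-9
VERIFY_TOL = 1e-6


@dataclass(frozen=True)
class RatioConstraint:
    """Bounds on the flux ratio numerator/denominator, e.g. RuBisCO vC/vO.

    With both fluxes nonnegative, r_lb <= vC/vO <= r_ub is equivalent to the
    linear pair  r_lb*vO - vC <= 0  and  r_ub*vO - vC >= 0 ; at vO = 0 the
    pair forces vC = 0.
    """

    numerator: str
    denominator: str
    r_lb: float
    r_ub: float

    def __post_init__(self):
        if self.r_lb > self.r_ub:
            raise ValueError(f"ratio constraint: r_lb {self.r_lb} > r_ub {self.r_ub}")
        if self.r_lb <= 0 or self.r_ub <= 0:
            raise ValueError("ratio bounds must be positive")


def linearize_ratio(rc: RatioConstraint) -> list[tuple[dict[str, float], float]]:
    """Two <=-rows over net fluxes: (coeff map, rhs) with sum coeff*v <= rhs."""
    return [
        ({rc.denominator: rc.r_lb, rc.numerator: -1.0}, 0.0),  # r_lb*vO - vC <= 0
        ({rc.numerator: 1.0, rc.denominator: -rc.r_ub}, 0.0),  # vC - r_ub*vO <= 0
    ]


@dataclass
class FitConstraints:
    """Activity floors and ratio constraints of the fit.

    Biomass / maintenance reactions are located through their model roles
    unless explicit ids are given. Defaults: v_bio >= 1e-6, each maintenance
    (non-metabolic ATP consumption) flux >= 0.001.
    """

    biomass_min: float = DEFAULT_BIOMASS_MIN
    maintenance_min: float = DEFAULT_MAINTENANCE_MIN
    biomass_id: Optional[str] = None
    maintenance_ids: Optional[list[str]] = None
    extra_min_flux: dict[str, float] = field(default_factory=dict)
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)

    def min_flux_map(self, model: MetabolicModel) -> dict[str, float]:
        """Concrete reaction-id -> minimum net flux map for a model."""
        out: dict[str, float] = {}
        bio = [self.biomass_id] if self.biomass_id else [
            r.id for r in model.reactions if r.role == ReactionRole.BIOMASS
        ]
        for rid in bio:
            out[rid] = max(out.get(rid, 0.0), self.biomass_min)
        maint = self.maintenance_ids if self.maintenance_ids is not None else [
            r.id for r in model.reactions if r.role == ReactionRole.MAINTENANCE
        ]
        for rid in maint:
            out[rid] = max(out.get(rid, 0.0), self.maintenance_min)
        for rid, val in self.extra_min_flux.items():
            out[rid] = max(out.get(rid, 0.0), float(val))
        for rid in out:
            model.reaction(rid)  # KeyError on unknown id
        for rc in self.ratio_constraints:
            for rid in (rc.numerator, rc.denominator):
                rxn = model.reaction(rid)
                if rxn.reversible:
                    raise ValueError(
                        f"ratio constraint on reversible reaction {rid!r}: "
                        "ratio bounds assume nonnegative fluxes"
                    )
        return out


@dataclass
class SplitSystem:
    """Reversible-split representation: y >= 0 with v = P y (net), a = A y.

    ``pos[j]``/``neg[j]`` are the y-columns of reaction j's forward and
    backward half-fluxes (``neg[j] = -1`` for irreversible reactions, whose
    single variable keeps the original bounds).
    """

    model: MetabolicModel
    n_vars: int
    pos: np.ndarray  # (N_R,) int
    neg: np.ndarray  # (N_R,) int, -1 where irreversible
    var_lb: np.ndarray
    var_ub: np.ndarray
    S_split: sparse.csr_matrix  # N_met x n_vars
    net_map: sparse.csr_matrix  # N_R x n_vars: v = net_map @ y
    act_map: sparse.csr_matrix  # N_R x n_vars: a = act_map @ y

    def net(self, y: np.ndarray) -> np.ndarray:
        return self.net_map @ y

    def activity(self, y: np.ndarray) -> np.ndarray:
        return self.act_map @ y

    def embed(self, v: np.ndarray) -> np.ndarray:
        """Split a net flux vector into y with minimal activity (p*n = 0)."""
        y = np.zeros(self.n_vars)
        for j in range(len(self.pos)):
            if self.neg[j] < 0:
                y[self.pos[j]] = v[j]
            else:
                y[self.pos[j]] = max(v[j], 0.0)
                y[self.neg[j]] = max(-v[j], 0.0)
        return y


def build_split_system(model: MetabolicModel) -> SplitSystem:
    """Split every reversible reaction into forward/backward half-fluxes."""
    n_r = model.n_reactions
    pos = np.full(n_r, -1, dtype=int)
    neg = np.full(n_r, -1, dtype=int)
    var_lb: list[float] = []
    var_ub: list[float] = []
    for j, rxn in enumerate(model.reactions):
        if rxn.lb < 0:
            pos[j] = len(var_lb)
            var_lb.append(0.0)
            var_ub.append(max(rxn.ub, 0.0))
            neg[j] = len(var_lb)
            # when ub < 0 the backward half-flux is mandatory
            var_lb.append(max(0.0, -rxn.ub))
            var_ub.append(-rxn.lb)
        else:
            pos[j] = len(var_lb)
            var_lb.append(rxn.lb)
            var_ub.append(rxn.ub)
    n_vars = len(var_lb)
    S = model.stoichiometric_matrix().tocsc()
    rows, cols, vals = [], [], []
    nrows, ncols, nvals = [], [], []
    arows, acols, avals = [], [], []
    for j in range(n_r):
        col = S.getcol(j).tocoo()
        for i, s in zip(col.row, col.data):
            rows.append(i); cols.append(pos[j]); vals.append(s)
            if neg[j] >= 0:
                rows.append(i); cols.append(neg[j]); vals.append(-s)
        nrows.append(j); ncols.append(pos[j]); nvals.append(1.0)
        arows.append(j); acols.append(pos[j]); avals.append(1.0)
        if neg[j] >= 0:
            nrows.append(j); ncols.append(neg[j]); nvals.append(-1.0)
            arows.append(j); acols.append(neg[j]); avals.append(1.0)
    return SplitSystem(
        model=model,
        n_vars=n_vars,
        pos=pos,
        neg=neg,
        var_lb=np.array(var_lb),
        var_ub=np.array(var_ub),
        S_split=sparse.csr_matrix((vals, (rows, cols)), shape=(model.n_metabolites, n_vars)),
        net_map=sparse.csr_matrix((nvals, (nrows, ncols)), shape=(n_r, n_vars)),
        act_map=sparse.csr_matrix((avals, (arows, acols)), shape=(n_r, n_vars)),
    )


@dataclass
class LadProgram:
    """Assembled LP over x = [y (split fluxes), e (residual slacks)].

    G y <= h collects minimum-flux and ratio rows (over y only);
    the residual rows couple y and e. ``objective`` is the full c vector.
    """

    split: SplitSystem
    data: ReactionData
    constraints: FitConstraints
    lam: float
    mapped_ids: list[str]
    mapped_pos: np.ndarray  # model column of each mapped reaction
    w: np.ndarray
    d: np.ndarray
    G: sparse.csr_matrix  # extra linear rows over y
    h: np.ndarray
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    objective: np.ndarray

    @property
    def n_y(self) -> int:
        return self.split.n_vars

    def phi(self, y: np.ndarray) -> float:
        """Data-discordance of a split point: the LP objective at minimal e."""
        a = (self.split.act_map[self.mapped_pos] @ y)
        val = float(np.sum(self.w * np.abs(a - self.d)))
        if self.lam:
            val += self.lam * float(np.sum(y))
        return val


def build_lad_program(
    model: MetabolicModel,
    data: ReactionData,
    constraints: Optional[FitConstraints] = None,
    lam: float = 0.0,
) -> LadProgram:
    constraints = constraints if constraints is not None else FitConstraints()
    split = build_split_system(model)
    mapped_ids = data.mapped_ids
    if not mapped_ids:
        raise ValueError("no reaction carries mapped expression data")
    mapped_pos = np.array([model.reaction_position(r) for r in mapped_ids])
    w = data.table.loc[mapped_ids, "w"].to_numpy(dtype=float)
    d = data.table.loc[mapped_ids, "d"].to_numpy(dtype=float)
    n_y, n_e = split.n_vars, len(mapped_ids)

    # residual rows:  a_i - e_i <= d_i   and   -a_i - e_i <= -d_i
    A_act = split.act_map[mapped_pos]
    E = sparse.identity(n_e, format="csr")
    res_rows = sparse.vstack(
        [sparse.hstack([A_act, -E]), sparse.hstack([-A_act, -E])], format="csr"
    )
    res_rhs = np.concatenate([d, -d])

    # extra rows over y: minimum net flux and ratio constraints
    g_rows, g_rhs = [], []
    for rid, minv in constraints.min_flux_map(model).items():
        j = model.reaction_position(rid)
        g_rows.append(-split.net_map[j])  # -v_j <= -minv
        g_rhs.append(-minv)
    for rc in constraints.ratio_constraints:
        for coeffs, rhs in linearize_ratio(rc):
            row = sparse.csr_matrix((1, n_y))
            for rid, cf in coeffs.items():
                row = row + cf * split.net_map[model.reaction_position(rid)]
            g_rows.append(row)
            g_rhs.append(rhs)
    if g_rows:
        G = sparse.vstack(g_rows, format="csr")
        h = np.array(g_rhs)
        G_full = sparse.hstack([G, sparse.csr_matrix((G.shape[0], n_e))], format="csr")
        A_ub = sparse.vstack([res_rows, G_full], format="csr")
        b_ub = np.concatenate([res_rhs, h])
    else:
        G = sparse.csr_matrix((0, n_y))
        h = np.zeros(0)
        A_ub, b_ub = res_rows, res_rhs

    A_eq = sparse.hstack(
        [split.S_split, sparse.csr_matrix((model.n_metabolites, n_e))], format="csr"
    )
    lo = np.concatenate([split.var_lb, np.zeros(n_e)])
    hi = np.concatenate([split.var_ub, np.full(n_e, np.inf)])
    c = np.concatenate([np.full(n_y, lam, dtype=float), w])
    return LadProgram(
        split=split,
        data=data,
        constraints=constraints,
        lam=lam,
        mapped_ids=mapped_ids,
        mapped_pos=mapped_pos,
        w=w,
        d=d,
        G=G,
        h=h,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(model.n_metabolites),
        lo=lo,
        hi=hi,
        objective=c,
    )


def solve_lp(
    prog: LadProgram,
    objective: np.ndarray,
    extra_rows: Optional[sparse.csr_matrix] = None,
    extra_rhs: Optional[np.ndarray] = None,
):
    """Solve an LP over the program's feasible set with a custom objective."""
    A_ub, b_ub = prog.A_ub, prog.b_ub
    if extra_rows is not None:
        A_ub = sparse.vstack([A_ub, extra_rows], format="csr")
        b_ub = np.concatenate([b_ub, extra_rhs])
    return linprog(
        objective,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=prog.A_eq,
        b_eq=prog.b_eq,
        bounds=np.column_stack([prog.lo, prog.hi]),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_FEAS_TOL},
    )


@dataclass
class FitResult:
    status: str  # optimal | infeasible | unbounded
    v_star: Optional[np.ndarray] = None  # net fluxes, length N_R
    a_star: Optional[np.ndarray] = None  # activities, length N_R
    y_star: Optional[np.ndarray] = None  # split-variable solution
    z_star: Optional[float] = None  # attained weighted LAD objective
    program: Optional[LadProgram] = None


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve_lad(
    model: MetabolicModel,
    data: ReactionData,
    constraints: Optional[FitConstraints] = None,
    lam: float = 0.0,
) -> FitResult:
    """Solve the weighted LAD data-integration program.

    Returns status "infeasible"/"unbounded" without relaxation when the
    constraint set admits no steady-state flux distribution.
    """
    prog = build_lad_program(model, data, constraints, lam)
    res = solve_lp(prog, prog.objective)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FitResult(status=status, program=prog)
    y = res.x[: prog.n_y]
    return FitResult(
        status="optimal",
        v_star=prog.split.net(y),
        a_star=prog.split.activity(y),
        y_star=y,
        z_star=float(res.fun),
        program=prog,
    )
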