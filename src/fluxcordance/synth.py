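"""Synthetic models and two-condition expression data with known ground truth.

The generator emulates the structural features the pipeline must handle:
a compartmented stoichiometric network (cytosol plus organelles) with
inter-compartment transporters, cytosolic boundary exchanges, optional
organelle-to-environment exchanges that bypass the cytosol (removed by
model reduction), a biomass reaction, three energy-maintenance reactions,
and AND/OR GPR rules on a fraction of reactions.

Ground-truth fluxes are drawn as averages of random-objective LP vertices
of the feasible polytope (an interior-leaning feasible point), optionally
re-projected after planting fold-changes on chosen reactions. Replicate
expression values are noisy observations of the absolute activity of the
true flux through each GPR gene, arranged so the AND=min / OR=max mapping
recovers the activity in expectation: the limiting gene of an AND complex
sits at the activity and its partners are inflated; the dominant isozyme
of an OR sits at the activity and its partners are deflated. Noise is
additive Gaussian truncated at zero (expression is nonnegative).

True activities are kept within [0, 1] so that, at zero noise, the
max-scaled data vector coincides with the activity profile of a feasible
flux distribution and the LAD fit attains a perfect score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .expression import ExpressionMatrix
from .fit import FitConstraints
from .gpr import And, Gene, Or, gpr_genes, parse_gpr
from .model import MetabolicModel, Metabolite, Reaction, ReactionRole

__all__ = [
    "SyntheticScenario",
    "make_toy_model",
    "draw_true_fluxes",
    "simulate_expression",
    "make_scenario",
    "chain_model",
    "branched_cycle_model",
    "two_compartment_model",
]

DEFAULT_BOUND = 10.0
#: flux cap used when drawing true fluxes, so activities stay in [0, 1]
TRUE_FLUX_CAP = 1.0


# ---------------------------------------------------------------------------
# Frozen hand-built fixtures
# ---------------------------------------------------------------------------


def chain_model(d_bounds: float = DEFAULT_BOUND) -> MetabolicModel:
    """Irreversible chain A_ext -> A -> B -> B_ext (3 reactions, 2 metabolites).

    Reaction 1 imports A, reaction 2 converts A to B, reaction 3 exports B.
    At steady state all three carry the same flux.
    """
    mets = [Metabolite("A", "cytosol"), Metabolite("B", "cytosol")]
    rxns = [
        Reaction("R_in", 1, {"A": 1.0}, 0.0, d_bounds, role=ReactionRole.EXCHANGE,
                 gpr=parse_gpr("g1")),
        Reaction("R_conv", 2, {"A": -1.0, "B": 1.0}, 0.0, d_bounds, gpr=parse_gpr("g2")),
        Reaction("R_out", 3, {"B": -1.0}, 0.0, d_bounds, role=ReactionRole.EXCHANGE,
                 gpr=parse_gpr("g3")),
    ]
    return MetabolicModel(name="chain", metabolites=mets, reactions=rxns)


def branched_cycle_model() -> MetabolicModel:
    """Chain with an internal 2-cycle carrying no data.

    A_ext -> A -> B -> B_ext plus B <-> C <-> B via two reactions forming a
    cycle whose flux is unconstrained by any data (their net circulation is
    free within bounds).
    """
    mets = [Metabolite(m, "cytosol") for m in ("A", "B", "C")]
    rxns = [
        Reaction("R_in", 1, {"A": 1.0}, 0.0, DEFAULT_BOUND, role=ReactionRole.EXCHANGE,
                 gpr=parse_gpr("g1")),
        Reaction("R_conv", 2, {"A": -1.0, "B": 1.0}, 0.0, DEFAULT_BOUND, gpr=parse_gpr("g2")),
        Reaction("R_out", 3, {"B": -1.0}, 0.0, DEFAULT_BOUND, role=ReactionRole.EXCHANGE,
                 gpr=parse_gpr("g3")),
        Reaction("R_bc", 4, {"B": -1.0, "C": 1.0}, 0.0, DEFAULT_BOUND),
        Reaction("R_cb", 5, {"C": -1.0, "B": 1.0}, 0.0, DEFAULT_BOUND),
    ]
    return MetabolicModel(name="branched_cycle", metabolites=mets, reactions=rxns)


def two_compartment_model() -> MetabolicModel:
    """Cytosol + chloroplast with a transporter and two bypass exchanges.

    The two chloroplast<->environment exchanges feed a chloroplast-only
    metabolite X[h] used by no other reaction, so reduction removes exactly
    two reactions and one metabolite.
    """
    mets = [
        Metabolite("A[c]", "cytosol"),
        Metabolite("A[h]", "chloroplast"),
        Metabolite("B[h]", "chloroplast"),
        Metabolite("X[h]", "chloroplast"),
    ]
    rxns = [
        Reaction("R_in", 1, {"A[c]": 1.0}, 0.0, DEFAULT_BOUND, role=ReactionRole.EXCHANGE,
                 gpr=parse_gpr("g1")),
        Reaction("T_A", 2, {"A[c]": -1.0, "A[h]": 1.0}, 0.0, DEFAULT_BOUND, gpr=parse_gpr("g2")),
        Reaction("R_ab", 3, {"A[h]": -1.0, "B[h]": 1.0}, 0.0, DEFAULT_BOUND,
                 gpr=parse_gpr("g3a and g3b")),
        Reaction("T_B", 4, {"B[h]": -1.0, "A[c]": 1.0}, 0.0, DEFAULT_BOUND),
        Reaction("R_out", 5, {"A[c]": -1.0}, 0.0, DEFAULT_BOUND, role=ReactionRole.EXCHANGE,
                 gpr=parse_gpr("g5a or g5b")),
        Reaction("EX_X_in", 6, {"X[h]": 1.0}, 0.0, DEFAULT_BOUND, role=ReactionRole.EXCHANGE),
        Reaction("EX_X_out", 7, {"X[h]": -1.0}, 0.0, DEFAULT_BOUND, role=ReactionRole.EXCHANGE),
    ]
    return MetabolicModel(name="two_compartment", metabolites=mets, reactions=rxns)


def parallel_routes_model() -> MetabolicModel:
    """Two irreversible parallel routes from one precursor (a vC/vO analogue).

    EX_in -> P; P -> Q via R_C and via R_O; Q -> out. Any split of the input
    flux between R_C and R_O is a steady state, so a ratio constraint
    r_lb <= vC/vO <= r_ub carves a wedge out of the optimal set.
    """
    mets = [Metabolite("P", "cytosol"), Metabolite("Q", "cytosol")]
    rxns = [
        Reaction("EX_in", 1, {"P": 1.0}, 0.0, DEFAULT_BOUND, role=ReactionRole.EXCHANGE,
                 gpr=parse_gpr("gin")),
        Reaction("R_C", 2, {"P": -1.0, "Q": 1.0}, 0.0, DEFAULT_BOUND, gpr=parse_gpr("gc")),
        Reaction("R_O", 3, {"P": -1.0, "Q": 1.0}, 0.0, DEFAULT_BOUND, gpr=parse_gpr("go")),
        Reaction("EX_out", 4, {"Q": -1.0}, 0.0, DEFAULT_BOUND, role=ReactionRole.EXCHANGE),
    ]
    return MetabolicModel(name="parallel_routes", metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# Random toy generator
# ---------------------------------------------------------------------------


def make_toy_model(
    seed: int,
    n_internal: int = 10,
    compartments: Sequence[str] = ("cytosol", "chloroplast", "mitochondrion"),
    with_bypass_exchanges: int = 0,
    frac_reversible: float = 0.15,
    frac_gpr: float = 0.8,
    n_branches: int = 3,
) -> MetabolicModel:
    """Random connected compartmented toy model; deterministic given seed.

    The network is a linear backbone of ``n_internal`` species threading
    through the compartments (with explicit transporters at every
    compartment change), plus random same-compartment branch reactions, an
    ATP/ADP energy subsystem with one maintenance reaction per compartment,
    a biomass reaction, cytosolic boundary exchanges, and
    ``with_bypass_exchanges`` organelle-to-environment exchanges. A strictly
    positive flux through backbone, energy chain and biomass is feasible by
    construction.
    """
    if "cytosol" not in compartments:
        raise ValueError("compartments must include 'cytosol'")
    if n_internal < 3:
        raise ValueError("need at least 3 internal species")
    rng = np.random.default_rng(seed)
    organelles = [c for c in compartments if c != "cytosol"]

    mets: list[Metabolite] = []
    met_ids: set[str] = set()
    rxns: list[dict] = []

    def add_met(species: str, comp: str) -> str:
        mid = f"{species}[{comp}]"
        if mid not in met_ids:
            mets.append(Metabolite(mid, comp, base_species=species))
            met_ids.add(mid)
        return mid

    def add_rxn(rid, stoich, lb=0.0, ub=DEFAULT_BOUND, gpr="", role=ReactionRole.NORMAL):
        rxns.append(dict(id=rid, stoichiometry=stoich, lb=lb, ub=ub, gpr=gpr, role=role))

    # compartment walk for the backbone: start and end in the cytosol with
    # one excursion per organelle
    comp_seq = ["cytosol"] * n_internal
    if organelles and n_internal >= 5:
        span = max(1, (n_internal - 2) // (2 * len(organelles)))
        pos = 1
        for org in organelles:
            end = min(pos + span, n_internal - 1)
            for i in range(pos, end):
                comp_seq[i] = org
            pos = end + 1
            if pos >= n_internal - 1:
                break

    species = [f"S{i+1}" for i in range(n_internal)]
    add_rxn("EX_in", {add_met(species[0], "cytosol"): 1.0}, role=ReactionRole.EXCHANGE)
    backbone_mets = [("cytosol", species[0])]
    cur_comp = "cytosol"
    # species[0] enters in the cytosol; transport it if the walk starts elsewhere
    for i in range(n_internal):
        target = comp_seq[i]
        sp = species[i]
        add_met(sp, cur_comp) if i == 0 else None
        if i > 0:
            prev = species[i - 1]
            if target != cur_comp:
                add_rxn(f"T_{prev}_{target[:4]}",
                        {add_met(prev, cur_comp): -1.0, add_met(prev, target): 1.0})
                cur_comp = target
            add_rxn(f"R_{prev}_{sp}",
                    {add_met(prev, cur_comp): -1.0, add_met(sp, cur_comp): 1.0})
    if cur_comp != "cytosol":
        add_rxn(f"T_{species[-1]}_cyto",
                {add_met(species[-1], cur_comp): -1.0, add_met(species[-1], "cytosol"): 1.0})
    terminal = add_met(species[-1], "cytosol")
    add_rxn("EX_out", {terminal: -1.0}, role=ReactionRole.EXCHANGE)

    # energy subsystem: ATP imported to cytosol, distributed, burned by
    # maintenance, ADP returned and exported
    add_rxn("EX_atp", {add_met("atp", "cytosol"): 1.0}, role=ReactionRole.EXCHANGE)
    add_rxn("EX_adp", {add_met("adp", "cytosol"): -1.0}, role=ReactionRole.EXCHANGE)
    maint_comps = ["cytosol"] + organelles[:2]
    for comp in maint_comps:
        tag = comp[:4]
        if comp != "cytosol":
            add_rxn(f"T_atp_{tag}",
                    {add_met("atp", "cytosol"): -1.0, add_met("atp", comp): 1.0})
            add_rxn(f"T_adp_{tag}",
                    {add_met("adp", comp): -1.0, add_met("adp", "cytosol"): 1.0})
        add_rxn(f"NGAM_{tag}",
                {add_met("atp", comp): -1.0, add_met("adp", comp): 1.0},
                role=ReactionRole.MAINTENANCE)

    # biomass: consumes the terminal species and cytosolic ATP
    add_rxn("BIO", {terminal: -1.0, "atp[cytosol]": -1.0, "adp[cytosol]": 1.0},
            role=ReactionRole.BIOMASS)

    # random same-compartment branch conversions
    by_comp: dict[str, list[str]] = {}
    for m in mets:
        if m.base_species.startswith("S"):
            by_comp.setdefault(m.compartment, []).append(m.id)
    branch_pool = [(c, ids) for c, ids in by_comp.items() if len(ids) >= 2]
    for k in range(n_branches):
        if not branch_pool:
            break
        comp, ids = branch_pool[int(rng.integers(len(branch_pool)))]
        a, b = rng.choice(ids, size=2, replace=False)
        rid = f"B{k+1}_{a.split('[')[0]}_{b.split('[')[0]}"
        if any(r["id"] == rid for r in rxns):
            continue
        reversible = rng.random() < frac_reversible
        add_rxn(rid, {a: -1.0, b: 1.0}, lb=-DEFAULT_BOUND if reversible else 0.0)

    # bypass exchanges: organelle-to-environment boundary reactions on
    # existing organelle metabolites (zero flux keeps the model feasible)
    org_mets = [m.id for m in mets if m.compartment != "cytosol"]
    if with_bypass_exchanges > len(org_mets):
        raise ValueError("not enough organelle metabolites for requested bypass exchanges")
    for k in range(with_bypass_exchanges):
        mid = org_mets[k % len(org_mets)]
        sign = -1.0 if k % 2 == 0 else 1.0
        add_rxn(f"EX_bypass{k+1}", {mid: sign}, role=ReactionRole.EXCHANGE)

    # GPRs on a fraction of internal (non-boundary, non-pseudo) reactions
    candidates = [
        r for r in rxns
        if r["role"] == ReactionRole.NORMAL
    ]
    n_gpr = int(round(frac_gpr * len(candidates)))
    chosen = rng.choice(len(candidates), size=n_gpr, replace=False) if n_gpr else []
    for gi, ci in enumerate(sorted(chosen)):
        u = rng.random()
        if u < 0.6:
            rule = f"g{gi+1:03d}a"
        elif u < 0.8:
            rule = f"g{gi+1:03d}a and g{gi+1:03d}b"
        else:
            rule = f"g{gi+1:03d}a or g{gi+1:03d}b"
        candidates[ci]["gpr"] = rule

    reactions = [
        Reaction(
            id=r["id"], index=j + 1, stoichiometry=r["stoichiometry"],
            lb=r["lb"], ub=r["ub"], gpr=parse_gpr(r["gpr"]), role=r["role"],
        )
        for j, r in enumerate(rxns)
    ]
    model = MetabolicModel(
        name=f"toy_seed{seed}", metabolites=mets, reactions=reactions,
        compartments=list(compartments),
    )
    # generation contract: the constrained polytope must be nonempty
    v = _feasible_point(model, FitConstraints().min_flux_map(model))
    if v is None:
        raise RuntimeError(f"generated model (seed {seed}) admits no feasible flux vector")
    return model


# ---------------------------------------------------------------------------
# Ground-truth fluxes
# ---------------------------------------------------------------------------


def _flux_lp_parts(model: MetabolicModel, min_flux: dict[str, float], cap: Optional[float]):
    lb, ub = model.bounds()
    if cap is not None:
        lb = np.maximum(lb, -cap)
        ub = np.minimum(ub, cap)
    rows, rhs = [], []
    for rid, minv in min_flux.items():
        j = model.reaction_position(rid)
        row = np.zeros(model.n_reactions)
        row[j] = -1.0
        rows.append(row)
        rhs.append(-minv)
    A_ub = np.array(rows) if rows else None
    b_ub = np.array(rhs) if rows else None
    S = model.stoichiometric_matrix()
    return S, A_ub, b_ub, lb, ub


def _feasible_point(model: MetabolicModel, min_flux: dict[str, float], cap: Optional[float] = None):
    S, A_ub, b_ub, lb, ub = _flux_lp_parts(model, min_flux, cap)
    res = linprog(
        np.zeros(model.n_reactions), A_ub=A_ub, b_ub=b_ub,
        A_eq=S, b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([lb, ub]), method="highs",
    )
    return res.x if res.status == 0 else None


def _l1_project(
    model: MetabolicModel,
    v_target: np.ndarray,
    min_flux: dict[str, float],
    cap: Optional[float],
    extra_rows: Optional[np.ndarray] = None,
    extra_rhs: Optional[np.ndarray] = None,
) -> Optional[np.ndarray]:
    """Feasible flux vector of minimal L1 distance to ``v_target``.

    Variables [v, e]; minimize sum e subject to e >= |v - v_target|, the
    constrained polytope, and optional extra <=-rows over v.
    """
    S, A_ub, b_ub, lb, ub = _flux_lp_parts(model, min_flux, cap)
    n = model.n_reactions
    eye = np.eye(n)
    A_abs = np.block([[eye, -eye], [-eye, -eye]])
    b_abs = np.concatenate([v_target, -v_target])
    blocks, rhs = [A_abs], [b_abs]
    for rows, rr in ((A_ub, b_ub), (extra_rows, extra_rhs)):
        if rows is not None and len(rows):
            blocks.append(np.hstack([rows, np.zeros((rows.shape[0], n))]))
            rhs.append(np.asarray(rr))
    A_full = np.vstack(blocks)
    b_full = np.concatenate(rhs)
    A_eq = sparse.hstack([S, sparse.csr_matrix((model.n_metabolites, n))], format="csr")
    res = linprog(
        np.concatenate([np.zeros(n), np.ones(n)]),
        A_ub=A_full, b_ub=b_full, A_eq=A_eq, b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack(
            [np.concatenate([lb, np.zeros(n)]), np.concatenate([ub, np.full(n, np.inf)])]
        ),
        method="highs",
    )
    return res.x[:n] if res.status == 0 else None


def draw_true_fluxes(
    model: MetabolicModel,
    seed: int,
    condition_effects: Optional[dict[str, float]] = None,
    n_objectives: int = 8,
    constraints: Optional[FitConstraints] = None,
    shrink: float = 0.3,
) -> np.ndarray:
    """Draw a feasible interior-leaning flux vector, with optional planted folds.

    The base vector is the average of ``n_objectives`` vertices obtained by
    maximizing random Gaussian objectives over the constrained flux polytope
    (fluxes capped at 1 so activities live in [0, 1]), shrunk by ``shrink``
    and L1-projected back onto the polytope so typical activities sit well
    below the cap and leave headroom for fold-changes. With
    ``condition_effects`` = {reaction id: fold}, the targeted activities are
    forced up to fold x their base value and the vector is re-projected onto
    the constrained polytope by minimizing the L1 distance to the base.
    """
    constraints = constraints if constraints is not None else FitConstraints()
    min_flux = constraints.min_flux_map(model)
    rng = np.random.default_rng(seed)
    S, A_ub, b_ub, lb, ub = _flux_lp_parts(model, min_flux, TRUE_FLUX_CAP)
    n = model.n_reactions
    pts = []
    for _ in range(n_objectives):
        c = rng.standard_normal(n)
        res = linprog(
            -c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(model.n_metabolites),
            bounds=np.column_stack([lb, ub]), method="highs",
        )
        if res.status != 0:
            raise RuntimeError(
                f"constrained flux polytope is empty or unbounded (status {res.status})"
            )
        pts.append(res.x)
    v0 = np.mean(pts, axis=0)
    if shrink < 1.0:
        proj = _l1_project(model, shrink * v0, min_flux, TRUE_FLUX_CAP)
        if proj is None:
            raise RuntimeError("shrink projection unexpectedly infeasible")
        v0 = proj
    if not condition_effects:
        return v0

    # plant folds: raise the targeted fluxes, then L1-project back to feasibility
    extra_rows, extra_rhs = [], []
    for rid, fold in condition_effects.items():
        rxn = model.reaction(rid)
        if rxn.gpr is None:
            raise ValueError(f"planted effect on {rid!r}, which carries no GPR")
        if rxn.reversible:
            raise ValueError(f"planted effect on reversible reaction {rid!r} unsupported")
        j = model.reaction_position(rid)
        target = fold * max(v0[j], 1e-3)
        if target > ub[j] + 1e-9:
            raise ValueError(
                f"fold {fold} on {rid!r} exceeds its flux cap ({target:.3g} > {ub[j]:.3g})"
            )
        row = np.zeros(n)
        row[j] = -1.0
        extra_rows.append(row)
        extra_rhs.append(-target)
    v = _l1_project(
        model, v0, min_flux, TRUE_FLUX_CAP,
        extra_rows=np.array(extra_rows), extra_rhs=np.array(extra_rhs),
    )
    if v is None:
        raise ValueError("planted effects are incompatible with feasibility")
    return v


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    model: MetabolicModel,
    v_true: np.ndarray,
    noise_sd: float,
    n_reps: int,
    seed: int,
) -> ExpressionMatrix:
    """Replicate expression whose GPR mapping recovers |v_true| in expectation.

    Single-gene rules get gene value = activity + noise. For a flat AND the
    first gene is limiting (value = activity) and partners are inflated
    (x1.5-2.5); for a flat OR the first gene dominates and partners are
    deflated (x0.3-0.8); deeper trees get all genes at the activity (min and
    max both recover it). A gene shared by several reactions keeps its first
    assignment. Noise is i.i.d. Gaussian per replicate, truncated at 0.
    """
    if n_reps < 2:
        raise ValueError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    targets: dict[str, float] = {}

    def assign(gene: str, value: float) -> None:
        targets.setdefault(gene, value)

    for j, rxn in enumerate(model.reactions):
        if rxn.gpr is None:
            continue
        act = abs(float(v_true[j]))
        node = rxn.gpr
        if isinstance(node, Gene):
            assign(node.name, act)
        elif isinstance(node, And) and all(isinstance(c, Gene) for c in node.children):
            assign(node.children[0].name, act)
            for c in node.children[1:]:
                assign(c.name, act * rng.uniform(1.5, 2.5))
        elif isinstance(node, Or) and all(isinstance(c, Gene) for c in node.children):
            assign(node.children[0].name, act)
            for c in node.children[1:]:
                assign(c.name, act * rng.uniform(0.3, 0.8))
        else:
            for g in sorted(gpr_genes(node)):
                assign(g, act)

    genes = sorted(targets)
    base = np.array([targets[g] for g in genes])
    noise = rng.normal(0.0, noise_sd, size=(len(genes), n_reps)) if noise_sd > 0 else np.zeros((len(genes), n_reps))
    values = np.maximum(base[:, None] + noise, 0.0)
    df = pd.DataFrame(values, index=genes, columns=[f"rep{i+1}" for i in range(n_reps)])
    return ExpressionMatrix(values=df)


# ---------------------------------------------------------------------------
# Scenario: the full two-condition study setup
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScenario:
    """Two-condition ground truth: model, true fluxes, expression, planted set."""

    model: MetabolicModel
    v_true_a: np.ndarray
    v_true_b: np.ndarray
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    planted_up_a: list[str]
    noise_sd: float
    n_reps: int
    seed: int
    constraints: FitConstraints = field(default_factory=FitConstraints)


def make_scenario(
    seed: int,
    n_internal: int = 10,
    compartments: Sequence[str] = ("cytosol", "chloroplast", "mitochondrion"),
    with_bypass_exchanges: int = 2,
    frac_reversible: float = 0.15,
    frac_gpr: float = 0.8,
    fold: float = 5.0,
    n_planted: int = 2,
    noise_sd: float = 0.05,
    n_reps: int = 3,
) -> SyntheticScenario:
    """Generate a complete two-condition scenario with planted fold-changes.

    Condition A carries ``n_planted`` reactions whose true activity is fold x
    that of condition B; replicate expression (3 replicates, truncated
    Gaussian noise sd 0.05 by default) is simulated per condition.
    """
    model = make_toy_model(
        seed,
        n_internal=n_internal,
        compartments=compartments,
        with_bypass_exchanges=with_bypass_exchanges,
        frac_reversible=frac_reversible,
        frac_gpr=frac_gpr,
    )
    rng = np.random.default_rng(seed + 1)
    # ground truth lives in the reduced model (bypass exchanges carry no
    # flux), so the fitted pipeline sees a realizable activity profile
    from .model import reduce_model

    red = reduce_model(model)
    v_b_red = draw_true_fluxes(red, seed + 2)
    # plantable: GPR-bearing, irreversible, and fold x base activity within the cap
    candidates = [
        r.id
        for r in red.reactions
        if r.gpr is not None
        and not r.reversible
        and r.role == ReactionRole.NORMAL
        and fold * max(v_b_red[red.reaction_position(r.id)], 1e-3) <= 0.9 * TRUE_FLUX_CAP
    ]
    if len(candidates) < n_planted:
        raise RuntimeError("not enough GPR-bearing irreversible reactions to plant effects")
    # jointly raising several fluxes can be infeasible under the cap for a
    # particular subset: bounded retries over candidate subsets
    v_a_red = planted = None
    for _ in range(25):
        trial = sorted(rng.choice(candidates, size=n_planted, replace=False).tolist())
        try:
            v_a_red = draw_true_fluxes(red, seed + 2, condition_effects={r: fold for r in trial})
        except ValueError:
            continue
        planted = trial
        break
    if planted is None:
        raise RuntimeError("could not plant a feasible effect set after bounded retries")

    def lift(v_red: np.ndarray) -> np.ndarray:
        v = np.zeros(model.n_reactions)
        for rid, val in zip(red.reaction_ids, v_red):
            v[model.reaction_position(rid)] = val
        return v

    v_a, v_b = lift(v_a_red), lift(v_b_red)
    expr_a = simulate_expression(model, v_a, noise_sd, n_reps, seed + 3)
    expr_b = simulate_expression(model, v_b, noise_sd, n_reps, seed + 4)
    return SyntheticScenario(
        model=model,
        v_true_a=v_a,
        v_true_b=v_b,
        expr_a=expr_a,
        expr_b=expr_b,
        planted_up_a=planted,
        noise_sd=noise_sd,
        n_reps=n_reps,
        seed=seed,
    )
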