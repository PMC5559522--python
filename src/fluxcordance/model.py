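"""Compartmented metabolic models: loading, validation, reduction.

The central container is :class:`MetabolicModel`: a stoichiometric matrix
``S`` (metabolites x reactions) over compartmented metabolites, with flux
bounds, GPR rules and reaction roles (biomass / maintenance / exchange /
transport / normal). Two dialects are supported: SBML Level 3 with the
FBC package (read through cobra) and a plain JSON dialect that round-trips
exactly and is the native format of the synthetic generator.

Model reduction removes boundary (exchange) reactions that bypass the
cytosol — organelle-to-environment exchanges — together with any
metabolites they leave orphaned. Keeping only cytosolic exchanges forces
all import/export to route through the cytosol, which is the physiological
topology of a plant cell and avoids spurious organelle shortcuts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import sparse

from .gpr import GPRNode, gpr_genes, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ReactionRole",
    "ModelValidationError",
    "ModelFormatError",
    "load_model",
    "write_json_model",
    "reduce_model",
    "steady_state_residual",
    "COMPARTMENT_ALIASES",
    "canonical_compartment",
]


class ModelValidationError(ValueError):
    """Model content violates a structural invariant (duplicate ids, ...)."""


class ModelFormatError(ValueError):
    """Model file cannot be parsed under the declared dialect."""


class ReactionRole(str, Enum):
    NORMAL = "normal"
    BIOMASS = "biomass"
    MAINTENANCE = "maintenance"
    EXCHANGE = "exchange"
    TRANSPORT = "transport"


#: Canonical compartment name -> accepted aliases (matched case-insensitively).
COMPARTMENT_ALIASES: dict[str, tuple[str, ...]] = {
    "cytosol": ("c", "cytosol", "cytoplasm", "cyto"),
    "chloroplast": ("h", "chloroplast", "plastid", "s"),
    "mitochondrion": ("m", "mitochondrion", "mitochondria"),
    "peroxisome": ("p", "peroxisome"),
    "environment": ("e", "environment", "extracellular", "external"),
}


def canonical_compartment(label: str, aliases: Optional[dict[str, tuple[str, ...]]] = None) -> str:
    """Map a free-form compartment label to its canonical name, if aliased."""
    aliases = COMPARTMENT_ALIASES if aliases is None else aliases
    low = label.lower()
    for canon, names in aliases.items():
        if low == canon or low in names:
            return canon
    return label


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    base_species: str = ""

    def __post_init__(self):
        if not self.base_species:
            object.__setattr__(self, "base_species", strip_compartment(self.id, self.compartment))


def strip_compartment(met_id: str, compartment: str) -> str:
    """Compartment-free identity of a metabolite id.

    Recognises the two common suffix conventions, ``species[comp]`` and
    ``species_comp`` (full label or any alias); otherwise the id itself is
    the base species.
    """
    canon = canonical_compartment(compartment)
    candidates = {compartment.lower(), canon.lower(), *[a.lower() for a in COMPARTMENT_ALIASES.get(canon, ())]}
    low = met_id.lower()
    for tag in sorted(candidates, key=len, reverse=True):
        if low.endswith(f"[{tag}]"):
            return met_id[: -(len(tag) + 2)]
        if low.endswith(f"_{tag}"):
            return met_id[: -(len(tag) + 1)]
    return met_id


@dataclass(frozen=True)
class Reaction:
    id: str
    index: int  # 1-based, matching published numbering / file order
    stoichiometry: dict[str, float]
    lb: float
    ub: float
    gpr: Optional[GPRNode] = None
    role: ReactionRole = ReactionRole.NORMAL

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def __post_init__(self):
        if self.lb > self.ub:
            raise ModelValidationError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")


@dataclass
class MetabolicModel:
    name: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    compartments: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.compartments:
            seen: list[str] = []
            for m in self.metabolites:
                if m.compartment not in seen:
                    seen.append(m.compartment)
            self.compartments = seen
        self._validate()
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}

    # -- structure ---------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def reaction_position(self, rxn_id: str) -> int:
        """0-based column of the reaction in S (its ``index`` field is 1-based)."""
        return self._rxn_index[rxn_id]

    def metabolite_position(self, met_id: str) -> int:
        return self._met_index[met_id]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def stoichiometric_matrix(self) -> sparse.csc_matrix:
        """S as a sparse N_met x N_R matrix; column j matches reaction j."""
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(j)
                vals.append(float(coeff))
        return sparse.csc_matrix(
            (vals, (rows, cols)), shape=(self.n_metabolites, self.n_reactions)
        )

    @property
    def lb(self) -> np.ndarray:
        return np.array([r.lb for r in self.reactions])

    @property
    def ub(self) -> np.ndarray:
        return np.array([r.ub for r in self.reactions])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lb, self.ub

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        indices = [r.index for r in self.reactions]
        if len(set(indices)) != len(indices):
            raise ModelValidationError("duplicate reaction indices")
        comp_set = set(self.compartments)
        known = set(met_ids)
        for m in self.metabolites:
            if m.compartment not in comp_set:
                raise ModelValidationError(
                    f"metabolite {m.id}: compartment {m.compartment!r} not declared"
                )
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in known:
                    raise ModelValidationError(
                        f"reaction {r.id} references undeclared metabolite {met_id!r}"
                    )
            if r.gpr is not None and any(not g for g in gpr_genes(r.gpr)):
                raise ModelValidationError(f"reaction {r.id}: empty gene token in GPR")

    # -- roles -------------------------------------------------------------

    def is_boundary(self, rxn: Reaction) -> bool:
        """One-sided stoichiometry: pure source or pure sink."""
        coeffs = [c for c in rxn.stoichiometry.values() if c != 0]
        if not coeffs:
            return False
        return all(c > 0 for c in coeffs) or all(c < 0 for c in coeffs)

    def infer_role(self, rxn: Reaction) -> ReactionRole:
        if rxn.role != ReactionRole.NORMAL:
            return rxn.role
        if self.is_boundary(rxn):
            return ReactionRole.EXCHANGE
        comps = {self.metabolite(m).compartment for m in rxn.stoichiometry}
        if len(comps) > 1:
            return ReactionRole.TRANSPORT
        return ReactionRole.NORMAL

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            name=self.name,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            compartments=list(self.compartments),
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def load_model(path: Union[str, Path], dialect: str = "auto") -> MetabolicModel:
    """Load a metabolic model from SBML (L3 + FBC) or the JSON dialect.

    Reaction 1-based indices follow file order. ``dialect="auto"`` picks by
    extension (.xml/.sbml -> sbml, .json -> json).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if dialect == "json":
        return _load_json(path)
    if dialect == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing required key {key!r}")
    mets = [
        Metabolite(id=m["id"], compartment=m["compartment"], base_species=m.get("base_species", ""))
        for m in doc["metabolites"]
    ]
    rxns = []
    for j, r in enumerate(doc["reactions"]):
        try:
            gpr = parse_gpr(r.get("gpr", "") or "")
        except ValueError as exc:
            raise ModelFormatError(f"{path}: reaction {r.get('id')}: {exc}") from exc
        rxns.append(
            Reaction(
                id=r["id"],
                index=j + 1,
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                gpr=gpr,
                role=ReactionRole(r.get("role", "normal")),
            )
        )
    return MetabolicModel(
        name=doc.get("name", path.stem),
        metabolites=mets,
        reactions=rxns,
        compartments=list(doc.get("compartments", [])),
    )


def _load_sbml(path: Path) -> MetabolicModel:
    import cobra.io  # heavy import, deferred

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises assorted types on bad files
        raise ModelFormatError(f"{path}: SBML parse failure ({exc})") from exc
    comp_names = dict(cm.compartments)  # id -> (possibly empty) name
    mets = [
        Metabolite(id=m.id, compartment=canonical_compartment(comp_names.get(m.compartment) or m.compartment))
        for m in cm.metabolites
    ]
    rxns = []
    for j, r in enumerate(cm.reactions):
        rule = r.gene_reaction_rule or ""
        rxns.append(
            Reaction(
                id=r.id,
                index=j + 1,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                gpr=parse_gpr(rule),
            )
        )
    return MetabolicModel(name=cm.id or path.stem, metabolites=mets, reactions=rxns)


def write_json_model(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Serialize to the JSON dialect; read-back reproduces S, bounds, GPRs."""
    doc = {
        "name": model.name,
        "compartments": model.compartments,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "base_species": m.base_species}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lb": r.lb,
                "ub": r.ub,
                "gpr": r.gpr.to_string() if r.gpr is not None else "",
                "role": r.role.value,
            }
            for r in model.reactions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


# ---------------------------------------------------------------------------
# Reduction and steady state
# ---------------------------------------------------------------------------


def reduce_model(model: MetabolicModel, cytosol: str = "cytosol") -> MetabolicModel:
    """Remove boundary exchanges that bypass the cytosol.

    A reaction is an exchange iff its stoichiometry is one-sided (pure source
    or sink) or its role is explicitly ``exchange``; it bypasses the cytosol
    iff none of its metabolites lives in the cytosol compartment. Metabolites
    participating in no remaining reaction are dropped as well. Idempotent.
    """
    cyto = canonical_compartment(cytosol)
    comp_canon = {c: canonical_compartment(c) for c in model.compartments}
    if cyto not in comp_canon.values():
        raise ModelValidationError(
            f"model {model.name!r} declares no {cyto!r} compartment: {model.compartments}"
        )

    def bypasses_cytosol(rxn: Reaction) -> bool:
        comps = {comp_canon[model.metabolite(m).compartment] for m in rxn.stoichiometry}
        return cyto not in comps

    kept: list[Reaction] = []
    for rxn in model.reactions:
        is_exchange = rxn.role == ReactionRole.EXCHANGE or (
            rxn.role == ReactionRole.NORMAL and model.is_boundary(rxn)
        )
        if is_exchange and bypasses_cytosol(rxn):
            continue
        kept.append(rxn)
    used = {m for r in kept for m in r.stoichiometry}
    mets = [m for m in model.metabolites if m.id in used]
    rxns = [replace(r, index=j + 1) for j, r in enumerate(kept)]
    return MetabolicModel(
        name=model.name + "_reduced" if not model.name.endswith("_reduced") else model.name,
        metabolites=mets,
        reactions=rxns,
        compartments=[c for c in model.compartments if any(m.compartment == c for m in mets)],
    )


def steady_state_residual(model: MetabolicModel, v: Sequence[float]) -> float:
    """Max-norm of S @ v (0 for a steady-state flux distribution)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (model.n_reactions,):
        raise ValueError(
            f"flux vector has shape {v.shape}, expected ({model.n_reactions},)"
        )
    S = model.stoichiometric_matrix()
    return float(np.max(np.abs(S @ v))) if model.n_metabolites else 0.0
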