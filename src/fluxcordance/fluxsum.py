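"""Metabolite flux-sums: turnover descriptors over sampled flux distributions.

For a flux distribution v* and a metabolite m, the flux-sum is

    f_m = sum_{j in R_m} |v*_j|

where R_m indexes every reaction in which m participates as substrate or
product. The sum is unweighted by stoichiometric coefficients and carries
no 1/2 production/consumption factor (the ``classic`` variant,
f_m = 1/2 * sum |s_mj v_j|, is available for comparison).

Two namespaces are supported: *compartmental*, where each subcellular
localization of a species is its own metabolite (key ``species[comp]``),
and *pooled*, where R_m* is the union over all compartments of a base
species (key ``species[*]``) — matching bulk measurements that cannot
resolve organelles. A transporter moving a species between compartments
appears once in the pooled set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MetabolicModel
from .optima import FluxSample

__all__ = ["FluxSumSample", "reaction_index_set", "flux_sums", "metabolite_keys"]


@dataclass
class FluxSumSample:
    """n x M matrix of flux-sum values over sampled flux distributions."""

    values: np.ndarray
    index: list[str]  # "species[compartment]" or "species[*]"
    mode: str  # "compartmental" | "pooled"

    def column(self, key: str) -> np.ndarray:
        return self.values[:, self.index.index(key)]


def metabolite_keys(model: MetabolicModel, mode: str) -> list[str]:
    if mode == "compartmental":
        return [f"{m.base_species}[{m.compartment}]" for m in model.metabolites]
    if mode == "pooled":
        seen: list[str] = []
        for m in model.metabolites:
            key = f"{m.base_species}[*]"
            if key not in seen:
                seen.append(key)
        return seen
    raise ValueError(f"mode must be 'compartmental' or 'pooled', got {mode!r}")


def reaction_index_set(model: MetabolicModel, key: str, mode: str = "compartmental") -> set[int]:
    """0-based reaction positions of R_m for a metabolite key.

    Compartmental keys are either a metabolite id or ``species[compartment]``;
    pooled keys are ``species[*]`` or a bare base-species name. Each reaction
    appears at most once (union semantics in pooled mode).
    """
    if mode == "compartmental":
        targets = set()
        for m in model.metabolites:
            if key == m.id or key == f"{m.base_species}[{m.compartment}]":
                targets.add(m.id)
        if not targets:
            raise KeyError(f"unknown compartmental metabolite key {key!r}")
    elif mode == "pooled":
        base = key[:-3] if key.endswith("[*]") else key
        targets = {m.id for m in model.metabolites if m.base_species == base}
        if not targets:
            raise KeyError(f"unknown base species {base!r}")
    else:
        raise ValueError(f"mode must be 'compartmental' or 'pooled', got {mode!r}")
    return {
        j
        for j, rxn in enumerate(model.reactions)
        if any(mid in targets and coeff != 0 for mid, coeff in rxn.stoichiometry.items())
    }


def flux_sums(
    sample: FluxSample,
    model: MetabolicModel,
    mode: str = "compartmental",
    variant: str = "plain",
) -> FluxSumSample:
    """Flux-sum matrix for every metabolite key under the given mode.

    ``variant="plain"`` (default) is the unweighted sum of absolute net
    fluxes over R_m; ``variant="classic"`` uses 1/2 * sum |s_mj * v_j|.
    """
    if sample.values.shape[1] != model.n_reactions:
        raise ValueError("sample and model disagree on reaction count")
    if variant not in {"plain", "classic"}:
        raise ValueError(f"variant must be 'plain' or 'classic', got {variant!r}")
    keys = metabolite_keys(model, mode)
    absv = np.abs(sample.values)
    cols = []
    for key in keys:
        idx = sorted(reaction_index_set(model, key, mode))
        if not idx:
            cols.append(np.zeros(sample.values.shape[0]))
            continue
        if variant == "plain":
            cols.append(absv[:, idx].sum(axis=1))
        else:
            coeffs = _pooled_coeffs(model, key, mode, idx)
            cols.append(0.5 * (absv[:, idx] * np.abs(coeffs)[None, :]).sum(axis=1))
    return FluxSumSample(values=np.column_stack(cols), index=keys, mode=mode)


def _pooled_coeffs(model: MetabolicModel, key: str, mode: str, idx: list[int]) -> np.ndarray:
    """Summed |stoichiometric coefficient| of the key's metabolites per reaction."""
    if mode == "compartmental":
        targets = {
            m.id
            for m in model.metabolites
            if key == m.id or key == f"{m.base_species}[{m.compartment}]"
        }
    else:
        base = key[:-3] if key.endswith("[*]") else key
        targets = {m.id for m in model.metabolites if m.base_species == base}
    out = []
    for j in idx:
        rxn = model.reactions[j]
        out.append(sum(abs(c) for mid, c in rxn.stoichiometry.items() if mid in targets))
    return np.array(out)
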