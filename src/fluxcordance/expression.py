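"""Mapping replicate gene expression onto reactions via GPR rules.

The data flow mirrors standard transcriptome integration for
constraint-based models: per replicate, each reaction with a GPR rule gets
the rule's numeric value (AND = min, OR = max over resolved genes); across
replicates a mean and a sample standard deviation are formed; means are
scaled to the per-experiment maximum so the data vector d lives in [0, 1];
the replicate standard deviation (on the same scale) drives a per-reaction
residual weight w = 1 / max(sigma, eps), so reactions whose expression is
inconsistent across replicates pull less on the fit.

Input expression is expected as an already-normalized gene x replicate
table (>= 2 replicates); microarray/RNA-seq preprocessing is upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .gpr import eval_gpr
from .model import MetabolicModel

__all__ = [
    "ExpressionMatrix",
    "ReactionData",
    "read_expression_tsv",
    "map_expression",
    "summarize_and_scale",
    "reaction_data_from_expression",
    "DEFAULT_SIGMA_FLOOR",
]

DEFAULT_SIGMA_FLOOR = 0.01  # on the scaled [0, 1] axis


@dataclass
class ExpressionMatrix:
    """Gene x replicate expression values (normalized units, >= 0)."""

    values: pd.DataFrame  # index: gene ids, columns: replicate labels

    def __post_init__(self):
        df = self.values
        if df.shape[1] < 2:
            raise ValueError(f"need >= 2 replicates, got {df.shape[1]}")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def replicates(self) -> list[str]:
        return list(self.values.columns)


def read_expression_tsv(path: Union[str, Path]) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column, replicates after."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df)


@dataclass
class ReactionData:
    """Per-reaction fit data: scaled mean d, scaled replicate std, weight.

    ``table`` is indexed by reaction id with columns ``d``, ``sigma``, ``w``,
    ``mapped``; unmapped reactions carry NaN in d/sigma/w and mapped=False.
    """

    table: pd.DataFrame
    scale: float  # the global max mean the data was divided by

    @property
    def mapped_ids(self) -> list[str]:
        return list(self.table.index[self.table["mapped"]])

    def d(self, rxn_id: str) -> float:
        return float(self.table.at[rxn_id, "d"])

    def w(self, rxn_id: str) -> float:
        return float(self.table.at[rxn_id, "w"])

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, sep="\t", index_label="reaction_id")


def map_expression(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    missing_gene: str = "ignore",
) -> pd.DataFrame:
    """Evaluate every reaction's GPR per replicate.

    Returns a reactions x replicates table containing only reactions whose
    GPR resolved in at least one replicate (in practice: in all, since
    gene presence does not vary across replicates).

    ``missing_gene="ignore"`` drops absent genes from their operator (the
    default: a missing probe is missing data); ``"zero"`` treats them as
    zero expression.
    """
    if missing_gene not in {"ignore", "zero"}:
        raise ValueError(f"missing_gene must be 'ignore' or 'zero', got {missing_gene!r}")
    rows: dict[str, list[float]] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        vals = []
        for rep in expr.replicates:
            col = expr.values[rep]
            gene_values = col.to_dict()
            if missing_gene == "zero":
                from .gpr import gpr_genes

                for g in gpr_genes(rxn.gpr):
                    gene_values.setdefault(g, 0.0)
            v = eval_gpr(rxn.gpr, gene_values)
            if v is None:
                vals = []
                break
            vals.append(v)
        if vals:
            rows[rxn.id] = vals
    if not rows:
        raise ValueError(
            "no reaction GPR resolved against the expression matrix: "
            "gene identifier namespaces likely differ"
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.replicates)


def summarize_and_scale(
    mapped: pd.DataFrame,
    model: MetabolicModel,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> ReactionData:
    """Replicate mean/std per reaction, scaled to the experiment maximum.

    The mean and the sample (n-1) standard deviation are computed over
    replicates; both are divided by the max mean so d in [0, 1] and sigma
    stays on d's scale. Weights are w = 1 / max(sigma, sigma_floor).
    """
    if mapped.shape[1] < 2:
        raise ValueError("need >= 2 replicates to estimate a standard deviation")
    means = mapped.mean(axis=1)
    stds = mapped.std(axis=1, ddof=1)
    scale = float(means.max())
    if scale <= 0:
        raise ValueError("all mapped expression means are zero; scaling undefined")
    d = means / scale
    sigma = stds / scale
    w = 1.0 / np.maximum(sigma, sigma_floor)
    table = pd.DataFrame(index=[r.id for r in model.reactions], dtype=float)
    table["d"] = d
    table["sigma"] = sigma
    table["w"] = w
    table["mapped"] = table.index.isin(mapped.index)
    return ReactionData(table=table, scale=scale)


def reaction_data_from_expression(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    missing_gene: str = "ignore",
) -> ReactionData:
    """Convenience composition: map_expression then summarize_and_scale."""
    return summarize_and_scale(map_expression(model, expr, missing_gene), model, sigma_floor)
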