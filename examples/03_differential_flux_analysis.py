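"""Two-condition differential flux and flux-sum analysis on synthetic data.

Generates a compartmented toy model with known ground truth: condition A
carries two reactions whose true activity is 5x that of condition B, and
replicate expression (3 replicates, truncated-Gaussian noise) is simulated
for both conditions. The pipeline reduces the model, fits each condition by
weighted LAD, samples each alternative-optima space, and compares per-
reaction flux distributions with the dual Mann-Whitney rule. The planted
reactions should be recovered as significant with direction A_greater;
pooled metabolite flux-sums show the knock-on turnover changes.
"""

from fluxcordance.expression import reaction_data_from_expression
from fluxcordance.fluxsum import flux_sums
from fluxcordance.model import reduce_model
from fluxcordance.optima import build_optimal_space, sample_optima
from fluxcordance.stats import differential_flux_report, differential_fluxsum_report
from fluxcordance.synth import make_scenario

sc = make_scenario(seed=7)  # fold 5, noise sd 0.05, 3 replicates
model = reduce_model(sc.model)
print(f"model: {model.n_reactions} reactions after reduction; planted: {sc.planted_up_a}")

samples = {}
for label, expr, seed in (("A", sc.expr_a, 21), ("B", sc.expr_b, 22)):
    data = reaction_data_from_expression(model, expr)
    space = build_optimal_space(model, data, sc.constraints)
    samples[label] = sample_optima(space, n=1000, seed=seed, warmup=500, thin=10)
    print(f"condition {label}: z* = {space.z_star:.3f}")

rep = differential_flux_report(samples["A"], samples["B"])
sig = rep.table[rep.table["significant"]].sort_values("p_two")
print(f"\n{len(sig)} of {len(rep.table)} reactions differential at alpha = 0.05")
print("planted reactions in the report:")
print(sig.loc[sig.index.intersection(sc.planted_up_a),
              ["mean_A", "mean_B", "ratio_A_over_B", "p_two", "direction"]].round(4))

fs_rep = differential_fluxsum_report(
    flux_sums(samples["A"], model, "pooled"),
    flux_sums(samples["B"], model, "pooled"),
)
top = fs_rep.table[fs_rep.table["significant"]].sort_values("p_two").head(5)
print("\ntop differential pooled flux-sums (metabolite turnover):")
print(top[["mean_A", "mean_B", "ratio_A_over_B", "direction"]].round(4))
print(
    "\nFluxes are fitted in per-condition relative units (expression is "
    "scaled to each experiment's maximum), so the mean ratio understates "
    "the raw planted fold; what the dual Mann-Whitney test certifies is "
    "that the planted reactions carry significantly larger flux in A, with "
    "the turnover of the metabolites they touch shifting accordingly."
)
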