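# Methods

This note documents the models, algorithms and numerical choices behind
`fluxcordance`, in the order the pipeline applies them.

## Model handling and reduction

A metabolic model is a compartmented stoichiometric system: metabolites with
compartment labels (matched case-insensitively against an alias table —
cytosol/c, chloroplast/h/plastid, mitochondrion/m, peroxisome/p — because
SBML dialects disagree), reactions with bounds, GPR rules and roles
(biomass, maintenance, exchange, transport, normal). A reaction is detected
as a boundary *exchange* iff its stoichiometry is one-sided (pure source or
sink), the standard criterion; roles set explicitly in the file are
respected.

**Reduction** removes every exchange whose metabolites all lie outside the
cytosol. Such organelle-to-environment shortcuts let the solver bypass
cytosolic transport and bias flux predictions; removing them forces all
import/export through the cytosol, the physiological topology of a plant
cell. Metabolites orphaned by the removal are dropped as well — the
operation changes both the reaction and the metabolite count. Reduction is
idempotent and never touches a reaction with a cytosolic participant.
Reported reaction indices are 1-based in file order, so rows of any report
can be traced back to the published numbering of a model.

## Expression integration

Input is an already normalized gene × replicate table (≥ 2 replicates);
microarray/RNA-seq preprocessing and probe-to-gene mapping are upstream and
out of scope. Per replicate, each reaction's GPR is evaluated numerically:
AND (enzyme complex) → minimum of its resolved genes, OR (isozymes) →
maximum. Genes absent from the table are treated as missing data, not as
zero expression — they are dropped from their operator, and a rule with no
resolvable leaf is unmapped. (A `missing_gene="zero"` mode exists for
sensitivity checks.) Replicate means and sample (n−1) standard deviations
are computed per reaction, then both are divided by the maximum mean of the
experiment, so the data vector d lives in [0, 1] and is invariant to
rescaling the whole matrix.

The replicate standard deviation enters the fit as an inverse weight,
w = 1 / max(σ, ε) with ε = 0.01 on the scaled axis: reactions whose
expression is inconsistent across replicates pull less on the fit. A weight
— rather than a transform of d — keeps the data values interpretable and the
objective linear; the functional form is exposed in config since other
choices (dividing the data, dividing the residual) are defensible.

## The weighted LAD fit

The fit minimizes Σᵢ wᵢ·|aᵢ(v) − dᵢ| over steady-state flux distributions
(S·v = 0, bounds), with the activity aᵢ = vᵢ⁺ + vᵢ⁻ after splitting each
reversible reaction into two nonnegative half-fluxes. Expression is
signless evidence of enzyme activity, so the residual matches activity, not
net flux; the split keeps everything linear. Each absolute residual is
linearized with a slack eᵢ ≥ |aᵢ − dᵢ|, giving one LP solved with HiGHS
(through `scipy.optimize.linprog`; feasibility tolerance 1e-9, reported
constraints verified at 1e-6).

Hard constraints: biomass flux ≥ 1e-6 (the model must "live"), each
maintenance reaction (non-metabolic ATP consumption, typically one per
energized compartment) ≥ 0.001, plus optional per-reaction minimum-flux
bounds and flux-ratio constraints. A ratio bound r_lb ≤ v_C/v_O ≤ r_ub
(e.g. RuBisCO carboxylation vs oxygenation, with r_lb = 1.5, r_ub = 4 the
physiological range) is linearized exactly as r_lb·v_O − v_C ≤ 0 and
r_ub·v_O − v_C ≥ 0 for irreversible pairs; at v_O = 0 the pair forces
v_C = 0. Minimum-flux bounds can be *calibrated* as a fraction (e.g. 20%)
of a reaction's maximum flux over the alternative-optima space, so the
bound is meaningful on the model's own flux scale.

No regularization is applied by default — the optimal set should be exactly
the set of equally data-concordant flux distributions. An optional L1 flux
penalty λ·Σaⱼ (default λ = 0) is available to discourage loops through
data-free reactions. A degenerate split (v⁺, v⁻ simultaneously positive) is
permitted; the sampler and FVA treat activity and net flux consistently.
Infeasible or unbounded programs are reported as such, never silently
relaxed.

## The alternative-optima space

Fixing the objective at its optimum with a relative tolerance of 1e-6
(plus 1e-9 absolute — exact equality would make the face numerically empty)
defines the polytope of equally data-concordant flux distributions, in the
split-variable space.

**FVA over optima** solves two LPs per reaction (min and max net flux) over
that polytope. **Sampling** uses hit-and-run: from an interior point (the
average of the LAD optimum and all FVA vertex solutions — a convex
combination, hence inside), each step draws a direction, computes the
feasible chord exactly (bounds and linear rows in closed form; the convex
piecewise-linear objective budget by a breakpoint walk), and jumps to a
uniformly chosen point of the chord. Warmup 1000 steps and thinning 10 by
default; n = 20 000 stored samples per condition by default (tests and the
acceptance analysis use n ≤ 5000 to keep runtimes in seconds-to-minutes).

Direction choice matters more than usual here. The optimal face is
extremely thin in the coordinates pinned by the data (the budget allows
only ~1e-6-scale residual trades), so isotropic directions in the null
space of S produce near-zero chords and the chain freezes in the directions
the data leave free. Directions are therefore drawn as an 80/20 mixture of
(a) differences of two random FVA vertex solutions — these span exactly the
affine hull of the optimal face, the same idea as ACHR-type samplers used
for flux-space sampling — and (b) isotropic null-space directions. The
vertex pool is fixed before sampling, so the kernel remains a proper Markov
chain with the uniform law invariant. On a one-dimensional optimal set the
scheme is exactly uniform (verified by Kolmogorov-Smirnov distance < 0.05
at n = 5000); in higher dimension it is asymptotically uniform, and every
sample row is verified against steady state, bounds, the objective budget
and the FVA ranges (`check_sample`). Whether the original notion of a
"uniform sample of alternative optima" means volume-uniform or
vertex-uniform is ambiguous; volume-uniform is implemented.

## Flux-sums

For each sampled flux distribution, the flux-sum of metabolite m is
f_m = Σ_{j∈R_m} |v*_j| with R_m all reactions in which m participates as
substrate or product — deliberately unweighted by stoichiometric
coefficients and without the conventional ½ factor (the `classic` variant
½·Σ|s_mj·v_j| is available for comparison). |v| is the net flux magnitude.
Two namespaces: *compartmental* (each localization its own metabolite,
keys `species[compartment]`) and *pooled* (R_m* is the union over
compartments, keys `species[*]`), matching bulk measurements that cannot
resolve organelles. A transporter counts once in the pooled set, so
compartmental ≤ pooled ≤ sum-of-compartmental holds per base species.

## Differential testing

Per item (reaction flux or metabolite flux-sum), the two cell types'
sampled distributions are compared with Mann-Whitney tests: both
right-tailed directions and the two-tailed test. An item is *differential*
only if it passes the two-tailed test **and** the right-tailed test of the
winning side, both at α = 0.05 — the dual-pass rule prevents calls where
the two test families disagree. Means and their A/B ratio are reported for
interpretability only (ratio undefined when |mean_B| < 1e-12); calls are
made on distributions, never on means. No multiple-testing correction is
applied by default, matching the raw-α convention of this analysis style; a
Benjamini-Hochberg option exists.

Exact p-values (full enumeration over rank assignments, midranks for ties)
are used below a combined sample size of 20; larger samples use the normal
approximation with continuity and tie correction. Identical constant
samples short-circuit to p = 1.

A caveat stated rather than hidden: the sampler's draws are Markov-chain
dependent, and rank tests on thousands of dependent draws are nominally
anticonservative. With the mixed direction scheme and thinning ≥ 20 the
null rejection rate on these toys is near α (measured 0.04–0.14), but the
procedure's significance calls on dense chains should be read as a ranking
device, not calibrated error rates. The thinning parameter is exposed.

**Scenario comparison**: p-value vectors of two runs (e.g. with and without
ratio constraints) are binarized (p < α → 0, else 1) and compared by
Hamming distance, with an optional exclusion list for reactions directly
affected by the added constraints. The two-tailed p-value is the default
binarization; the dual-test flag is available.

## Synthetic data

The generator builds compartmented toy networks with the structural
features the pipeline must survive: a linear backbone threading cytosol and
organelles with explicit transporters, random same-compartment branch
reactions (a fraction reversible), an ATP/ADP energy subsystem with one
maintenance reaction per energized compartment, a biomass sink, cytosolic
boundary exchanges, organelle-to-environment bypass exchanges (which model
reduction must remove), and AND/OR GPRs on a configurable fraction of
internal reactions.

Ground-truth fluxes are averages of random-objective LP vertices of the
constrained flux polytope (interior-leaning), shrunk to ~30% of the flux
cap and re-projected so typical activities sit well below 1 and leave
headroom for planted fold-changes; fluxes are capped at 1 so that, at zero
noise, the max-scaled data vector is exactly the activity profile of a
feasible flux distribution and the fit attains z* = 0 (the noiseless
identifiability check). Condition A plants fold-5 effects on a feasible
subset of GPR-bearing irreversible reactions (bounded retries over subsets,
since joint folds can be infeasible under the cap). Truth is drawn on the
*reduced* model and lifted with zeros on the bypass exchanges, so the
pipeline's reduction step never invalidates it.

Replicate expression is simulated per gene so the GPR mapping recovers the
true activity in expectation: single genes sit at the activity; the
limiting gene of an AND complex sits at the activity with partners inflated
×1.5–2.5; the dominant OR isozyme sits at the activity with partners
deflated ×0.3–0.8. Noise is additive Gaussian (sd 0.05 by default, 3
replicates), truncated at zero since expression is nonnegative.

What the synthetic conditions do **not** emulate: probe effects, batch
effects, cross-platform normalization, many-to-many gene-reaction maps,
thermodynamic (loop-law) infeasibilities, or the size of a genome-scale
model (~30 vs ~455 reactions). Passing tests therefore establish the
correctness of the machinery — fit optimality, polytope characterization,
test calibration on planted truths — not the biological fidelity of any
specific prediction on real data.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| biomass_min | 1e-6 | minimal biomass flux (arbitrary flux units) |
| maintenance_min | 0.001 | minimal flux per maintenance reaction |
| sigma floor ε | 0.01 | weight cap w ≤ 100 on the scaled data axis |
| λ | 0 | optional L1 flux penalty |
| opt_tol / abs_tol | 1e-6 / 1e-9 | objective budget defining the optimal face |
| n samples | 20 000 | stored draws per condition (analyses here use ≤ 5000) |
| warmup / thin | 1000 / 10 | chain burn-in and thinning |
| α | 0.05 | per-item significance level, dual-pass rule |
| r_lb, r_ub | 1.5, 4 | carboxylation/oxygenation ratio bounds when enabled |
| calibration fraction | 0.2 | minimum-flux bound as a share of optimal-space max |

## Known limitations

- Dual MW significance on dependent chain draws is nominally inflated (see
  above); thinning trades runtime for calibration.
- Volume-uniform sampling of the optimal face is the declared
  interpretation; vertex-uniform sampling would weight the same face
  differently.
- Max-scaling puts each condition's fluxes on its own relative scale;
  between-condition mean ratios understate raw fold-changes whenever the
  scaling reaction itself differs between conditions. Significance calls
  are unaffected (they are rank-based within items).
- Ratio constraints require irreversible numerator/denominator reactions
  (validated), as for RuBisCO's two half-activities.
- No MILP submodel extraction, no quadratic (least-squares) fit variant, no
  gap-filling or model curation: models are taken as given.
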