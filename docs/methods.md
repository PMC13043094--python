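# Methods

This note documents the models, defaults and numerical choices behind
`layerprot`, and what the synthetic-data experiments do and do not
establish about real data.

## Study design and simulation model

`generate_design` builds the paired stricture cohort: each case
individual contributes a strictured (STR) and a non-strictured (NSTR)
sample per layer, each control (CTRL) individual one sample per layer.
With the default 12 cases + 8 controls this yields 32 sample channels per
layer, dealt into two 16-channel multiplex sets (pairs are never split
across sets; groups are balanced across sets by round-robin assignment).
NSTR samples are refined into stricture-adjacent (Adj) and distal (Dist)
subgroups, alternating across cases (6/6 by default). Every set carries a
pooled reference channel and a booster channel. The reference pool is
formed per layer from equal aliquots of all samples — a single pool
serves both sets of a layer — and the booster is a high-input STR pool
(default 10× the mean STR amount); the booster is excluded from all
statistics.

Intensities are log-normal at the protein level:

    log2 intensity = baseline + group_effect + b_individual + s_set + eps

with per-protein baselines drawn from N(11, 1.5²) on the log2 scale
(arbitrary units typical of reporter-ion summaries). Defaults for the
variance components, chosen once as representative of protein-level
isobaric data and used as the fixed study conditions throughout the test
suite:

| parameter | default | meaning |
|---|---|---|
| sigma_individual | 0.35 | between-individual biological SD (log2) |
| sigma_set | 0.20 | additive multiplex-set batch SD |
| sigma_meas_tmt | 0.15 | TMT measurement SD |
| sigma_meas_lf | 0.25 | label-free measurement SD |
| rho_platforms | 0.5 | correlation of the two platforms' errors |
| lf_dropout_midpoint / slope | 8.0 / 1.0 | logistic missingness in log2 intensity |

Both platforms share the latent biological signal (baseline + effect +
individual intercept) because they measure aliquots of the same samples;
`rho_platforms` splits the measurement error into a shared and a private
component, which is the dial that makes dependence-aware p-value merging
testable. TMT missingness is structural only (a configurable fraction of
proteins is present in a single set); label-free missingness is
intensity-dependent (missing-not-at-random, MNAR).

Planted effects: DE proteins get |log2 effect| from a truncated normal
(mean 1.5, SD 0.4, floor 0.8 by default — the regime of the strongly
changed proteins that gradient analyses focus on; recovery experiments
that need specific effect sizes set them explicitly). Trend classes place
the Adj/Dist effects on the CTRL = 0, STR = 1 axis: progressive
(x_adj ≈ 0.45–0.65 with y_dist at 40–60 % of x), adjacent-saturating
(x ≈ 1, y ≈ 0.3–0.5), early-shift (x ≈ y ≈ 1), jittered uniformly inside
those windows so planted classes sit inside their classification cells.

What the generator does **not** emulate: peptide-level rollup, isotopic
impurity / ratio compression, per-sample loading differences, and
correlated protein modules. Passing recovery tests therefore demonstrates
the pipeline's correctness under its own assumptions, not robustness to
every artifact of real MS data.

## Tissue-area standardization

Regions are axis-aligned rectangles (rows = radial axis, fixed; columns =
lateral axis, tuned; 0-based half-open intervals; lateral width =
2 × halfwidth). Net area is the foreground-pixel count times
(µm/px)²/10⁶. The search finds the smallest integer halfwidth whose area
reaches the target by bisection (monotonicity makes this exact in
≤ log2(width)+1 steps); if discrete columns overshoot the target by more
than the tolerance, the smallest halfwidth reaching target − tol is used
and the residual recorded. Default tolerance: 0.5 % of the target — the
target itself defaults to 44 mm², and sub-pixel exactness is unattainable
on integer widths. Serial sections are consumed greedily; sections beyond
the target are left untouched.

## Normalization

TMT: value = log2(sample / same-set reference), then per-sample median
centering. The reference ratio removes per-protein loading and, because
the reference is shared, carries quantities across sets.

Label-free: log2, per-sample raw-median centering over the
complete-observation proteins, then a second per-sample refinement using
medians of deviations from each protein's cross-sample median (the
protein medians are also subtracted; they are per-protein constants, so
group contrasts are untouched). The first pass absorbs per-sample scaling
exactly; the second tightens the offsets on a concentrated basis.

A finding worth recording: with MNAR dropout **and** a large DE fraction,
any median-based per-sample centering acquires a small group-dependent
offset, because dropout biases which proteins are complete and the DE
proteins contaminate the centering basis asymmetrically. At the default
study conditions (10 % DE) the resulting combined-level WE attenuation is
about −0.01 to −0.04 log2 units (worst at effect 2.0), within the ±0.05
recovery bound; at 20 %+ DE fractions it roughly doubles. The TMT
reference-ratio route is immune. Interpret label-free-only effect sizes
from heavily perturbed datasets with this in mind.

Batch handling for PCA restricts to complete-observation proteins and
removes per-set protein means (adding back the grand mean), which removes
an additive set effect exactly while leaving within-set contrasts
untouched.

## Mixed-model differential expression

Per protein: `abundance ~ group + set + (1 | individual)`, REML. The set
term is omitted exactly when the protein is quantified in one set. The
fit profiles the likelihood on the variance ratio λ = σ_b²/σ_e², solving
the stationarity equation of the profiled REML criterion with Brent
root-finding to near machine precision; λ = 0 boundary solutions fall
back to the fixed-effects model with residual degrees of freedom.

Contrasts are differences of estimated marginal means averaged over set
levels with equal weights; in this additive model the set coefficients
cancel, so a contrast is a linear function of the group coefficients.
Degrees of freedom use the Satterthwaite approximation with an analytic
gradient and the expected REML information; in balanced designs this is
exact (the paired two-group case reproduces the closed-form paired t-test
to ~1e-12, df = n−1). Kenward–Roger, the common alternative in mixed-model
front ends, agrees closely on this near-balanced design; a cross-check
against R's lmerTest/emmeans (observed-Hessian Satterthwaite) shows
identical estimates and p-values within ~1e-3 on the 32-sample design.
The df method is recorded in output metadata.

FDR families are per (layer, platform, comparison); pooling across
comparisons is configurable. Per-platform DE: FDR < 0.05 and
|ΔEMM| > 0.3 (strict). Non-estimable contrasts (a group entirely missing)
propagate as missing with a reason code, never as zero — the interlayer
zero rule is applied only at the interlayer-classification step.

## Cross-platform integration

P-values are merged with the correlation-adjusted Stouffer combination on
upper-tail normal quantiles; ρ is estimated empirically as the
across-protein Pearson correlation of signed platform z-scores (clipped
to [0, 1]), or fixed by configuration; Fisher and max-p are available
behind the same interface. Single-platform records pass through. The
weighted estimate uses inverse-variance weights — the canonical choice
for a "weighted average" of estimates with known standard errors, and
exactly recoverable in tests. Combined DE: merged FDR < 0.05 and
|WE| ≥ 0.3 (non-strict at the combined level, strict per platform —
implemented literally).

The ranking score is sign(WE) × mean(percentile of |WE|, percentile of
−log10 merged FDR) among each comparison's DE proteins; ranks are per
direction, ties broken by |WE| then accession; top-k lists are exported
per comparison and their union can exceed k. Percentile selections use
the nearest-rank quantile of |WE| within comparison and direction, with
strict exceedance. These conventions are validated through their
qualitative properties (directionality, monotonicity, dominance), which
is what they are used for downstream.

## Structure and trends

PCA is protein-centered SVD on the batch-corrected complete matrix;
component signs are fixed so the mean STR score is ≥ the mean CTRL score
(signs are otherwise arbitrary; the convention makes score plots and
tests reproducible). PC1 vs PC3 is the default display pair; any pair is
selectable.

Trend scaling divides each refined-group contrast by the CTRL–STR span,
making the coordinates direction-agnostic and affine-invariant; proteins
with a zero span are excluded with a reason. The 16-box grid is numbered
row-major from the top-left; the numbering is a documented convention
(any fixed bijection serves the purpose of referencing plot regions).
Pattern classification checks, in order: early-shift (y ≥ 1 − tol),
adjacent-saturating (x ≥ 1 − tol and y < x), progressive (monotone
within tol), else non-monotone — saturation must be tested before the
progressive clause, which it otherwise satisfies. The tolerance defaults
to one grid cell (0.25). The refinement gate admits only proteins with a
combined-level STRvCTRL call. Sequential-DE counts tally DE flags along
DistvCTRL, AdjvDist, STRvAdj plus the composite AdjvCTRL.

Interlayer classification marks a protein DE in a layer when either
stricture comparison is combined-DE; the layer's change is proxied by the
average WE of the two comparisons, set to zero for a layer where the
protein is not quantified.

## Problem sizes and determinism

The test suite and the acceptance script run the simulations at sizes
chosen to give stable Monte Carlo answers on a single CPU in minutes:
2,000 proteins for null calibration (99 % binomial band on the p < 0.05
fraction), ≥ 500 planted DE proteins pooled over effects 0.5/1.0/2.0 for
the ±0.05 WE bias bound, 200 planted proteins per trend class for the
≥ 80 % recovery bound, and 300–1,000 replicates for the paired-t oracle.
All generators are bit-reproducible under a fixed seed; the pipeline
derives per-stage substreams from a single root seed, and two runs with
the same configuration produce byte-identical TSV outputs.

## Known limitations

- The label-free MNAR attenuation described above.
- Satterthwaite (not Kenward–Roger) degrees of freedom; negligible here,
  but not identical in strongly unbalanced designs.
- The ranking-score and refinement conventions are reasonable
  reconstructions validated by their qualitative properties, not by
  comparison with an external reference implementation.
- Booster-channel physics (ratio compression) is not modeled; the
  channel exists in the design and simulation but carries no statistics.
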