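# layerprot

Tissue-layer-resolved differential proteomics for intestinal strictures:
a tested, reusable implementation of a dual-platform (isobaric TMT +
label-free) analysis pipeline for laser-microdissected submucosa (SM) and
muscularis propria (MP), exercisable end to end on synthetic data with
planted ground truth.

## The problem

Crohn's-disease strictures remodel the deeper intestinal wall layers —
fibrosis in the submucosa, muscular hypertrophy in the muscularis propria —
but bulk or mucosal-biopsy proteomics cannot resolve these compartments.
The workflow modeled here isolates each layer by laser microdissection
from paired strictured (STR) / non-strictured (NSTR) ileum of affected
patients plus independent control (CTRL) ileum, standardizes every sample
to an equal **net tissue area** (44 mm², correcting for dense vs. loose
tissue), quantifies proteins on two parallel MS platforms from aliquots of
the same samples, and tests for layer-wise differential expression (DE)
along with proximity gradients (NSTR refined into adjacent **Adj** /
distal **Dist** tissue).

## The statistics

Per protein and layer, log2 abundance is modeled with a linear mixed
model,

    abundance ~ Group + TMT_set + (1 | individual)

fitted by REML (the set term is dropped for proteins quantified in a
single multiplex set). Group contrasts are differences of estimated
marginal means, ΔEMM, with Satterthwaite degrees of freedom and
Benjamini–Hochberg FDR; a protein is DE on one platform when
FDR < 0.05 and |ΔEMM| > 0.3.

Because both platforms measure the same aliquots, their p-values are
merged with a correlation-adjusted Stouffer combination,

    z = (z_a + z_b) / sqrt(2 + 2·rho),

with rho estimated from the across-protein correlation of platform
z-scores, and effect sizes are combined into the **weighted estimate**
(WE), the inverse-variance weighted average of the platform ΔEMMs.
Combined-level DE requires merged FDR < 0.05 and |WE| ≥ 0.3. DE proteins
are scored directionally (sign(WE) × mean percentile of |WE| and of
−log10 merged FDR) for ranked "top" lists, cross-tabulated between layers
(concordant / discordant / layer-predominant), and profiled along the
CTRL→Dist→Adj→STR axis: scaling each group mean to the CTRL = 0, STR = 1
range places every protein in a 16-box reference grid and classifies its
trend as progressive, adjacent-saturating, or early-shift.

The synthetic-data module generates the full study design (12 cases + 8
controls → 32 samples per layer in 2 × 16-channel multiplex sets with
pooled reference and booster channels), planted protein effects, both
platforms' intensities with shared biological signal and correlated
measurement error, intensity-dependent label-free dropout, and binary
tissue masks for the area-standardization module.

## Worked example

```python
import layerprot as lp

cfg = lp.PipelineConfig(n_proteins=500, fractions={"up": 0.06, "down": 0.06}, seed=42)
out = lp.run_all(cfg)
sm = out["summary"]["layers"]["SM"]
print("SM combined DE: %d up / %d down of %d proteins tested" % (
    sm["combined_de_up"], sm["combined_de_down"], sm["recovery"]["n_tested"]))
print("sensitivity %.2f, empirical FDR %.3f, WE mean bias %+.3f" % (
    sm["recovery"]["sensitivity"], sm["recovery"]["empirical_fdr"],
    sm["recovery"]["we_mean_bias"]))
```

prints

```
SM combined DE: 30 up / 30 down of 500 proteins tested
sensitivity 1.00, empirical FDR 0.017, WE mean bias +0.021
```

With 30 "up" and 29 "down" proteins planted, the combined-level caller
recovers every planted effect, admits a single false positive (empirical
FDR 0.017, below the nominal 0.05), and estimates effect sizes with a
+0.02 log2 bias. The run also writes per-layer DE tables, ranked top
lists, PCA scores, interlayer categories, and trend profiles
(`out["trends_SM"]` holds each DE protein's scaled coordinates, box index
and pattern).

The same stages are exposed on the command line:

```
layerprot simulate --seed 2 --out sim/
layerprot standardize --mask mask.png --um-per-px 2.0 --rows 100:1100 --target 44
layerprot run --config cfg.yaml --out results/
```

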