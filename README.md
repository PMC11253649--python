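# mrmediate

Two-sample Mendelian randomization (MR) screening and two-step mediation
analysis for microbiome–metabolite–disease causal networks, with a
synthetic GWAS summary-statistics generator so that the entire pipeline is
testable end to end without downloading any external GWAS.

## Who this is for

Genetic epidemiologists who want a reproducible, scriptable implementation
of the common MR screening workflow: take a catalogue of exposure traits
(e.g. gut-microbial abundances across taxonomic ranks), a catalogue of
candidate mediators (e.g. blood metabolites), and a disease outcome, all as
GWAS summary statistics; screen every exposure for a causal effect on the
outcome; screen the mediators the same way; connect the two layers by a
third screen; and decompose each exposure's total effect into a
metabolite-mediated and a direct component.

## The statistics

For each exposure, instruments are SNPs passing a p-value threshold
(5×10⁻⁸, or the conventional 1×10⁻⁵ relaxation for microbial traits),
LD-independence by greedy clumping (r² ≤ 0.001 within 10,000 kb), an
instrument-strength requirement F ≥ 10 with

&nbsp;&nbsp;&nbsp;&nbsp;R² = 2β² / (2β² + 2N·se²),&nbsp;&nbsp;&nbsp;
F = (N − 2)·R² / (1 − R²),

and absence of known confounder associations (screened against a local
annotation table). After allele harmonization, per-SNP Wald ratios
β_out/β_exp are combined by three estimators:

- **IVW** — the 1/se² weighted mean of ratios (= zero-intercept weighted
  least squares of β_out on β_exp);
- **MR-Egger** — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy;
- **weighted median** — the cumulative-weight interpolated median of
  ratios, consistent while < 50% of weight is invalid.

Diagnostics are Cochran's Q (heterogeneity), the Egger intercept test
(pleiotropy), MR-PRESSO (resampling-based outlier detection and removal)
and leave-one-out. The primary estimator follows the preference ladder —
pleiotropy → Egger, else heterogeneity → weighted median, else IVW — and
analyses with both pleiotropy and heterogeneity significant are excluded.
Significant pairs are re-tested in the reverse direction to flag
bidirectional relationships.

Mediation uses the product of coefficients: with β0 the exposure→outcome
total effect, β1 the exposure→mediator effect and β2 the mediator→outcome
effect, the mediated effect is b = β1·β2, the direct effect β0 − b, and a
mediator is *positive* when b shares β0's sign, *negative* otherwise.

## Worked example

Generate a synthetic three-source study with planted causal structure (two
microbial taxa act on the disease through metabolite `met_0000` with
θ_EM = 0.5, θ_MO = 0.3 and direct effect 0.05), screen it, and decompose:

```bash
mr simulate --out-dir world --seed 3
mr screen --exposures world/microbiota_catalogue.tsv \
          --outcome world/disease_GBM_syn.tsv --ld world/ld.tsv --out micro_results.tsv
mr screen --exposures world/metabolite_catalogue.tsv \
          --outcome world/disease_GBM_syn.tsv --ld world/ld.tsv --out metab_results.tsv
mr screen --exposures world/microbiota_catalogue.tsv \
          --outcome world/met_0000.tsv --ld world/ld.tsv --out link_results.tsv
mr mediate --micro-outcome micro_results.tsv --metab-outcome metab_results.tsv \
           --micro-metab link_results.tsv --out mediation.tsv --sankey-out sankey.tsv
```

`mediation.tsv` then contains (seed 3):

```
exposure        mediator  outcome          beta0    beta1    beta2    b        direct   proportion
phylum.Laccofi  met_0000  disease_GBM_syn  0.19691  0.48868  0.29998  0.14659  0.05032  0.74447
class.Gafilac   met_0000  disease_GBM_syn  0.19005  0.51264  0.29998  0.15378  0.03627  0.80915
```

Read: each taxon's total log-odds effect on the disease (β0 ≈ 0.2, truth
0.05 + 0.5·0.3 = 0.2) splits into a mediated part b = β1·β2 ≈ 0.15 (truth
0.15) running through the metabolite and a direct remainder ≈ 0.05 (truth
0.05); both taxa are positive mediators with ~75–80% of the effect
mediated. `sankey.tsv` is the matching edge list for any Sankey renderer.

The same workflow is available as a library (`run_screen`,
`build_mediation_network`, ...), and the estimators are scikit-learn
compatible (`IVWEstimator().fit(beta_exp, beta_out, se_out)` with fitted
attributes `beta_`, `se_`, `pval_`, `or_`, ...).

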