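# Methods

## Scope and assumptions

The package implements the laboratory side of clinical PRS reporting: given
a published scoring file, a genotyped (optionally imputed) sample, and a
pre-built reference panel, it produces a standardized population-structure-
adjusted score and a dichotomous risk category per disease, plus a separate
candidate list of monogenic secondary findings. It assumes:

- a single genome build shared by all inputs (no liftover; builds are the
  caller's responsibility);
- biallelic, upstream-normalized variant records;
- imputation, phasing, variant calling and variant annotation happen
  upstream;
- the published per-SD odds ratio transfers to the population being tested
  (the classification is only as good as this assumption, which is why the
  report carries a fixed limitations block).

## Raw scoring and harmonization

The raw PRS is `sum_j w_j * g_ij` over available loci; missing genotypes
contribute nothing. We deliberately do not mean-impute missing dosages:
mean imputation requires cohort allele frequencies, which a single-sample
clinical batch does not have, and skipping keeps single-sample results
deterministic and consistent with the projection step (which also skips).

Harmonization matches each weight-table locus to the observed REF/ALT pair
at the same (chrom, pos): effect allele = ALT is used as-is; effect allele
= REF uses the complement dosage `2 - d`. Strand-ambiguous palindromic
pairs (A/T, C/G) are dropped by default because strand cannot be verified
without frequency information — frequency-based strand inference is
intentionally out of scope; the policy is configurable (`keep`). Loci that
are absent or allele-mismatched are dropped with a logged reason; drops
degrade the score, never abort it. Scoring supports both hard calls (GT)
and imputed dosages (DS); DS is preferred when present because it carries
imputation uncertainty.

QC: a sample must have an overall call rate *strictly greater than* 98.5%
(configurable); equality fails.

## Population-structure adjustment

Reference construction: dosages are variance-standardized under
Hardy–Weinberg, `(g - 2p)/sqrt(2p(1-p))` with `p` the reference ALT
frequency; zero-variance variants are excluded; the standardized matrix is
decomposed by SVD. Sign is fixed deterministically (largest-magnitude
loading positive per PC) so bundles reproduce bit-for-bit across runs.
Reference coordinates are `U*S`; eigenvalues are the squared singular
values.

Projection: a new sample's standardized dosages (using *reference*
frequencies) are multiplied by stored per-allele loadings, and the raw
projection is rescaled by `sqrt(eigenvalue) * 2` per PC. The bundle stores
loadings pre-scaled as `V / (2*sqrt(eigenvalue))`, so this literal recipe
returns exactly `x . V` — a held-in reference sample reprojects onto its
stored coordinates to machine precision, and a left-out sample lands within
`0.1*sqrt(eigenvalue)` per PC on structured panels (both are pinned by
tests). The scaling mode is recorded in the bundle manifest so alternative
conventions remain expressible. Missing variants are skipped, never
mean-imputed; projection requires ≥50% of reference variants (error below,
warning below 90% because coordinates attenuate toward the origin as
coverage falls).

Adjustment: per disease, `PRS_raw ~ PC1 + PC2 + PC3 + PC4` is fitted by OLS
in reference *controls* (≥6 required; rank-deficient designs are rejected,
except that identically-zero PC columns are pinned to coefficient 0). The
adjusted score is the residual; standardization uses the mean and SD
(ddof=1) of the adjusted score over *all* reference samples (controls-only
available as an option). Exact OLS identities give the invariants the tests
check: control residuals have mean 0 and correlation < 1e-10 with each PC;
the standardized adjusted score has reference mean 0 and SD 1 to 1e-12.

Four PCs is a fixed contract of the reference bundle (readers reject
anything else): it matches the adjustment model the assay was designed
around, and the simulator's scenarios place all systematic structure in the
leading components.

## Risk threshold

`tau = ln(target OR)/ln(OR_sd)`, target OR defaulting to 2 and configurable
per disease. OR_sd must be supplied per disease (> 1); there are no
defaults because the value is disease- and publication-specific.
Classification is strict: a score exactly at tau is average risk. The
report describes every non-high result as average risk, reports monogenic
findings in a separate section, and never comments on PRS-monogenic
interactions. Sex-specific diseases are scored only when the sample's
reported sex matches the configuration; unspecified sex conservatively
skips them rather than reporting a score whose reference distribution may
not apply.

## Secondary findings

The four screening rules are applied independently and all triggered rules
are recorded; the flagged set is exactly the union of the per-rule sets
(property-tested against a brute-force oracle). MAF gates are strict `<`
(0.1% for ClinVar P/LP and LoF, 0.03% for HGMD DM). Unknown MAF passes the
gates by default: in a screening context, absence from population frequency
databases is evidence of rarity; this is configurable. The 59-gene panel
and per-gene LoF-mechanism flags ship as an editable TSV because panel
recommendations accrue over time; the LoF flags are the package's own
curation defaults and should be reviewed before clinical use. Output is a
candidate list — classification and orthogonal confirmation are human steps.

## Validation statistics

- Odds ratios use the cross-product with the Woolf log-scale CI
  (z = 1.959964 at 95%, configurable alpha). The method was chosen because
  recomputing the shipped published 2×2 counts reproduces every printed OR
  and CI at printed precision — an automated check, not an assumption. Any
  zero cell yields a degenerate result (OR 0 or infinity, CI undefined).
- Quantile curves use rank-based equal-count bins (sizes differ by ≤1, ties
  broken by stable input order for determinism); bins with zero cases or
  zero controls are flagged, excluded from the Pearson correlation, and
  warned about.
- Concordance reports the agreement fraction and MCC; a zero marginal makes
  MCC undefined and flagged rather than zero.
- Site concordance treats calls and truth as sets of normalized
  (chrom, pos, ref, alt) keys, optionally restricted to half-open BED
  intervals; empty denominators give NaN rather than a silent 0.
- Display rounding is half-up, matching the printed tables it is compared
  against.

## Synthetic cohorts

`simulate.CohortSpec` defines the study conditions. Genotypes follow the
Balding–Nichols model (ancestral frequency Uniform(0.05, 0.95); per-
subpopulation frequency Beta-distributed with divergence F; genotypes
Binomial(2, p)); the divergence parameter is recovered by an independent
Hudson-style estimator within ±0.02 in tests. Weights are N(0, 0.1²) with
the effect allele assigned randomly to REF or ALT to exercise
harmonization; simulated allele pairs are non-palindromic so every locus is
scoreable. Disease labels follow a logistic model whose log-odds is linear
in the standardized adjusted score with slope ln(OR_sd), the intercept
solved numerically to hit the target prevalence. One seed drives named
substreams (variants, frequencies, genotypes, weights, disease), so
changing one stage's consumption does not perturb another's.

What the simulator does *not* emulate: linkage disequilibrium, admixture
gradients, imputation error, genotyping batch effects, and real ACMG-region
variant content. Passing tests therefore demonstrate the correctness of the
pipeline's mathematics and its behaviour under frequency-driven structure —
not the analytical performance of any physical assay.

### Calibration scenario

The threshold-calibration check needs a designed truth. Under the
logistic-normal model the dichotomized odds ratio (above vs below tau)
always exceeds the target of 2 and approaches it only as OR_sd → 1; the
helper `simulate.expected_dichotomous_or` computes it by numerical
integration. The calibration scenario was therefore fixed at OR_sd = 1.3
and prevalence 0.15, where the design value is 2.13 — within a quarter of a
Woolf SE of 2 at n = 20,000 — before any test was run. Fifty full
end-to-end replicates (simulate → score → PCA → control-fit → standardize →
classify at tau) must produce a CI covering 2 at least 45 times. Observed
empirical ORs run slightly above the integral's 2.13 (median ≈ 2.3 across
replicates), consistent with the small-count upward bias of the
cross-product estimator at ~20 high-risk cases per replicate; the coverage
criterion absorbs this.

The confounded scenario (`risk_freq_shift`) shifts each non-first
subpopulation's risk-allele frequency by a fixed amount in the risk
direction, separating the raw score distributions deterministically
(SMD ≈ 2.7 at shift 0.05 with 300 loci) while leaving per-allele effects
identical; adjustment must recover ≥80% of the separation (observed ≈ 99%).

### Problem sizes

Test and acceptance runs use scaled study sizes chosen to make the
statistics decisive at interactive cost: reference cohorts of 500–1,000
samples and 150–300 variants for exact-identity properties; 600-sample
5-subpopulation panels for leave-one-out projection; n = 20,000 with 200
variants for each calibration replicate (50 in tests, 20 in the acceptance
script); n = 50,000 score-level cohorts for quantile curves.

## Known limitations

- No trans-ancestry or local-ancestry scoring; one adjustment model is
  applied to everyone, which corrects score *location* across groups but
  not differences in predictive accuracy.
- No absolute-risk modelling and no clinical recommendations beyond the
  fixed limitations text.
- The projection coverage floor guards against gross attenuation but
  low-coverage projections are still biased toward the origin.
- Multi-allelic records must be split upstream; the readers reject them.
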