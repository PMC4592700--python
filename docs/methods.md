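# Methods

## Calling model

Each sample × marker × tissue is reduced from the genotyping software's
sized-peak table to at most two allele peaks. Peaks outside the marker's
expected product-size window are discarded; the tallest surviving peak is
the major allele, and the tallest peak at least `min_allele_spacing_bp`
(default 2.0 bp, the dinucleotide-repeat unit) away is accepted as a second
allele iff its height reaches `het_min_fraction` (default 0.20) of the
major height. Height ties break toward the shorter fragment, making the
reduction deterministic and order-independent. No published threshold exists
for the heterozygosity fraction in this assay class; 0.20 is this package's
documented choice and both knobs are exposed in the calling config.

Informativeness is decided by the constitutional (normal) genotype alone:
homozygous ⇒ `ni`. For heterozygous normals, tumor alleles are paired with
normal alleles by size within `size_bin_bp` (default ±1 bp, sub-bp sizing
jitter being typical of capillary/gel systems). A tumor missing one
constitutional allele entirely is LOH by complete loss (no ratio defined).
Otherwise the allele ratio R = (T₁N₂)/(T₂N₁) is computed and LOH called when
R ≤ `lower_ratio` or R ≥ `upper_ratio` (defaults 0.5 and 2.0 = 1/0.5,
boundary inclusive). The symmetric two-sided rule follows from "≥50 %
reduction in *either* allele": with `upper = 1/lower` the decision is
invariant under simultaneously relabeling alleles in both tissues (tested).
A tumor allele that pairs with neither normal allele (novel length —
possible instability or sample mix-up) is flagged and the cell set to
`missing`; microsatellite instability is deliberately not scored as LOH.

## Summaries

FAL (fractional allele loss) per sample = (#LOH loci)/(#informative loci),
undefined when no locus is informative; `missing` cells never enter the
denominator. Values are kept at full precision and rounded half-up to three
decimals only at presentation. A region's informativeness/LOH status is the
OR over its markers; exclusive-LOH fractions use *all* studied samples as
denominator (a deliberate convention: a sample uninformative in the target
region simply cannot be an exclusive-LOH case, and no informativeness
requirement is imposed on the other regions).

## Statistical engine

All tests are implemented in-package and cross-checked against independent
references in the test suite:

* **Fisher's exact test** (r × 2): full enumeration of tables with the
  observed margins in log-factorial arithmetic; the two-sided p is the sum
  of point probabilities not exceeding the observed table's (with 1e-7
  relative slack on the log scale for float safety). For three or more
  strata this is the Freeman–Halton extension, used for the three-level
  total-PSA stratification. Point probabilities sum to 1 within 1e-12.
* **Mann–Whitney U**: exact by complete enumeration of rank assignments for
  total n ≤ 12 without ties (two-sided p = probability of a U at least as
  extreme on either side); otherwise normal approximation with tie-corrected
  variance and 0.5 continuity correction. U is reported as min(U_A, U_B);
  two identical samples give p = 1 by convention.
* **Kruskal–Wallis** with tie correction, p from the χ² upper tail (k−1 df).
  For two groups H equals the squared uncorrected Mann–Whitney z (tested as
  an algebraic identity).
* **Spearman** as Pearson correlation of mid-ranks, p via the t
  approximation; **linear regression** as closed-form OLS with the n−2 df
  slope t-test.

Stratifications follow the study's cut-offs (age 72, PSA 10/20, free/total
PSA 0.16, PSA density 0.15, volume 50 ml, Gleason 7, stage T2/T3). Boundary
values go to the upper stratum for "≥"-labelled dichotomies; the three-level
PSA split is labelled with strict lower bounds, so there the boundary goes
down — the `GroupingRule` carries a per-rule flag. Missing clinical values
are excluded pairwise with a logged count. No multiple-testing correction is
applied in the primary report; Benjamini–Hochberg q-values are available
behind `fdr=True`.

## Synthetic cohorts

The generator emulates the assumed data-generating process, not raw
electropherograms: per patient, one latent deletion event per region
(all of a region's markers share it), per-marker constitutional
heterozygosity, and peak heights proportional to allele copy fractions
under multiplicative lognormal noise. Defaults define the reference study
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 50 | cohort size |
| `het_prob` | 0.415/0.368/0.452 per region | solves 1−(1−h)^k = region informativeness 0.80/0.60/0.70 |
| `loh_prob` | 0.575/0.23/0.40 per region | latent deletion probability |
| `tumor_purity` | 0.7 | tumor-cell fraction of the biopsy |
| `loss_completeness` | 0.0 | fraction of the lost allele remaining in tumor cells |
| `peak_height_mean` | 2000 RFU | scale only; calls are scale-invariant |
| `peak_cv` | 0.1 | CV of lognormal peak noise |
| `stutter_fraction` | 0 (off) | optional −2 bp shoulder peak |
| `psad_odds_ratio` | 1.0 (null) | link of P(PSAD ≥ 0.15) to latent 15q/13q LOH |
| `psad_high_prob` | 0.84 | baseline P(PSAD ≥ 0.15) |

The closed-form ratio a caller should see for a true event is
`expected_ratio(purity, completeness) = (1−purity) + purity·completeness`;
purity 0.5 with complete loss sits exactly on the inclusive 0.5 boundary,
and at the default purity 0.7 the expected ratio 0.3 is comfortably
detectable, so calls are near-perfect at CV 0.1 (the log of R carries noise
s.d. ≈ 2·CV). Allele sizes are drawn on a 2 bp grid inside each marker's
window. Clinical covariates are drawn from ranges typical of a
prostate-biopsy cohort (age ~N(71, 8.6) clipped to 55–86, lognormal PSA and
volume, the empirical Gleason/stage frequencies); only PSA density is linked
to LOH — through the latent 15q/13q deletion indicator via a two-point
logistic model — so every other variable is an exact null for type-I-error
studies. Fixed seed ⇒ byte-identical outputs.

What the generator does **not** emulate: stutter ladders beyond a single
shoulder, dye pull-up, size-standard miscalibration, preferential
amplification of short alleles, somatic mosaicism of purity across markers,
and realistic PSA biology. Passing tests therefore validate the analysis
logic under the stated model, not robustness to every artifact of real
fragment data.

## Test problem sizes and numerical choices

The acceptance battery uses the packaged 50 × 7 reference matrix for all
cohort-level checks (each sub-second); engine exactness uses 1000 random
2×2 tables and complete rank enumeration up to n = 10; calibration uses
noiseless cohorts of 100–500 patients; parameter recovery runs 20 seeds at
n = 500 (~7 s); null flag-rate estimation runs 500 cohorts of 50 (~30 s).
Clopper–Pearson intervals are used for binomial coverage checks
(conservative by construction).

## Known limitations

* Exact conditional tests are discrete and therefore conservative: at this
  cohort size the realized type-I error of the Fisher battery is below the
  nominal 0.05 for several cells (measured 0.01–0.07 across region ×
  variable cells under the null generator), most strongly where margins are
  small or skewed (the 30-informative region; the 8/42 PSA-density split).
  This is a property of exact tests, not an implementation artifact — the
  p values agree with independent enumeration to ~1e-12.
* The packaged reference matrix is a transcription; its per-sample FAL
  values and all summaries are recomputed from the calls rather than trusted
  from any printed column, and the package reports computed exact p values
  next to, never asserting equality with, user-supplied published ones.
* Single-marker, single-tumor calling only: no joint multi-sample model, no
  copy-number inference beyond the binary call, no MSI classification.
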