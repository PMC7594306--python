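# Methods

## Statistical model

For trait records of n genotyped animals the full model (Model ADR) is

    y = Xb + Qc + u + v + w + e

with

- `b`: fixed effects — intercept, herd, year and season factors
  (dummy-coded against the first observed level), age at calving as a
  linear covariate, and genome-wide SNP homozygosity as a linear
  covariate. Homozygosity is the per-animal proportion of homozygous
  markers and enters in percent, so its coefficient `b` reads as the
  effect of a 1% increase — the genome-wide inbreeding-depression
  estimate. Fitting this regression also keeps the dominance component
  mean-zero: without it, directional dominance inflates σ²_D and shifts
  the mean of the back-solved dominance effects.
- `c ~ N(0, I σ²_HYS)`: random herd-year-season contemporary groups
  (the observed herd × year × season interaction).
- `u ~ N(0, G σ²_A)`, `v ~ N(0, D σ²_D)`, `w ~ N(0, R σ²_ROH)`,
  `e ~ N(0, I σ²_E)`.

Models A, AD and AR drop the obvious terms. The phenotypic variance is
defined as σ²_P = σ²_A + σ²_D + σ²_ROH + σ²_E (the HYS component is
excluded); σ²_G is the sum of the genetic components.

### Relationship matrices

With `p_i` the observed sample frequency of allele A at marker i (mean
genotype code / 2 over all genotyped animals) and `p*_i` the observed
frequency of marker i lying inside a ROH:

- `Z` has entries −2p, 1−2p, 2−2p for genotypes BB, AB, AA;
  `G = ZZ'/Σ2pq` (VanRaden method 1).
- `H` has entries −2p², 2pq, −2q²; `D = HH'/Σ(2pq)²` (the statistical,
  allele-substitution parametrization, which makes G and D orthogonal
  in expectation under Hardy–Weinberg).
- `M` has entries 1−p* (in ROH) and −p* (not in ROH);
  `R = MM'/Σp*q*`. The denominator deliberately carries no factor 2 —
  ROH status is a single indicator per animal, not an allele dosage.

Monomorphic markers (and markers always/never in ROH) produce zero
covariate columns and drop out of the denominators automatically; no
marker filtering is performed, so marker indexing is stable.
Because the ROH status of a marker depends partly on its genotype, R is
structurally collinear with G and D. `orthogonalize_M` offers the
regression pre-correction: each M column is replaced by its
least-squares residual on (intercept, Z column, H column), making the
corrected R orthogonal to both. This is provided as an option, not the
default, matching the primary analysis.

### ROH detection

The detector reproduces the two-stage scanning procedure of the PLINK
`--homozyg` family. Stage one slides a 15-SNP window along each
chromosome; a window is homozygous when it has ≤ 1 heterozygous call,
and a marker is eligible when at least 5% of the windows covering it
are homozygous (the tool default for the hit threshold, exposed as a
parameter since the criterion set leaves it implicit). Stage two takes
maximal runs of eligible markers, breaks them at inter-marker gaps
> 500 kb, and within each run selects segments satisfying all five
criteria: length ≥ 1 Mb (inclusive bp span), ≥ 15 SNPs, ≤ 100 kb per
SNP, ≤ 1 heterozygote, no internal gap > 500 kb. Among all passing
intervals the reported segments are the *maximal* ones (not contained in
any other passing interval), chosen greedily by SNP count (ties to the
leftmost) under a non-overlap constraint. This rule is pinned by an
exhaustive-enumeration oracle (`rohdom.validation`) that recomputes
everything marker-by-marker; detector and oracle agree exactly on
hundreds of random small chromosomes. Missing-call criteria are not
implemented: the pipeline requires complete (imputed) genotypes and the
PLINK missing-data window parameters would be dead code.

## Estimation

### AI-REML

Variance components are estimated by restricted maximum likelihood with
average-information updates. Per iteration the pipeline forms
V = Σ σ²_k K_k, its Cholesky factorization, P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹,
the score −½(tr(PK_k) − y'PK_kPy) and the AI matrix ½ (K_kPy)'P(K_lPy).
Proposed steps are safeguarded in order: (1) the AI step with
negative-bound components parked at a small positive floor; (2) an
active-set refinement that holds boundary-pushed components at the
floor and re-solves the AI system for the rest; (3) an EM-flavoured
gradient step (2σ⁴/n · score). Each candidate passes a backtracking
line search on the restricted likelihood. A component pushed against
zero in two consecutive iterations is fixed to exactly 0, flagged, and
removed from the update; this mirrors how production REML software
reports slightly negative components.

Convergence requires |Δ log L| < 1e−8 and max |Δσ²|/σ²_P < 1e−8
(both configurable); the iteration cap is 200 and non-convergence
raises an error carrying the full trajectory. A 1e−6-scaled ridge is
added to V only if a Cholesky factorization fails, and that event is
logged.

Standard errors come from the pseudo-inverse of the AI matrix evaluated
over *all* model components at the converged point, so components fixed
at the zero boundary still carry a curvature-based SE (as ASReml-style
software reports). The same matrix provides delta-method SEs for the
variance ratios σ²_•/σ²_P and σ²_•/σ²_G and the correlations between
component estimates.

BLUPs are recovered as σ²_k K_k Py (group-level σ²_HYS Q'Py for the HYS
term); at convergence y = Xb̂ + Qĉ + û + v̂ + ŵ + ê holds to numerical
precision, which the tests assert.

### Model comparison

Nested models are compared with T = 2(logL_full − logL_reduced) and the
boundary mixture P = 0.5·Pr(χ²₁ > T), T clamped at zero (P = 0.5).
Both fits must share data and fixed effects; restricted likelihoods are
then comparable because only the random structure differs.

### Back-solving

`α̂ = Z'G⁻¹û/Σ2pq` and its dominance/ROH analogues. The centred Gram
matrices are singular (the all-ones vector is in their null space), so
the inverse is an eigenvalue pseudo-inverse with a relative cutoff of
1e−10; since BLUPs lie in the column span of their matrix, the
reconstruction identities Zα̂ = û, Hd̂ = v̂, Mr̂ = ŵ hold to ~1e−14 and
are enforced at 1e−6 in the tests. The mean dominance effect is
d̄ = −(100·b)/N_SNP (b is reported per 1% homozygosity; the factor 100
moves it to the per-unit scale), and
σ²_D,full = σ²_D + N·mean((2pq)²)·d̄² completes the dominance variance
for the directional part absorbed by the fixed regression.

### Single-SNP GWAS

Per marker, allele count j (0/1/2), heterozygosity k (0/1/0) and in-ROH
status l (0/1) are fitted jointly as fixed effects by generalized least
squares with V from a converged Model-A fit held fixed across markers
(EMMAX/P3D approximation; dominance and ROH relationship matrices are
not carried in the background, matching the reference analysis).  After
whitening by the Cholesky factor of V each marker is an OLS problem
with a re-estimated residual scale — with V = I the scan is *exactly*
joint OLS, which the tests verify against statsmodels.  P-values use
the standard-normal reference by default (Student-t with residual
degrees of freedom is available for small fixtures).  Effects whose
whitened covariate is (near-)collinear are flagged inestimable, never
zero-filled; collinearity ties are resolved by dropping the last
(ROH-most) column.  Benjamini–Hochberg q-values are computed per effect
type per scan (via statsmodels, pinned to a hand-rolled step-up oracle
in the tests) with a 10% FDR call; the genomic inflation factor is the
median observed χ² over 0.4549, and no genomic-control correction is
applied even when λ exceeds 1.

## Synthetic data

The generator produces ROH by genuine identity by descent, not by
pasting homozygous blocks. Founders draw haplotypes from a uniform
allele-frequency law on [0.05, 0.95]; descendants are formed by meiosis
with Haldane (no-interference) crossovers at 1 cM/Mb. The mating design
has a random-mating core population plus a configurable fraction of
close matings — half sibs by default, full sibs optionally — applied
either only to the parents of the study cohort or in every generation.
The default conditions (100 founders, 6 generations, core size 150,
80% half-sib matings for the final generation of 2,000 animals, 5,000
markers on 5 × 100 Mb chromosomes) give genome-wide homozygosity around
0.67 with a standard deviation of ~0.03 and a mean per-SNP in-ROH
frequency of ~0.13 — the same regime as a 75k-chip dairy-cattle cohort
(homozygosity ≈ 64%, ROH frequency ≈ 11%), though with more
animal-to-animal spread because a 5-chromosome desk genome has far
fewer independent segments than a 30-chromosome cattle genome.

Phenotypes follow the ADR generative process with raw (uncentred)
incidences: y = Xb + Qc + Σ z·a + Σ het·d + Σ x·r + e with
d_j = d̄ + δ_j. Raw coding matters: it makes a nonzero d̄ act as genuine
inbreeding depression, with an implied homozygosity slope of exactly
−d̄·N_SNP per unit (−d̄·N_SNP/100 per 1%). Raw additive coefficients
are set to a = α − (q−p)d so the statistical allele-substitution
effects equal the drawn α; the additive, dominance-deviation, ROH, HYS
and residual draws are each rescaled so their realized variance equals
the configured target exactly, making the stored truth the target
itself. Default trait block: σ²_P = 100 with additive/dominance/ROH
shares 30/5/3%, σ²_HYS = 10, d̄ = 0.02 (a depression signal of the same
relative size as yield traits in large dairy datasets: about 0.1
phenotypic SD per percent homozygosity).

What passing tests do and do not show: the generator has no
linkage-disequilibrium structure beyond what drift, the founder pool
and inbreeding create, no minor-allele-frequency ascertainment, no
selection, no QTL distinct from markers (marker effects are causal),
and fixed-effect factors are assigned independently of the genotypes.
Recovery results therefore validate the estimation machinery, not the
robustness of the method to LD between markers and causal loci or to
confounding between management groups and genetics.

## Validation studies and problem sizes

- ROH oracle equivalence: 200 random chromosomes of 20–60 markers,
  mixed spacings and heterozygosity rates; exact agreement required.
- Variance-component recovery: 25 replicates of the default conditions
  (n = 2,000, m = 5,000); a component counts as recovered when the
  estimate is within 2 reported SEs of the generating value; ≥ 90%
  required per component.
- Null GWAS calibration: 40 replicates with all random components zero,
  n = 1,200, m = 5,000 on ten 50-Mb chromosomes, with purely
  drift-driven inbreeding (50 founders, 15 generations of random
  mating). The old, short ROH maximize the effective number of
  independent ROH tests per replicate; statistics are pooled across
  replicates before computing the type-I error at P < 0.05 (required
  0.05 ± 0.01) and λ (required within [0.95, 1.05]). Pooling is
  essential: per-replicate λ for the ROH effect scatters with
  sd ≈ 0.13 from ROH-status LD alone (roughly 200 effective tests per
  genome), so only the pooled median is a meaningful calibration
  measurement.
- The n = 12 REML toy is checked against a Nelder–Mead maximization of
  the explicitly coded restricted-likelihood formula (agreement 1e−4).

These sizes keep the full suite and the acceptance script in the
tens-of-minutes range on a single CPU while leaving each check
statistically meaningful.

## Known limitations

- Single-trait REML only; no multi-trait or genomic-prediction support.
- The GWAS background carries only the additive component (P3D); exact
  per-marker REML is not implemented.
- Boundary SEs (for components fixed at zero) are curvature-based and
  approximate; the usual asymptotics do not strictly apply on the
  boundary.
- The ROH detector assumes complete genotypes and breaks segments at
  chromosome boundaries with no special edge handling.
- `R` measures sharing of ROH *positions*, not haplotype identity; it
  is not the segment-based relationship matrix used for mate selection.
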