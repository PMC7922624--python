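# Methods

This note documents the models, the synthetic data they are exercised on,
and the numerical and design choices a maintainer would want to know.

## Synthetic populations (`simdata`)

The generator's job is to reproduce the *statistical structure* the
downstream analyses assume, not cattle biology per se.

**Haplotypes.** Each breed (Jersey = 0, Holstein = 1) has a pool of
`n_founders` (default 10) founder haplotypes whose alleles are Bernoulli
draws from per-marker frequencies shaped by `maf_shape` (Beta(a, a) scaled
into [0.05, 0.95], with a small between-breed jitter of SD 0.05). Sampled
haplotypes are founder mosaics: walking along each chromosome, the copy
switches to a random founder with probability `1 − exp(−ld_rho·d)` per
inter-marker gap of `d` bp, and always at chromosome starts. LD therefore
decays with distance at a rate set by `ld_rho`; `ld_rho = 0` gives pure
founder copies (maximal LD within lineages), `ld_rho = 1` effectively
independent markers. A founder-mosaic process was chosen over coalescent
simulation because it is simple, exactly seedable, and gives directly
tunable LD — the price is that its LD is "random founder noise" rather
than genealogically realistic (no allele-frequency/LD coupling, no
recombination hotspots). Conclusions about imputation accuracy at a given
LD level transfer; conclusions about absolute accuracy for real cattle do
not.

**Markers.** SNPs get uniform random positions per chromosome (defaults:
5 chromosomes × 10 Mb, a scaled-down genome keeping realistic ~10 kb HD
marker spacing). Each SV anchors in a random inter-SNP gap with log-uniform
length 100 bp–10 kb, so some SV intervals span SNPs (needed for the
SNP-in-SV exclusion toggle); SV alleles ride on the haplotypes exactly like
SNP alleles. Default type mix is 90% DEL / 5% INV / 5% DUP, matching the
deletion-dominated composition of imputable SV panels; insertions are
supported in the alphabet but off by default.

**Individuals.** Breed fractions come from {0, 0.25, 0.5, 0.75, 1} with
weights favouring purebreds; each of an individual's two haplotypes is
drawn from the Holstein pool with probability equal to its Holstein
fraction. Sire–son pairs: the son's paternal haplotype is a recombinant
gamete of the sire's two haplotypes (per-bp crossover rate 1e-8, ~1 cM/Mb),
so allele transmission is exactly checkable. Twice-sequenced duplicates are
extra rows sharing the original's genotypes but drawing sequencing depth
independently.

**Depth and missingness.** Read depth is Poisson(`depth_mean`, default 8)
per SV call; calls below the threshold (default 5) are recoded to the
missing code, which is literally the integer 5 in the genotype alphabet
{0, 1, 2, 5}. Only the threshold is prescribed by the analysis convention;
Poisson is this package's choice of depth law.

**Phenotypes.** Per trait, Gaussian effects are drawn for a random 10% of
SNPs and of SVs. The SNP component, SV component and Gaussian residual are
*orthogonalised in sample and scaled so their sample variances are exactly*
`prop_var_snp`, `prop_var_sv` and the remainder of a unit phenotypic
variance (defaults 0.50 / 0.05 / 0.45, a large SNP component next to a
small SV component as estimated for production traits). Exact scaling makes
variance bookkeeping checkable to 1e-9 and gives REML tests a sharp truth;
the cost is a slight distortion of the sampling distribution of realised
heritability, irrelevant to everything tested here. An optional additive
breed effect (default 0.5 SD per unit Holstein fraction) exercises the
fixed covariate.

## SV catalog (`sv_catalog`)

Coordinates are 0-based half-open internally; BED-like files are native and
VCF (1-based, INFO/END inclusive) is converted on read. "Overlap ≥ 1 bp"
means intersection length ≥ 1 under half-open arithmetic, so intervals that
merely touch do not merge. Merging is type-aware (DEL with DEL, etc.),
collapses multi-way overlaps transitively (union–find over the pairwise
overlap graph), and represents a merged cluster by the union span — the
conservative choice for the downstream SNP-in-SV exclusion. Validation
sets: TWICE_SEQ keeps SVs called in both sequencing replicates of at least
one duplicated individual, FAM those called in both members of at least one
sire–son pair. `min_overlap_bp` is exposed because the 1-bp rule is a
convention, not a law.

## Relationship matrices (`relmat`)

`G = WW′/m` with `w_ij = (x_ij − 2p_i)/√(2p_i(1−p_i))`; frequencies are
computed on the analysis cohort itself; missing codes are mean-imputed to
`2p_i` before standardisation (which provably leaves `p_i` unchanged).
Markers enter when polymorphic and above `maf_min` (default 0 — the 0.05
MAF filter belongs to the sequence reference panel, not the GRM). The
dedicated self-relationship estimator (`1 + (x² − (1+2p)x + 2p²)/(2pq)`) is
available behind `yang_diagonal`; the default diagonal uses the same cross
formula with j = k. A ridge of 1e-6·mean(diag) is added (and logged) only
when a covariance factorisation fails downstream.

## REML and BLUP (`mixedmodel`)

Average-information REML on (σ²₁[, σ²₂], σ²ₑ): the first update is an EM
step for stability; afterwards AI updates are used, with two guards —
if an AI update pushes components below the floor `1e-8·var(y)`, the
offending components are clamped at the floor and the AI system re-solved
for the free ones (an active-set step, which is what makes null components
converge in a handful of iterations instead of crawling by EM); if that
also fails, a full EM step (positivity-preserving, monotone in the
restricted likelihood) is substituted. Convergence: relative restricted
log-likelihood change < 1e-8, cap 200 iterations; non-convergence returns
the fit flagged with its iteration trace. Standard errors come from the
inverse AI matrix; ratio SEs are not propagated. In ratio tables,
components below `1e-6·σ²ₚ` are displayed as 0 while stored estimates stay
unrounded — note the SV share of genetic variance is computed from
*unrounded* components, so it can differ in the third digit from a value
recomputed from rounded table entries.

BLUP solves GLS at fixed components: `b = (X′V⁻¹X)⁻¹X′V⁻¹y`,
`u_k = σ²_k G_k Z′V⁻¹(y − Xb)`; these satisfy Henderson's mixed-model
equations exactly and predict unphenotyped individuals through the G
off-diagonals. The fixed design always carries an intercept; aliased
columns (e.g. breed fraction in a single-breed cohort) are dropped with a
warning at spec construction.

## GWAS and meta-analysis (`assoc`)

Markers are tested one at a time by GLS with V fixed at the null-model
components — the EMMAX/GCTA-MLMA scheme — rather than refitting variance
components per marker; p-values are two-sided standard normal on
`t = b/SE` (equivalently a 1-df Wald χ²). Monomorphic markers and markers
aliased with the fixed design return NA rows with a reason. The conditional
scan simply appends the conditioning marker's dosage to the fixed design,
so a tested marker in perfect LD with it comes back NA — the expected
signature when a significant variant merely tags a known gene. The
t-correlation matrix `V` is estimated pairwise-complete over the full
marker universe; an ill-conditioned `V` (condition number > 1e10) falls
back to the Moore–Penrose pseudo-inverse with a warning. The single-trait
bull/cow meta-analysis is the k = 2 special case of `χ² = t′V⁻¹t`; the
pooled-inverse-variance-effect alternative is a possible extension, not
implemented. LD around an SV is composite (dosage-correlation) r², since
phased data is not assumed, in a window anchored at the SV interval
midpoint; `r² > 0.5` is flagged as high LD. FDR is reported for the SV
class with `T` = number of SVs.

## Imputation-accuracy harness (`imputeval`)

The harness — fold construction, masking, leakage-free reference
assembly, pooled-R² scoring, threshold/MAF summaries and accuracy-based
selection — is the deliverable; production phasing/imputation engines are
external tools it can wrap. The built-in stand-in imputer regresses each
SV's dosage on its `w = 20` nearest flanking SNPs (ties to the lower
position) in the reference, predicting masked individuals with clipping to
[0, 2]; it needs ≥ 2 usable flanking SNPs and `w + 2` non-missing reference
calls, else NA. Accuracy is the squared Pearson correlation between imputed
dosage and true code, *pooled* over all masked individuals across folds
(per-fold averaging is available but pooling is the default and what the
summaries use); note r² is sign-blind. Anchor default is `start`, with
`middle`/`end` supported; the SNP-in-SV exclusion removes exactly the SNPs
whose positions fall in the SV's half-open interval. Selection keeps SVs
with accuracy strictly above 0.5 and merges selections across SV sets by
≥ 1 bp overlap.

## Prediction cross-validation (`cvpredict`)

Repeated k-fold (default 10×10) with a fresh seeded partition per repeat;
all models are evaluated on identical partitions, so model differences are
exactly paired. Per fold, variance components are re-estimated on the
training records by default (statistically clean); `refit_vc=False` reuses
a single full-data fit per model — faster and flagged in the log, at the
cost of a small information leak through the variance components only.
Validation individuals' phenotypes never enter the training right-hand
side; their GEBV come through G off-diagonals. Accuracy is the Pearson
correlation of GEBV with the held-out phenotype, aggregated as mean over
folds within a repeat, then mean ± SE over repeats (SE = SD of repeat
means / √repeats).

## Pipeline and formats (`io`, `pipeline`)

Dosage matrices, maps, phenotypes, GRMs and reports are TSV for
inspectability (GRMs also have a lower-triangle binary cache); SV genotypes
cross the boundary as VCF with GT/DP and INFO END/SVTYPE. All writers
round-trip bit-exactly with their readers. Every pipeline stage reads only
disk artifacts of earlier stages and writes a JSON metadata sidecar (stage,
parameters, version); all randomness flows through config seeds, so reruns
are byte-identical and a deleted intermediate can be regenerated by
rerunning its stage alone. The demo configuration (500 individuals, 5,000
SNPs, 200 SVs, reduced CV repeats) was sized to make the full chain a
sub-minute, single-CPU exercise while keeping every stage statistically
non-trivial; the same applies to the simulation sizes used in the test
suite (hundreds to 1,500 individuals).

## Known limitations

- The mosaic LD model has no genealogy: no drift, selection, or
  MAF-dependent LD; the generator's MAF spectrum is a free parameter
  (`maf_shape`) rather than an estimate of the real SV spectrum.
- The stand-in imputer is linear and unphased; absolute accuracies are not
  comparable to phasing-HMM pipelines, only contrasts (anchors, exclusion,
  LD level, MAF) are.
- Single-trait REML only; no pedigree A-matrix, no Bayesian mixture models.
- GRMs are unweighted; no LD-weighted or MAF-stratified variants.
- Ratio standard errors are not propagated from component SEs.
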