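# Methods

This note documents the models, estimators and numerical choices behind
`halfsibmap`, and what the simulation-based tests do and do not show.

## Simulation model (`popsim`)

A half-sib population consists of N paternal families of exactly n progeny.
Founders (default 1,000) are in linkage equilibrium: per-marker allele
frequencies are drawn once from a MAF law (default Uniform(0.05, 0.5); any
frequency in (0, 0.5] is accepted) and founder haplotype alleles are i.i.d.
Bernoulli(f). N sires are drawn without replacement; dams are drawn with
replacement from a pool of min(⌈20·N·n/30⌉, founders − N) founders,
reproducing the few-progeny-per-dam structure of AI breeding.

Meiosis is Bernoulli per interval: the gamete starts on a fair-coin homolog
per chromosome and switches independently in interval j with probability
r_j ∈ [0, 0.5]. Map length is the sum of interval rates, in Morgan; no
Haldane/Kosambi transform is used anywhere, and per-interval rates double
as switch probabilities. The synthetic design places q markers evenly on a
single chromosome with uniform rates (default 1 M total); a semi-real mode
accepts a bp position list and a cM:Mbp factor (e.g. the 1:1 transform).
An optional chi-square (m = 2) interference mode thins a doubled-intensity
Poisson process on the genetic scale (every second event kept, random
phase), preserving the expected crossover count; it is off by default since
the estimators are validated under the no-interference model.

Missingness is applied to the genotype matrix only: random per-entry
masking at a given fraction and/or block patterns (marker range × sample
fraction) that emulate chip-design missingness. Truth — parent haplotypes,
per-meiosis gametes, per-chromosome start homologs and crossover
intervals — is stored separately and is never read by the estimators.

What the generator does **not** emulate: founder linkage disequilibrium,
multi-generation pedigrees, selection, genotyping error (beyond
missingness), sex chromosomes, and systematic array-specific missingness
beyond the block model. Passing tests therefore demonstrate estimator
correctness under linkage-equilibrium founders and error-free genotypes;
on real array data, genotyping error and LD-induced phasing shortcuts can
shift the estimators' error rates.

## Quality control (`qc_io`)

Markers are ordered by the supplied physical map (1-based bp, closed
intervals). Filters, in order: blacklist (misplacement candidates), minor
allele frequency (> 0.01 kept, computed on non-missing calls over all
genotyped animals), Mendelian checks on opposing homozygotes
(families with > 5% inconsistent comparable calls removed, then SNPs
inconsistent in > 10% of informative families, then residual conflicting
progeny calls set missing — the progeny side, the parent kept). The
denominators (comparable calls per family; informative families per SNP)
follow common PLINK semantics. On simulated data the whole QC is a no-op,
which is asserted as a regression test.

## Estimators (`inference`)

All three estimators are method-family implementations sharing one
information model: a marker is informative for a family when the shared
parent is heterozygous there, which progeny alone reveal through opposing
homozygotes.

**Deterministic multipoint.** Progeny genotypes only; families need ≥ 30
progeny. Sire haplotypes are chained marker by marker: each heterozygous
marker is phased against the last 30 phased heterozygous loci by majority
agreement of progeny strand assignments (ties or no evidence leave it
unphased and excluded). Each progeny then receives origin calls at
discriminating markers; a switch between consecutive informative markers is
attributed fractionally to the spanned intervals, proportional to physical
length, with every spanned interval counting the meiosis as informative.
Interval rate = attributed switches / informative meioses.

**Pairwise likelihood.** Strictly two-locus, no multipoint chaining. For an
adjacent marker pair with the sire heterozygous at both, progeny
transmitting identifiable paternal alleles at both loci (doubly homozygous
progeny) form diagonal / off-diagonal two-locus counts; the family's phase
is the majority pairing and the minority counts recombinants. Classifiable
progeny are an ascertained subset: the maternal alleles must match the
transmitted paternal alleles at both loci, which is more or less likely
for recombinant than for parental configurations once allele frequencies
are skewed, so the raw recombinant fraction k/n is biased (upward by ~8%
at N=50 × n=1,000 under Uniform(0.05, 0.5) MAF in our measurements). The
estimator therefore solves the pooled maximum-likelihood estimating
equation Σ_f O_f = Σ_f N_f·θb_f/(θb_f + (1−θ)a_f), where (a_f, b_f) are
the classifiable probabilities of the family's parental and recombinant
configurations from population allele frequencies; at f = 0.5 this reduces
to k/n. The method family's known behaviour remains: at N = 10 families
many adjacent pairs have no doubly-heterozygous sire (undefined → imputed
0) and the minority rule is biased downward at small counts — the
estimator underestimates unless families are many and large. The full
mixture MLE over θ ∈ [0, 0.5] (including double-heterozygous progeny via
maternal allele frequencies under linkage equilibrium) is exposed for
arbitrary pairs (`two_locus_mle`), the tool of choice when screening for
misplaced markers.

**Transmission HMM.** Two hidden states (transmitted homolog), transition
probability r_j per interval (0.5 across chromosome joins, i.e. an
independent restart), emission = P(progeny genotype | transmitted parental
allele, co-parent). The parent side uses its own genotype where observed
(phased against progeny evidence with the same 30-locus window; unphased
heterozygous markers emit 0.5), falling back to population allele
frequencies; the co-parent side uses its genotype where observed, else
allele frequencies; missing progeny genotypes emit 1. Rates are
re-estimated by EM: r_j ← mean posterior switch probability over all
meioses of one sex, clamped to [1e−6, 0.5] (the floor keeps the chain
ergodic), initialised at 1e−3, iterated to max-change < 1e−4 or 20
iterations. Posterior decoding defines paths; posterior ties at 0.5 inherit
the previous state to avoid spurious switches. Zero-likelihood meioses are
flagged and excluded from the likelihood, not fatal. The forward–backward
inner loops are JIT-compiled with numba when available; a vectorised NumPy
fallback produces identical results.

**Map-confidence score and two-run scheme.** The per-marker confidence
score is the posterior-weighted fraction of meioses whose origin call
agrees with the locally smoothed path, where smoothing is the median of
the three nearest informative calls — a call counts against the marker
only when it is an isolated flip (differs from both informative
neighbours). Genuine crossovers are never isolated, so locally consistent
data score 1 exactly, while a misplaced marker flips in many meioses and
scores low. A 5-marker majority window was considered and rejected: it
penalises genuine crossovers adjacent to chromosome ends at small meiosis
counts. After a first HMM run, markers scoring below 0.986 (threshold
configurable; never-informative markers count as failing) and individuals
with more than 58 genome-wide crossovers are removed and the inference is
re-run once for the final estimates.

**Crossover records.** One record per origin switch, flanked by the
nearest informative markers, with the event placed at ⌊(left+right)/2⌋ bp.
Near-double crossovers (same meiosis, same chromosome, midpoints < 2 Mbp
apart by default) are reported as a per-chromosome proportion.

## Maps (`maps`)

Coordinates accumulate interval rates per chromosome (d_1 = 0). Undefined
(never-informative) intervals are imputed as 0 with a per-map count, so
accuracy is biased down rather than undefined. Quality against a known
truth: acc = d̂_q / d_q (total length ratio, summed over chromosomes) and
mse = (1/q) Σ (d̂_i − d_i)². Map comparison restricts to shared markers;
PCA runs on the rows of adjacent-interval rates, centred but not scaled
(all entries share Morgan units); hierarchical clustering uses the L2 norm
of coordinate differences with average linkage (configurable) and a
deterministic leaf order.

## Recombination traits (`traits`)

nco is the mean genome-wide crossover count over a parent's decoded
progeny. For shuffling, the transmitted proportion p of a chromosome is
measured in physical length between the first and last marker, with
segment breaks at crossover midpoints — consistent with midpoint event
placement. L_k is the marker-span fraction of the total autosomal span
(assembly chromosome lengths are not used; the statistic is a
within-panel quantity). Progeny lacking a decoded path on any chromosome
are skipped with n_i adjusted. Shuffling is invariant to the arbitrary
homolog labelling because 2p(1−p) is symmetric, and bounded by
0.5·Σ_k L_k². A z-scored column is provided since the trait is centred
and scaled before mixed-model analysis.

## Quantitative genetics (`quantgen`)

The GRM is VanRaden method 1 with observed allele frequencies; missing
calls are mean-imputed for G only; monomorphic markers are excluded. A
ridge of 1e−8 guards positive semidefiniteness.

Univariate weighted GBLUP is fitted by exact REML on a one-dimensional
profile: after transforming by D^{−1/2} and rotating by the
eigendecomposition of the transformed G, the restricted likelihood is a
scalar function of λ = σ_g²/σ_e², maximised by bounded search on
log10 λ ∈ [−8, 6] (a solution at the lower bound is reported as
σ_g² = 0). Constant weights only rescale σ_e²; the fit (μ, BLUPs, σ_g²) is
unchanged, and the BLUPs equal a direct Henderson MME solve (asserted to
1e−8 on small instances). The restricted LRT for σ_g² > 0 uses the
boundary null, P = 0.5·Pr(χ²₁ > LRT) with P = 0.5 at LRT = 0; empirical
size is conservative, as the boundary mixture predicts.

The bivariate cross-sex model (sex as fixed effect,
u = (u_s, u_d)′ ~ N(0, Σ ⊗ G), weighted residuals) is fitted by EM-REML
with a 100-iteration cap; non-convergence is flagged, not raised, because
boundary cases at small sample sizes routinely exhaust the cap while the
correlation estimate is already informative.

GWAS fixes the variance components at the null GBLUP fit (P3D) and
estimates each SNP effect by GLS under V = σ_g²G + σ_e²D, giving
T = m̂/SE and P = 2[1 − Φ(|T|)]; exact per-SNP REML is available behind
`per_snp_reml` but is not the default on runtime grounds. Individuals
missing a SNP's genotype are excluded for that SNP (no imputation);
monomorphic SNPs are skipped. Thresholds 1e−5 / 1e−4 flag strong /
suggestive signals; regions are chains of suggestive-or-stronger SNPs with
gaps ≤ 5 Mbp supported by ≥ 3 signals, summarised by
σ_x² = Σ 2f_i(1−f_i)m_i²; gene annotation lists genes within ±500 kb,
nearest first. Benjamini–Hochberg adjustment is the standard step-up.
The sex × breed contrasts use weighted least squares (weights = progeny
counts), type-II F tests, least-squares means over an equal-weight factor
grid and Tukey (studentized-range) adjusted pairwise tests.

## Problem sizes used in the test and acceptance runs

The accuracy claims are evaluated on the synthetic design (1 M chromosome,
1,500 SNPs, complete genotypes): deterministic at N=10 × n=50 over 10
repetitions, likelihood at N=50 × n=1,000 over 3 repetitions, HMM over the
N ∈ {10,50} × n ∈ {50,100} grid with 3 repetitions each; the missingness
comparison masks 50% of genotypes on five paired N=10 × n=50 populations.
Calibration checks use 500 linkage-equilibrium parents with 1,000 markers
(GWAS type-I error and heritability recovery at h² ∈ {0.1, 0.3, 0.5}, 20
replicates) and 200 null replicates of 100 parents for the restricted-LRT
size. These sizes make a full run take a few minutes on one CPU while
keeping Monte-Carlo standard errors well inside the asserted margins.

## Known limitations

* Dams in a paternal half-sib design carry too few progeny to phase from
  progeny alone, so female maps require either genotyped grand-parents
  (not modelled) or many-progeny dams; the machinery is symmetric but the
  validated path is the male map.
* The pairwise estimator's variance explodes under heavy missingness
  (few classifiable gametes per pair); this is a property of the method
  family, reproduced deliberately rather than patched.
* The MCS threshold (0.986) and crossover cap (58) are treated as given
  constants of the workflow; their optimality is not derivable from the
  validation design.
* EM-REML for the bivariate model converges slowly near boundaries; the
  100-iteration cap mirrors practical behaviour and is reported, but a
  non-converged Σ estimate should be interpreted with care.
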