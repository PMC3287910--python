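# Methods

This note records the statistical model implemented by `wavescore`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Model and test statistic

Genotypes are minor-allele dosages g ∈ {0,1,2}. The weighted genotype is
x = g/√(n·q(1−q)) with q the estimated MAF — the inverse-variance weighting
that makes a rare allele's contribution comparable to a common one's.
Population structure is removed by projecting genotypes, traits and
covariates off the top k principal components of the column-standardized
dosage matrix (M ← M − CC′M). Traits are then residualized by OLS on their
covariates (for the binary trait, OLS on the quantitative traits plus
covariates; a logistic option exists but the linear residual is the
default, matching the linear working models the pipeline fits).

For a window of m SNP columns X (centered per SNP) and residual trait Y,
the per-SNP score is U(j) = X(j)′Y with null variance
V(j) = (Y′Y/(n−1))·‖X(j)‖², and the window statistic is
T = ΣU(j)/√(ΣV(j)). This is the score statistic of a generalized linear
model with identity link evaluated at the null, summed over the window's
markers and standardized by the root summed variance. Because inference is
by permutation of Y (which leaves Y′Y invariant), the exact form of the
variance estimate affects only the statistic's scale, not the validity of
its p-values. Permutation statistics for all windows reduce to a single
matrix product per permutation batch, since Y enters T only through one
inner product with each window's per-individual sums.

Two-sided testing on |T| is the default. Empirical p-values use the
add-one convention p = (1+c)/(M+1), which guarantees p > 0 and validity;
the plain proportion c/M is available by configuration.

## Empirical-Bayes wavelet shrinkage

Each individual's weighted, adjusted genotype vector along a chromosome is
zero-padded to the next power of two and decomposed by a periodized Haar
DWT to full depth. The Haar family is the default because genotype signals
are piecewise constant; other PyWavelets families are accepted.

Detail coefficients z are modeled as z = u + N(0, σ²) with the
spike-and-slab prior u ~ (1−w)·δ₀ + w·Laplace(a). On the standardized
scale the slab-convolution marginal has the closed form

    g(z) = (a/2)·e^{a²/2} [ e^{−az}Φ(z−a) + e^{az}Φ(−z−a) ],   z ≥ 0,

and the nonzero part of the posterior of u given z is a two-sided
truncated-normal mixture, so the posterior median solves a single
Gaussian-tail equation; the implementation evaluates it in log space
(`scipy.special.log_ndtr`/`ndtri`) and is verified against a quadrature +
CDF-inversion oracle to 1e−6. The shrinkage rule is the posterior median:
it maps |z| ≤ t(w) to exactly zero, never increases a coefficient's
magnitude, and leaves very large coefficients nearly untouched — which is
what lets isolated rare-variant spikes survive denoising.

The mixing weight w is estimated per resolution level (level-dependent
thresholding) by maximizing the marginal log-likelihood
Σ log[(1−w)φ(z) + w·g(z)] over w ∈ [0,1]. The log-likelihood is strictly
concave in w, so a golden-section search is exact to ~1e−9; the search is
vectorized across individuals, which is what makes replicate-level
simulation studies affordable. The noise scale σ is the median absolute
finest-level detail divided by 0.6745 (the standard MAD convention),
shared across levels. Genotype signals can be so sparse that the MAD is
exactly zero; in that case σ falls back to the standard deviation of all
detail coefficients (logged), and if that is also zero the signal has no
details to shrink. Approximation coefficients are never thresholded. The
prior scale default a = 0.5 follows the established empirical-Bayes
thresholding literature.

Denoising scope is per chromosome by default (the whole multilocus vector
of an individual is one signal, windows are cut afterwards); per-window
denoising is available (`wavelet.scope = "window"`). The chromosome scope
can smear a spike's energy across a window boundary, which costs some
power relative to window scope but reflects treating the chromosome-wide
genotype as the signal of interest.

## Windows, filtering, ordering

Only nonsynonymous SNPs are tested by default. Fixed windows take eight
consecutive eligible SNPs within a chromosome (non-overlapping; a trailing
partial window is kept if it has ≥ 2 SNPs, since a 1-SNP "window" is a
single-marker test); gene windows take all of a gene's eligible SNPs and
genes with fewer than two are skipped. The stage order is: orient/impute →
nonsynonymous filter → MAF weighting → PC adjustment → denoising →
windowing → testing. Weighting precedes PC adjustment because the weights
are defined on raw allele counts; windows ignore gene boundaries in fixed
mode.

Component count k: chosen automatically at the last index where an
eigenvalue exceeds its successor (or the median of the remaining spectrum)
by a factor of 2; an explicit integer always overrides the heuristic.

## Multiple-testing corrections and the comparison study

Per-window empirical p-values are Bonferroni-multiplied by the number of
windows. The alternative — comparing each window's statistic to the
permutation distribution of the genome-wide maximum — is valid only when
all windows share one null distribution. `simulate_permcmp` quantifies
this: 100 independent variables, null draws of size 100,000 per variable
standing in for permutations, 1,000 alternative replicates in which
variable 1 equals 3 + e (e standard normal). In the homogeneous scenario
every null variable is e; in the heterogeneous scenario variable i is
a(i) + b(i)·e with a(i) ~ N(0,1) and b(i) ~ U[0.5,1.5] drawn once per run.
The functional variable keeps a(1)=0, b(1)=1 so that its null matches the
noise of its alternative; this is what makes the Bonferroni method's power
scenario-invariant (each variable is compared to its own null), which is
the study's central claim. Rejection is two-sided on |X| at α = 0.05;
family-wise error is the fraction of replicates with at least one false
rejection among the 99 null variables. "Type I error" here is family-wise
(per-replicate): with a per-test reading the Bonferroni numbers would be
~5×10⁻⁴, two orders of magnitude below what the study design reports.

The acceptance script averages the eight proportions over 20 independent
repetitions of this design. A single repetition's power estimate has a
Monte-Carlo standard deviation of ~0.02 (1,000 replicates plus
threshold-estimation noise from the finite null sample); averaging
repetitions reduces estimator noise without changing any design parameter.

## Synthetic cohort generator

`simulate_cohort` emulates the *structure* of a GAW17-style sample of
unrelated individuals: n = 697 by default, two subpopulations with
Balding–Nichols allele-frequency differentiation at level Fst, genes of
clustered rare variants (default MAF range 0.001–0.01, i.e. below 1%),
Age/Sex/Smoking covariates, three quantitative traits with distinct
covariate dependencies (Q1: Age + Smoking; Q2: none; Q4: Age + Sex +
Smoking), and a binary trait drawn from a logistic model of the
quantitative traits and covariates calibrated to ~30% prevalence. Causal
genes add a per-allele effect (default 0.7 residual-sd units, in the range
of the strongest simulated rare-variant effects in that benchmark) to one
quantitative trait; an optional `pop_effect` shifts trait means between
subpopulations to create genuine confounding for stratification
experiments. A truth table lists the causal variants.

What the generator does **not** emulate: linkage disequilibrium between
variants (rare variants are drawn independently), the benchmark's actual
phenotype model or gene list, sequencing artifacts, and relatedness.
Passing tests therefore demonstrate the pipeline's operating
characteristics — family-wise error control on null cohorts, detection of
a clustered-rare-variant gene above a single-SNP baseline, benefit of PC
adjustment under confounding — not performance on any particular real
dataset.

Monomorphic draws (possible at the rare end of the MAF range) are redrawn,
and as a last resort a single heterozygote is forced so every SNP is
testable; columns whose post-drift frequency exceeds 0.5 are flipped to
minor-allele orientation.

## Problem sizes used by the test suite

The correction-comparison checks run the study's full design (20
repetitions averaged). Pipeline-level calibration uses scaled-down
cohorts chosen to keep replicate counts high: family-wise error uses 200
replicates of a 150-individual, 100-window genome with 4,999 permutations
(the smallest count at which a Bonferroni rejection at 0.05 across 100
windows is attainable on the p-value lattice); the clustered-variant power
check uses 50 replicates of the default 697-individual cohort with 20
genes and 999 permutations; p-value uniformity uses 500 null windows at
999 permutations.

## Numerical conventions and edge cases

- Missing genotypes are imputed to the rounded per-SNP mean dosage before
  minor-allele orientation; monomorphic SNPs are dropped (their weight is
  undefined).
- Degenerate traits (all residuals zero) give T = 0 and p = 1.
- Collinear predictors in residualization fall back to the least-squares
  pseudoinverse with a logged warning.
- Windows with zero variance (V = 0) score T = 0.
- All randomness flows from a single integer seed; rerunning any command
  with the same seed reproduces output files byte for byte.

## Known limitations

- The score test's variance estimate is the simple residual-variance form;
  permutation calibration makes this a presentation choice, but reported T
  values are not directly comparable across windows of different size
  after denoising.
- OLS residualization of a binary trait is a linear-probability
  approximation; the logistic option changes the residual's meaning
  (response minus fitted probability).
- The max-statistic correction shares one permutation stream with the
  per-window p-values; this is deliberate (the comparison is the point)
  but means its p-values are not independent of the empirical ones.
- Chromosome-scope denoising can move signal energy across window
  boundaries (see above); use window scope when windows are scientifically
  meaningful units such as genes.
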