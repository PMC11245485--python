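# Methods

This note documents the models, estimators and design choices behind the
three-step hub-regulator screen and the synthetic data it is validated on.

## Differential expression (stand-in test)

The screen consumes only a DEG *set*, so the DE stage is deliberately
simple: per contrast (stress condition vs control), log2FC is the
difference of group means of log2(TPM + 1) (pseudocount configurable), the
p-value a two-sided Welch t-test per gene, adjusted by Benjamini–Hochberg
over all tested genes, with the decision rule |log2FC| > 1 and padj < 0.05.
This is a documented stand-in for a negative-binomial Wald test: it applies
the same decision rule and, on the generator's overdispersed
negative-binomial counts, recovers planted twofold-plus effects at ≥95%
sensitivity with ≤5% FDR (measured by the acceptance suite). Genes with zero
variance on both sides keep p = 1 rather than being dropped, so the BH
family size m is stable. TPM is the exact length-normalised per-million
formula; an all-zero library raises rather than silently producing NaN.

Known limitation: TPM is compositional, so very large planted effects shift
the apparent expression of unrelated genes. The generator keeps planted
genes at modest baseline abundance so this shift stays well below the
twofold decision threshold; with real data a median-of-ratios style
normalisation would be preferable and can be applied upstream.

## ICA clustering

The DEG × sample matrix (gene-wise Z of log2(TPM+1)) is centred and
whitened by eigendecomposition of its sample–sample covariance, then
unmixed with FastICA (logcosh contrast, symmetric fixed-point updates with
a deflation fallback and seeded restarts; non-convergence raises with the
attempt log). Genes act as observations, so the independent components are
gene-space loading patterns (unit-norm columns) and the matching sample
activities are recovered by least squares. Components are ordered by
captured energy and sign-fixed (largest-|loading| entry positive) so the
decomposition is reproducible across runs. K defaults to 9 — the cluster
count used for the real stress-DEG grouping — and is a config knob; there
is no automatic model selection.

Cluster assignment is argmax over |loading| with a within-column z-score
gate (default z_cut = 2.0, ties to the lowest component). The rule is our
declared choice: the threshold trades coverage for confidence. Module
components are recoverable when the planted modules are a *small fraction*
of the DEG set and carry shared sample-level activity beyond the condition
means — with equal-sized modules partitioning the whole matrix, the
gene-space sources lose excess kurtosis (at support 1/3 it is exactly
zero, and for two equal disjoint modules the 45°-rotated basis is *more*
non-Gaussian) and no kurtosis-seeking method can orient the basis. The
generator therefore surrounds the modules with a large background of
singleton stress-responsive genes, which is also what real stress DEG sets
look like (module targets are a minority of all DEGs).

## GENIE3-style network inference and hub ranking

One random-forest regression per target gene on the candidate regulators
(self excluded), 1000 trees by default with mtry = ceil(sqrt(R)) —
the original tree-ensemble network-inference defaults. Edge importance is
impurity reduction normalised per target to sum to one. Regulators are
sorted lexically before fitting and each target's forest is seeded from
(run seed, target id), so results are invariant to regulator order and
reproducible. Degree needs a retention rule (it is meaningless on the
complete weighted graph): each target keeps its top-E regulators (default
E = 5; an importance threshold is available), degrees are pooled across
clusters (per-cluster degrees also reported), and ties break by total
retained importance, then id. Note that E must be well below the number of
candidate regulators for degree to discriminate.

## Kinship mixed model (EMMA / EMMAX)

Kinship is VanRaden's genomic relationship matrix: dosages mean-imputed
per variant, centred by 2p, cross-product scaled by 2·Σp(1−p);
monomorphic variants dropped. The null model
y = Xb + u + e, u ~ N(0, sg²K), e ~ N(0, se²I) is fitted by REML on the
eigenbasis of S K S (S the projector off the fixed effects): with
eigenvalues xi and rotated contrasts eta, the restricted likelihood is a
1-D function of delta = se²/sg², maximised by a 101-point grid over
log-delta ∈ [−10, 10] refined by bounded Brent. Non-PSD K gets a 1e−8
jitter once, then errors. The scan reuses the null delta for every variant
(EMMAX / P3D): rotate y, X, g by the eigenbasis of K, weight by
(lambda_i + delta)^(−1/2), residualise against the fixed effects via QR and
F-test the genotype slope with (1, n−p−1) df. With K = I this reduces
exactly (to 1e−8) to the ordinary ANOVA F-test, and the tests verify the
eigen path against a naive V⁻¹ GLS oracle. An `exact=True` mode refits
delta per variant for oracle comparisons; it is an order of magnitude
slower and differs negligibly in ranking. Monomorphic variants are
reported with p = 1; variants with 0 < MAF < 0.05 (configurable) are
excluded. The promoter is 3000 bp upstream of the gene body, matching the
promoter definition used for regulatory-region analyses in rice.

LD is composite R² on unphased dosages (squared Pearson correlation),
missing genotypes dropped pairwise, monomorphic variants NaN.

## Diversity, sweep and geography

Per-site diversity is the unbiased estimator (n/(n−1))·2p(1−p) with n the
number of non-missing alleles; it equals the mean pairwise difference among
sampled alleles, and the tests check exact agreement with explicit
allele-pair enumeration. Window pi divides the per-site sum by the window
length in bp (200 bp default), the windowed-pi convention of standard VCF
tooling; the per-variant-site average is reported too. The sweep call
compares matched windows: informative windows are those with wild pi > 0,
and the flag requires the cultivated/wild ratio below 0.5 in ≥50% of them
(both cutoffs configurable; the underlying criterion is qualitative, so the
defaults are declared rather than derived). The precipitation test is our
operationalisation of "precipitation-related geographic distribution":
Welch t-test of accession mean precipitation between carriers and
non-carriers of the focal variant plus the point-biserial correlation,
flagged at alpha = 0.01.

## Pipeline semantics

The three filters run as a strict conjunction; with `report_all` (default)
every regulator is still scored on every step for diagnostics. Hub
retention keeps the top 9 regulators by pooled degree (the real screen
carried nine hub NACs forward); synthetic runs typically lower this.
Relaxing a *downstream* threshold (association p, sweep cutoffs,
precipitation alpha, hub count) can only grow the final set; upstream
thresholds (DEG calling, K) reshape the network stage, so no such guarantee
is claimed for them. Reports are timestamp-free and key-sorted: identical
config + seed reproduces report.json byte-identically.

## Synthetic data: what it emulates and what it does not

The generator mirrors the statistical structure the screen assumes, at desk
scale, with one master seed split into named child streams (expression,
genotypes, geography, phenotypes) so each generator is independently
reproducible.

*Expression* — hubs carry distinct condition-response profiles over
{drought, heat} (shared, drought-specific, heat-specific, then
mixed/repressed), latent activity = de_log2fc · profile + N(0, 0.7²) per
sample; targets follow their hub with slopes ±U(0.7, 1.3) plus N(0, 0.3)
noise; 300 singleton stress genes with their own profiles form the DEG
background; everything else is condition-independent. Counts are
negative-binomial (dispersion 0.05) around abundances scaled to a 2e6
library; 12 samples per condition (two varieties × two stages × three
replicates, the realistic pooled design). Defaults: 2000 genes, 20
regulators, 3 hubs × 30 targets, log2 effect 3 — strong but honest
stress inductions.

*Genotypes* — three groups (wild, japonica, indica; 70 accessions each by
default) under the Balding–Nichols model (subpopulation frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), F_ST = 0.3, ancestral p ~ U(0.05, 0.95)),
1000 variants over a 20-slot gene landscape (3 kb promoter + 3 kb body +
1 kb gap per regulator). Inside the sweep window (hub 1's region by
default) the cultivated groups are pushed to a shared near-fixed frequency
(0.01/0.99), which creates the diversity collapse; the causal promoter
InDel is excluded from the push so it stays polymorphic in the cultivated
panel — the association step would otherwise have no power, and the real
focal InDel segregates among the cultivars. The causal variant doubles as
the cline variant: its per-accession allele probability is linear in
standardised precipitation with the coefficient chosen in closed form so
that corr(dosage, precipitation) ≈ 0.6.

*Phenotypes* — cultivated accessions only (the wild group is not
phenotyped): y = 0.8·dosage + u + e with u ~ N(0, 0.4·K) on the cultivated
kinship and e ~ N(0, 0.6·I), so the causal effect is in residual-sd units.

Not emulated: recombination and realistic LD decay, demography beyond the
two-level drift model, read-level sequencing noise, multi-trait phenotype
correlation structure, spatially autocorrelated climate. Passing tests
therefore show the estimators and the screen's logic are correct and
calibrated under the assumed generative structure — not that the screen is
robust to every failure mode of real germplasm data (population-specific
LD with the causal site, phenotype confounding, batch effects).

## Numerical and testing choices

Coordinates are 1-based inclusive at all interfaces (VCF convention).
Acceptance-scale problem sizes are the package's own choices: 250-tree
forests for the 20-seed hub-recovery study (the 1000-tree default is
unchanged), n = 300 × 200 replicates for heritability recovery with one
shared kinship eigendecomposition, 20-seed calibration at 1000 variants,
500-seed null studies for the precipitation flag. The causal-recovery study
pre-calibrates its effect size to ~90% power with a closed-form
noncentral-F oracle rather than reusing the generator default. Degenerate
inputs fail loudly: all-zero libraries, out-of-range p-values, non-PSD
kinship after jitter, zero-variance Z-scores, empty allele classes.
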