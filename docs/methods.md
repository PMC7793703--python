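# Methods

## Scope and data model

`sweepscan` compares a focal population against a pooled reference panel
using genotype dosages from a multi-sample VCF.  Only biallelic SNPs are
used; multi-allelic records and indels are dropped on read.  Internally all
coordinates are 0-based half-open; VCF (1-based) and GFF3 (1-based
inclusive) are converted at the I/O boundary.  Missing genotypes (including
half-calls) reduce the per-site allele count and are never imputed — all
estimators below are valid under variable per-site sample size.  Sex
chromosomes are excluded by name (default `Z`, `W`), the only information
available without a karyotype model.

## Windowed diversity and FST

Per-site diversity uses the unbiased mean pairwise difference
`2·c0·c1 / (n(n−1))` over the `n` non-missing alleles, which equals the
fraction of differing haplotype pairs.  Window diversity divides the
per-site sum by the fixed window length (40 kb, step 20 kb by default);
trailing partial windows are dropped so per-bp values are comparable across
windows.  Because window length is constant, this normalization choice
cancels in the log2 θπ ratio.

FST uses the Weir & Cockerham (1984) variance components with r = 2
populations, observed heterozygosity taken from dosage-1 counts, and
ratio-of-sums windowing (Σa / Σ(a+b+c)) — the de-facto standard for
windowed resequencing scans.  Windowed values may be slightly negative and
are *not* clamped, since clamping would distort empirical quantiles.
Monomorphic sites contribute exact zeros.  Sites where either panel lacks a
diploid, or where the mean sample size is ≤ 1 (the finite-sample corrections
are undefined), are skipped.

"Top x%" selections use the nearest-rank rule: the threshold is the k-th
largest value with k = ceil(x·W) and the selected set is every window ≥ the
threshold, so tie behaviour is explicit and reproducible.  Windows with zero
diversity in either panel have an undefined log2 ratio and are excluded from
the ranking (flagged invalid) rather than assigned ±∞ — a conservative
choice, since such windows cannot enter the joint quantile calculation
consistently.  A window additionally needs `--min-snps` usable SNPs
(default 10) to suppress single-SNP noise windows.

## XP-CLR

The neutral model treats the reference panel frequency p₁ as a proxy for
the ancestral frequency and the focal frequency y as Gaussian,
y ~ N(p₁, ω·p₁(1−p₁)); density mass outside [0, 1] is collapsed onto the
boundaries (loss/fixation).  The observed focal count k₂ of m₂ alleles is
binomial given y.  Under a hard sweep with coefficient s at genetic distance
r Morgans, a lineage escapes the sweep with probability c = 1 − q0^(r/s)
(conventions: c = 1 at s = 0, c = 0 at r = 0); conditioning on whether the
tracked allele rode the sweep gives the mixture likelihood with binomial
success probability 1−c+cy (probability y) or cy (probability 1−y), with
the same boundary treatment.  The tracked allele is the reference-panel
minor allele (ties to the alternate allele), fixed for reproducibility; the
likelihoods are symmetric under allele relabelling.

The per-window score is `2·max_s Σ_j w_j(log L_sweep − log L_neutral)`
over a grid of s (default: 0 plus 20 log-spaced values in [1e-5, 0.5]).
Because the grid contains the neutral point, where the sweep kernel reduces
to the neutral kernel exactly, scores are non-negative by construction;
ties in the argmax resolve to the smallest s.  Log-likelihoods are floored
at log(1e-300) so zero-probability outcomes under c = 0 cannot produce −∞.

**ω estimation.** A method-of-moments estimator averages
`[(p̂₁−p̂₂)² − p̂₁(1−p̂₁)/m₁ − p̂₂(1−p̂₂)/m₂] / [p̂₁(1−p̂₁)]` over SNPs whose
reference frequency lies in (0.1, 0.9), removing the binomial sampling
noise of both panels, floored at 1e-6.  Note the model is one-sided: ω
measures the total focal-versus-reference drift variance in units of
p₁(1−p₁).  When both panels have drifted from a common ancestor (as in the
synthetic generator with ω_f = ω_r), the estimator recovers approximately
ω_f + ω_r; the generator configuration with ω_reference = 0 is therefore
the one whose generative coefficient the estimator recovers directly, and
is what the parameter-recovery experiments use.  Boundary collapse of
extreme drift draws biases the estimate a few percent low for ancestral
frequencies near the SFS edges; this is well inside the ±15% recovery
tolerance at 20,000 SNPs.

**Window construction.** Windows are 10 kb and non-overlapping; the sweep
site is placed at the window midpoint (one evaluation per window — 10 kb is
narrow relative to the sweep footprint, keeping the scan
O(windows × grid × SNPs)).  Because hitchhiking information lies mostly
*outside* a 10 kb window, each window is scored from all usable SNPs within
±`--flank` bp of its midpoint (default 50 kb), with r = distance × ρ and a
constant recombination rate ρ (default 3×10⁻⁸ M/bp ≈ 3 cM/Mb, typical of
chicken macrochromosomes; no genetic-map input is supported).  SNP sets are
capped at 200 per window by deterministic every-k-th subsampling by
position.  SNPs monomorphic in the reference panel carry no information
under this model (the neutral and sweep likelihoods coincide in the
degenerate limit) and are excluded from scoring.

**LD weights.** w_j = 1/(1 + number of other SNPs in the same scan set
whose genotypic correlation², computed from reference-panel dosages with
pairwise-complete samples, is ≥ 0.95).  Perfectly duplicated SNPs thus
share one SNP's worth of weight; zero-variance SNPs are treated as
uncorrelated.

**Quadrature.** Likelihood integrals over y use a fixed grid of
`integration_points` equal cells (default 1000).  Each cell contributes its
*exact* Gaussian mass (CDF difference; survival-function differences in the
upper tail to preserve relative precision), so the likelihood kernel's
outcome distribution sums to 1 at machine precision by construction even
when the drift variance is tiny relative to the cell width.  Within each
cell the smooth binomial factor is evaluated at the two points μ_c ± σ_c of
the cell's truncated-normal moments, reproducing the in-cell expectation
exactly through second order; against an adaptive-quadrature oracle the
worst relative error over a stress grid is ~3×10⁻⁷ at 1000 cells and
~2×10⁻⁴ at 200 cells.  SNPs with escape probability c > 1 − 10⁻⁶ are
skipped when accumulating the composite difference (their two kernels agree
to < 10⁻⁶), bounding the induced score error well below 10⁻³.  The
replicate experiments in the test suite and acceptance script run the scan
at 200 cells — already converged at the CLR decision scale — so twenty
5 Mb scans fit comfortably in a desktop run; the default remains 1000.

## ΔAF

Each SNP is polarized on the focal population's major allele (the allele
with ≥ half of the focal non-missing alleles; exact ties break to the
alternate allele, deterministically).  ΔAF is the absolute difference of
that allele's frequencies between panels; the screen keeps SNPs with
ΔAF strictly > 0.7.  ΔAF is reported per SNP as a stand-alone screen and
does not feed region calling.

## Regions, genes, and gene-list combination

Selected windows merge into maximal regions; book-ended windows (end ==
start) merge too, since a step of half the window size means adjacent
outlier windows share signal.  A gene is attached iff its interval overlaps
the region by ≥ 1 bp (half-open test; no promoter/flank extension).  The
joint θπ-ratio/FST screen contributes one gene list (the conjunction is
applied at window level) and XP-CLR another; union and intersection are
taken at gene-ID level (`--venn-mode two-set`, the default).
`--venn-mode three-set` instead builds separate top-5% lists for FST and the
log2 ratio and intersects three sets — both conventions appear in the
comparative-scan literature, so the switch leaves the choice explicit.
Region-level intersection (pi/fst ∩ XP-CLR intervals) is also reported.

## Synthetic data generator

The generator simulates at the allele-frequency level, deliberately
matching the scan's own model so that parameter recovery has clean
semantics: ancestral frequencies from a uniform(0.05, 0.95) SFS (or a 1/x
spectrum), independent Gaussian drift per panel with boundary collapse
(truncation to {0,1}, mirroring the scan's boundary-mass treatment),
binomial diploid sampling (defaults: 15 + 15 diploids, 20,000 SNPs on a
5 Mb chromosome, ω = 0.05 per panel).  A hard sweep re-draws focal
genotypes from the hitchhiking transform with one Bernoulli ride/escape
draw per SNP — a frequency-level approximation of the lineage process,
adequate for power experiments.  Everything is seeded and byte-reproducible.

What the generator does *not* emulate: recombination-generated haplotype
structure (LD beyond sweep-induced frequency correlation), demography
(bottlenecks, migration, population growth), sequencing error, or allele
ascertainment.  Passing tests therefore demonstrate correctness of the
estimators and power under the model's own assumptions, not robustness to
real-data violations of them — in particular the LD weights are exercised
only lightly, and background LD in real data will make empirical null
distributions wider than simulated ones.

## Numerical and degenerate-input conventions

- Zero-length or gap-producing window configurations are rejected
  (`step > size` would silently drop SNPs).
- Windows with no usable SNPs are flagged invalid, never scored.
- Duplicate (chrom, pos) VCF records keep the first occurrence; duplicate
  gene IDs collapse to their spanning interval.
- Output floats are formatted at six significant digits, making repeated
  runs byte-identical; provenance comments record the configuration with
  paths reduced to basenames for the same reason.
- CLI exit codes: 0 success, 2 input error, 3 computation error.

## Known limitations

- The constant-recombination assumption misplaces r in recombination
  hot/cold spots; XP-CLR scores near such features should be read with
  caution.
- The empirical top-x% rules calibrate against the analysed genome itself;
  on small simulated chromosomes the induced thresholds are noisy below a
  few hundred windows.
- With very strong sweeps the focal panel can lose all diversity in a
  window, which invalidates the log2 ratio there (excluded from ranking);
  the surrounding windows still carry the signal in practice.
- ω is a single genome-wide coefficient; locus-specific drift (e.g. from
  background selection) is absorbed into the empirical outlier thresholds
  rather than modelled.
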