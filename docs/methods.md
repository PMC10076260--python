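# Methods

This note records the models implemented in `introscan`, the choices
made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Coordinates, missingness, containers

All intervals are 0-based half-open internally; VCF positions are
converted on read and back on write, and exported BED files are
written verbatim. Human-readable tables are 1-based inclusive where
noted. Missing alleles use a sentinel (−1) that downstream statistics
propagate — nothing imputes missing data except the explicitly
cross-validated imputation inside the cluster-number selection. All
windowed operations are per-chromosome and never span chromosome
ends; the final partial window is kept.

## Copying-model painting

A recipient haplotype is modelled as a mosaic of the `N` donor
haplotypes. Transitions between adjacent sites `d` bp apart switch to
a uniformly chosen donor with probability `q = 1 − exp(−Ne·ρ·d/N)`;
the current donor also receives its `1/N` share of the switch mass
(the standard copying-model convention, so self-transitions have
probability `1 − q + q/N`). Emission: the observed allele matches the
copied donor with probability `1 − Mu`; sites where either allele is
missing emit probability 1 (uninformative). Posteriors come from a
scaled forward–backward pass with per-site normalisation constants —
`O(L·N)` per haplotype and numerically equivalent to log-space
computation (verified against exhaustive path enumeration to 1e−10).

`Ne` (dimensionless switch-intensity scaling) and `Mu` (miscopy
probability) are estimated per recipient accession by EM over both
haplotypes: the E-step accumulates expected switch events (including
self-switches, which are genuinely latent) and expected miscopies;
the M-step sets `Mu` to the miscopy fraction and maximises the
Bernoulli transition likelihood in `Ne` by bounded 1-D optimisation.
Exactly 10 iterations are run by default and the observed-data
log-likelihood trace is non-decreasing. The fitted parameters are
then fixed for the final painting. No genetic map is assumed:
physical distance is multiplied by a constant ρ (default 1e−8 per
bp), exposed in the run configuration. Per-SNP donor posteriors are
summed into donor-group (race) probabilities.

## Windows, genepool calls, blocks, masks

Per-SNP group probabilities are averaged over the SNPs inside 10-kb
non-overlapping windows ("combined" probabilities are read as the
window mean — the only combination rule the windowing supports); a
window is labelled with the argmax group when that mean probability
is ≥ 0.8, otherwise "unknown". An accession's genepool call requires
agreement between (a) the majority of its assigned windows and (b)
the per-chromosome majority vote; disagreement or ties flag the
accession ambiguous, and ambiguous accessions are excluded from
block statistics (logged).

Introgression blocks on a haplotype are runs of windows labelled with
the opposite genepool; runs separated by ≤ 50 kb are joined (bridged
unknown or same-genepool windows do not count toward support, but the
block coordinates span the join, matching interval-merge semantics),
and blocks supported by a single 10-kb window are dropped.
Per-accession block-length distributions are summarised by the
median. Ancestry masks set a haplotype's alleles to missing wherever
its window label is the other genepool or unknown, producing one
masked panel per ancestry; masking is idempotent and the two masks
plus the unknown windows partition each haplotype's alleles.

## Diversity, private alleles, load

Per-site nucleotide diversity is the unbiased pairwise estimator
`π = 2p̂(1−p̂)·n/(n−1)` on the `n` non-missing alleles, identical to
the fraction of differing pairs; sites with `n < 2` are skipped and
counted. Region θπ/bp divides the per-site sum by the region span;
a 100-kb window track is also emitted. On masked panels, sites are
filtered by PIND (share of individuals with at least one non-masked
allele); raising the PIND floor can only remove sites.

Private variants segregate in one continental group and are absent
in the other, split at 5% frequency and into synonymous vs
nonsynonymous (missense + loss-of-function). Genetic load is counted
per accession as alt-allele dosage by effect class (presence mode by
flag); missing genotypes contribute 0. Ratios are NA when the
synonymous count is zero. Group comparisons use two-sided
Wilcoxon–Mann–Whitney tests, exact for groups ≤ 20 without ties,
normal approximation with tie correction otherwise.

## FST, kinship, FLK, hapFLK

Weir & Cockerham (1984) variance components `a, b, c` are computed
per SNP (diploid formulation with observed heterozygosity, relevant
even for mostly selfed lines); window FST is the ratio of sums
`Σa / Σ(a+b+c)` and negative window estimates are retained. Sites
where any population has fewer than two called genotypes are NA.

Pairwise Reynolds distances are computed as `D = −ln(1 − θ̂)` with
`θ̂` the two-population multi-locus ratio estimator on a 250-kb
thinned panel; the population tree is neighbour-joining (scikit-bio)
with midpoint rooting (no outgroup is assumed), negative branch
lengths clipped at zero. The kinship entry `F_ij` is the shared
branch length from the root to the MRCA of populations i and j, and
`F_ii` the root-to-tip length. With fewer than three populations a
star fallback is used with a warning.

FLK: `p̂₀ = (1ᵀF⁻¹p)/(1ᵀF⁻¹1)`,
`T = (p − p̂₀1)ᵀ[p̂₀(1−p̂₀)F]⁻¹(p − p̂₀1)`, chi-square with
`n_pop − 1` df under drift; monomorphic SNPs are NA. The statistic
reduces numerically to the classical Lewontin–Krakauer form when
`F = c·I` and its type-I error calibrates to nominal levels under a
matched Balding–Nichols null.

hapFLK fits a fastPHASE-style haplotype-cluster HMM to the phased
panel: per-site cluster allele frequencies, per-site cluster weights,
and per-interval jump probabilities tied across clusters, all
EM-estimated (cap 100 iterations or Δloglik < 1e−4; fits whose
likelihood diverges are excluded with a warning). At each SNP the
per-population mean posterior cluster memberships replace allele
frequencies in the FLK quadratic form summed over clusters, and the
statistic is averaged over independent EM fits with distinct seeds
(20 at the published operating point — "20 EM cycles" is read as 20
independent fits, matching the scan tool's fit-averaging switch;
both the fit count and the per-fit iteration cap are parameters).
Clusters whose estimated ancestral frequency is within 0.01 of 0 or
1 are excluded from the sum: their `1/(p̂₀(1−p̂₀))` variance weight
is unstable and a single near-fixed cluster would otherwise dominate
the genome-wide distribution.

The cluster number K is chosen by cross-validation: on a ≥100-kb
spaced SNP subset, five replicate copies mask 10% of alleles, the
model is refitted, masked alleles are imputed from the fitted
posterior, and the K minimising the mean wrongly-imputed proportion
wins.

Raw hapFLK values are scaled to a chi-square null by robust moment
matching: `(s, d)` solve `median(X) = s·χ²_d(0.5)` and
`q75(X) = s·χ²_d(0.75)` (1-D root find on the quantile ratio), and
`p = P(χ²_d > x/s)`. This uses only the bulk of the distribution, so
selected outliers do not inflate the null. "FDR < 0.05" uses
Benjamini–Hochberg. Significant SNPs (p < 1e−3 and q < 0.05) become
10-kb regions centred on the SNP, merged within 5 kb; two runs (K=5
and K=K*) yield an extended (union) and a restricted (supported by
both) set, each then filtered to regions containing at least one
top-5% (or top-1%) FST window.

## Excess introgression and PAIL

Per-SNP ancestry of a haplotype is the genepool of its containing
window's label (a raw-posterior mode is available by flag for
sensitivity); unknown labels are excluded from the numerator but all
recipient haplotypes stay in the denominator, consistent with the
threshold arithmetic. With `n_A` Andean- and `n_M`
Mesoamerican-assigned accessions,
`F_A = (2n_A + n_M)/(2(n_A + n_M))` and `F_M` symmetrically; both
comparisons use ≥, values are reported truncated (not rounded) to
three decimals, and degenerate compositions (one count zero) warn.
Flagged SNPs are expanded ±2.5 kb (clipped at chromosome ends),
merged within 10 kb, and regions need ≥ 3 supporting SNPs. PAIL
requires all three evidence tracks to overlap region-wise: excess
introgression, hapFLK selection, FST outlier. Gene lists are
assigned by interval overlap; region sharing across accessions is
counted as ≥ 1 carrier haplotype per accession.

## LD

r² is the squared Pearson correlation between phased haplotype
allele indicators (not genotype dosage — with near-complete selfing
the two nearly coincide). Decay curves bin pairs (MAF ≥ 0.1, ≤ 5 Mb)
by distance; the r² = 0.2 crossing is linearly interpolated between
adjacent bin centres. Inter-chromosomal analysis thins to the first
MAF-passing SNP per 10-kb grid cell (deterministic), scores all
cross-chromosome pairs, keeps r² ≥ 0.8, merges SNP pairs whose both
sides lie within 100 kb (union-find), and retains region pairs
≥ 500 kb wide on each side (50 kb when restricted to selection
regions). A region pair is private to a group when no other group
links the same two regions (both-sides overlap test; one-sided
overlap leaves it private).

## Traits, H², QST

Broad-sense heritability uses an ANOVA method-of-moments
decomposition with genotype and environment as random effects,
components truncated at zero; designs with a single replicate in a
single environment are NA. A REML fit would be the natural
alternative for unbalanced field data; method-of-moments is
closed-form and adequate for the balanced synthetic designs used
here. PS = DTF(long day)/DTF(short day), with a
"delayed-or-no-flowering" flag when the long-day value is missing.
Trait PC1 standardises columns, mean-imputes missing cells (count
logged), and is sign-oriented to correlate positively with the first
input trait.

QST uses accession-level genotypic values (replicate means) in a
one-way random-effects decomposition with the unbalanced-design
correction for group size; the default convention is
`σ²_B/(σ²_B + 2σ²_W)`, with the inbred-lineage variant
`σ²_B/(σ²_B + σ²_W)` by flag — for fully selfed single-seed-descent
lines the inbred variant is the better-motivated choice and is what
the parameter-recovery validation targets; neither is asserted as
the published convention. Outlier percentiles use the "fraction of
reference values ≤ focal" definition; a focal trait at or above the
97.5th percentile of the high-heritability (H² > 0.65) metabolite
QST distribution is a selection candidate, and fewer than 20
reference metabolites flag a wide-interval warning.

## The synthetic generator

`simulate_panel` draws: ancestral frequencies Uniform(0.05, 0.95);
genepool frequencies by Balding–Nichols drift at `f_divergence`
(default 0.4, matching strong inter-genepool differentiation); race
frequencies by a second, nested Balding–Nichols step at `f_subgroup`
(default 0.1) — five races (M1, M2, A1–A3) without claiming
demographic realism. Donor lines are Bernoulli draws from race
frequencies; selfing makes both haplotypes identical. Recipient
ancestry along each chromosome is a continuous switch process with
per-bp rate `g·r` (defaults g = 20 generations, r = 1e−8), each
switch drawing the minor genepool with probability `m` (default
0.1); minor-ancestry tract lengths are therefore exponential with
mean `1/(g·r·(1−m))`, truncated at chromosome ends — at the default
parameters that mean exceeds the 5-Mb chromosomes, so realised tract
lengths are strongly end-censored and the closed form is only
recovered at higher `g` where tracts are short relative to the
chromosome (this is how the generator is validated). Alleles are
copied from one random donor haplotype of the tract's race with a
1e−3 miscopy rate so painting is non-degenerate. Optional engineered
adaptive-introgression loci force a chosen genepool over a region in
a Bernoulli-chosen fraction of recipients. Effect classes are drawn
i.i.d. per site (synonymous 0.25, missense 0.20, LoF 0.02) over a
regular gene grid; traits are group mean + line deviation +
environment effect + replicate noise with configurable variances.

What the generator does **not** emulate: real recombination maps and
hotspots, linked selection, realistic site-frequency spectra from a
demographic history, correlated effect classes along genes,
genotyping error structure, or unbalanced trait designs. Passing
tests therefore demonstrate the correctness and calibration of the
analysis chain under its stated model, not performance guarantees on
any particular real panel.

## Problem sizes and numerical settings

The validation suite runs the reference panel at 2 chromosomes × 5 Mb
with 3000 SNPs, 60 donors and 40 recipients (painting accuracy,
block recovery, masking) and the end-to-end PAIL study at 2 × 3 Mb,
1200 SNPs, 40 donors and 30 recipients over 10 seeds, with 3
painting-EM iterations, 3 hapFLK fits per run and a 15-iteration EM
cap — sizes chosen so the whole chain, including its ten-seed
replication, completes in minutes while every statistic operates far
from its small-sample limits. The published operating point (10
painting-EM iterations, 20 hapFLK fits, K grid up to 50) is the
library default or a documented parameter throughout. Seeds derive
from a single master seed via `numpy` seed sequences; all outputs
are bit-reproducible given (config, seed).

## Known limitations

- The hapFLK EM uses a simplified fastPHASE parameterisation (jump
  probabilities tied across clusters; no per-population cluster
  weights); it is validated by signal injection and calibration, not
  against the original scan software's numeric output.
- The chi-square moment-matching scaler assumes the bulk of the
  statistic distribution is null; a genome mostly under selection
  would violate this.
- Genepool calls with few chromosomes tie easily (the per-chromosome
  majority criterion), so small synthetic genomes produce more
  ambiguous accessions than a real 11-chromosome panel would.
- The interchromosomal union-find merge is quadratic in the number
  of high-LD SNP pairs; genome-scale runs should raise the thinning
  interval first.
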