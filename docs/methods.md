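# Methods

`madcpop` processes microhaplotype read-count reports (MADC format) from
targeted amplicon genotyping panels — the kind produced when a fixed ~3,000-locus
panel designed for one species is applied to a set of related species — and
carries the data through to SNP genotypes, diversity summaries, population
structure, phylogeny, and taxonomic mislabel flags. This note describes the
models and procedures, the synthetic data they are tested against, and the
numerical and design choices a maintainer should know about.

## Data model

A *marker locus* is one amplicon of the panel (54–81 bp around a designed
target SNP). A *microhaplotype* is a distinct amplicon sequence observed at a
locus, defined by the combination of the target-SNP allele and any off-target
variants inside the amplicon; within these short amplicons all variants are
treated as completely linked. The MADC table holds one row per
(locus, microhaplotype) with an integer read count per sample. Panel positions
are 1-based (VCF convention); offsets within amplicons are 0-based.

Sampling design: each accession (genebank seed lot) is genotyped as three
single-plant samples (biological replicates) plus one bulk of seven pooled
plants, so a single carries 2 allele copies per locus and a bulk 14.

## Cleaning and diversity accounting

* **Depth-1 zeroing.** A read depth of exactly 1 for a microhaplotype is
  treated as sequencing error and set to 0. The operation is idempotent and
  is re-applied after pooling when the three singles are consolidated into one
  pseudo-sample, so pooled and real samples face the same error model (the
  source protocol leaves the ordering unspecified; this is the symmetric
  choice).
* **Single vs bulk.** Per eligible accession (exactly 3 singles + 1 bulk) the
  per-sample microhaplotype counts are summarised as the median over singles,
  the bulk count, and their difference; a LOWESS curve (tricube local linear,
  fraction 2/3, 3 robustness iterations — the classical defaults, as the
  procedure is named without parameters in the source description) smooths the
  single-plant counts along the bulk-count ordering.
* **Replicate correlations.** Pearson correlations of per-locus total read
  counts (totals per marker, not per microhaplotype — robust to haplotype-set
  differences between replicates) over loci where at least one replicate has
  reads. The package-level reproducibility summary is the mean squared
  correlation over all replicate pairs.

## SNP extraction

Each observed microhaplotype is globally aligned to its locus's reference
amplicon (match +1, mismatch −1, gap open −4, gap extend −1; global alignment
because amplicons are anchored by design). Substitution columns across a
locus's haplotypes become SNPs; the designed target column is always emitted
and flagged even when monomorphic. A sample's allele depth (AD) at a column is
the sum of its read counts over microhaplotypes carrying that base there; DP is
the AD row sum and RA the reference-allele depth. Indel columns are aligned
through but not emitted (SNPs only); haplotypes aligning at below 50% identity
are flagged as putative paralogs and excluded from the collapse rather than
silently dropped. Alternate alleles are ordered by pooled read depth
(ties alphabetical). Output is VCF 4.2 with FORMAT `DP:RA:AD` and a `.` entry
for zero-depth calls; the ID field (`locus:offset`) disambiguates records that
share a position.

## Filtering

* **Presence.** A locus has data for a sample when its total read count is
  strictly greater than 10. The presence curve counts loci present in more
  than t% of samples for t = 5…100; the comparison is strict except at t=100,
  where it means "present in every sample" (a strict rule would make that
  entry vacuously zero). Thresholds are applied over samples by default (an
  accession-level reading is possible by collapsing replicates upstream).
* **Hind/HE.** For a sample with allele depths c₁…c_k summing to n ≥ 2,
  H_ind = (n² − Σc²)/(n(n−1)) — the probability that two reads drawn without
  replacement carry distinct alleles. Per SNP, H_ind is averaged over
  contributing samples, HE = 1 − Σp̂² with p̂ the pooled read-fraction allele
  frequencies over the same samples, and SNPs with ratio in [0.1, 1.0] are
  retained. The statistic is depth-aware and genotype-call-free; for a diploid
  outcrosser in Hardy–Weinberg equilibrium the expected ratio is
  (ploidy−1)/ploidy = 0.5, inbreeding pushes it toward 0 and paralog collapse
  above 1. Bulk samples are excluded by default (14 allele copies inflate
  within-sample heterozygosity).

  A structural consequence worth stating: in a multi-species dataset of
  selfers, SNPs that are *fixed differences between species* have H_ind ≈ 0
  but large pooled HE, so the 0.1 lower bound removes exactly the most
  species-diagnostic markers. The filtered set is therefore used for
  genotype-quality-sensitive statistics (PCA, the reported FST tables, the
  sample tree), while taxonomy-grade distances — the missingness-vs-FST trend
  and mislabel flagging — are computed from all extracted SNPs.

## Genotypes and population structure

* **Dosage calling.** Maximum-likelihood diploid dosage under binomial read
  sampling with per-read error ε = 0.01: alt-read fractions {ε, ½, 1−ε} for
  dosages 0/1/2, ties resolved to the heterozygote, missing when DP < 10.
  Multiallelic records collapse to the most-read alternate vs rest. This is a
  deliberately simple, deterministic caller (no hierarchical population
  prior); it is sufficient for structure-level analyses.
* **PCA.** SNP-wise mean imputation of missing dosages (imputed fraction
  logged), column centering, SVD; sign fixed by making each component's
  largest-magnitude loading positive. Phenotype PCA one-hot encodes
  categorical descriptors (full encoding, not dummy-dropped), standardises all
  columns, and by default keeps complete cases only.
* **Weir–Cockerham FST.** Per-SNP variance components a (among populations),
  b (among individuals within), c (within individuals) from genotype counts,
  with the weighted mean Σa/Σ(a+b+c) pooled over SNPs; monomorphic SNPs
  contribute nothing and SNPs without two genotyped individuals per
  population are skipped. Pairwise matrices at species level and at
  source-within-species level (the latter with "–" for pairs lacking data).
* **Missingness statistics.** Per-sample missing-locus counts are compared
  across species with Levene's test (mean-centred), Welch's heteroscedastic
  ANOVA, and Games–Howell post-hoc comparisons (studentized range on
  q = t·√2 with Welch–Satterthwaite df), summarised by a compact letter
  display built by insert-and-absorb over the significance graph. The
  missingness trend orders species by FST to a reference species — chosen as
  the least-missing species, the best available proxy for the panel's design
  species — and reports the Spearman correlation.

## Phylogeny and taxonomy

SNP genotypes become per-sample base strings (dosage 0 → ref, 2 → alt,
heterozygote → read-majority base with ties to ref, missing → N); IUPAC
ambiguity codes are not used because the TN93 distance is defined on
{A,C,G,T} and the target species are predominantly homozygous. Pairwise
distances use the Tamura–Nei (1993) closed form with empirical base
frequencies averaged over each pair (pairwise N deletion); saturated pairs
(non-positive logarithm argument) raise an error, or are recorded as missing
and pruned greedily before tree building. Trees are built by Saitou–Nei
neighbor joining on the Q-criterion with ties broken on the smallest index
pair and negative branch lengths clamped to zero (counted); NJ is exact on
additive matrices. Bootstrap support resamples SNP columns with replacement
(default 100 replicates), rebuilds sequences → distances → NJ, and reports
the percentage of completed replicates containing each internal bipartition of
the point tree; supports ≥ 50 are written as internal node labels. A species
tree is built by NJ on the pairwise FST matrix and rooted on the edge to a
chosen reference species.

**Mislabel flagging** is nearest-neighbour voting: for each sample, the k = 5
nearest neighbours excluding same-accession replicates; a flag requires one
*other* species to hold ≥ 80% of the neighbours, that species to have ≥ 2
accessions, and the mean distance to the voting neighbours to be below 0.9×
the mean distance to the sample's own-species nearest samples. The margin
term suppresses assignments between weakly separated sister species, where
between-species distances are comparable to within-species distances; such
cases are logged as ambiguous rather than flagged. One single-plant
representative per accession (highest total depth) feeds the tree and the
flags.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not any
particular dataset:

* **Panel.** Loci are apportioned to 8 chromosomes by largest remainder
  against a fixed reference distribution (414, 364, 419, 426, 390, 210, 367,
  410 per 3,000), with random 81-bp amplicon sequences, a random target
  offset, and 0–3 off-target SNPs per amplicon (truncated Poisson(1)).
* **Dropout.** Each locus amplifies in a species with probability
  sigmoid(a − b·d), d the species' divergence from the panel's design species;
  defaults a = 0.8, b = 1.2 give roughly 40–70% missing loci across the
  default divergence grid (0.25–1.20), matching the observed scale of
  cross-species transfer loss.
* **Allele frequencies.** Balding–Nichols: ancestral frequency
  p₀ ~ U(0.05, 0.95) per SNP; species frequency Beta-distributed around p₀
  with per-species differentiation θ_s = θ_between · d_s / mean(d), so genetic
  differentiation and marker dropout grow together along the divergence
  gradient (with the defaults, θ_s spans ≈ 0.10–0.48, the field-typical range
  for such species panels) and averages θ_between = 0.30; a second
  Balding–Nichols level (θ_within = 0.03) separates seed sources within a
  species. Alleles fixed at the species level stay fixed at the source level.
* **Genotypes.** Plants carry two amplicon haplotypes per locus, drawn
  allele-by-allele from their group's frequencies (linkage equilibrium across
  sites in the population, complete linkage within each copy); with
  probability F the two copies are identical by descent, giving the standard
  partial-selfing genotype frequencies. The default F = 0.7 represents
  predominant-but-partial selfing; it keeps enough residual heterozygosity
  that the Hind/HE filter's lower bound operates as a filter rather than
  rejecting essentially all true SNPs (the biology-facing tests exercise
  F = 0 and F = 0.9 explicitly).
* **Reads.** Per-locus amplification efficiency is lognormal (σ = 1.3, unit
  mean) and shared across samples — this locus effect is what makes replicate
  read-count profiles correlate, as they do in real amplicon data. Depth per
  sample × locus is negative binomial (mean 60 × efficiency, dispersion 30);
  reads are split multinomially across the sample's allele copies (2 or 14);
  with probability 0.05 per amplified sample × locus one spurious depth-1
  haplotype (a one-base mutation away from a real sequence, off the variant
  sites) is added. Dropped loci emit no reads.
* **Truth and mislabels.** A truth sidecar (JSON, lossless round trip) records
  amplification flags, frequencies, per-plant genotypes, true labels, and any
  injected species-label swaps (metadata carries the wrong label; truth keeps
  the real one). One seed determines everything; identical config + seed give
  byte-identical MADC and truth files.

What the generator does **not** emulate: linkage maps and recombination,
indels, paralogous amplification (low-identity haplotypes arise only from the
error model), quality scores, batch effects, and any correlation between a
locus's amplification efficiency and its divergence. Passing tests therefore
demonstrate correctness of the algorithms and calibration under these
idealised conditions, not performance on any particular real panel.

## Problem sizes and orchestration

The pipeline (`madcpop.pipeline.run_pipeline`, CLI `madcpop run`) executes the
stages in fixed order — simulate/ingest → depth-1 zeroing → presence filters →
SNP extraction → VCF → Hind/HE filter → dosage → diversity/correlations →
missingness statistics → PCA/FST → phylogeny → mislabel flags — writing every
artifact and a JSON run report whose per-stage in/out counts must reconcile
(in = out + dropped). Reruns with the same config and seed reproduce all
CSV/VCF/newick/JSON outputs byte for byte.

Tests and the acceptance script run the generator at reduced problem sizes
(hundreds to ~1,200 loci, tens of accessions) chosen so each statistical check
retains clear resolution: e.g. the missingness-divergence grid uses 1,200 loci
because the ~6%-per-step amplification gradient must clear binomial noise, the
estimator-recovery experiments use 2,000 SNPs and 20+20 diploids per
population, and the mislabel experiments use 600 loci with three equidistant
species (pairwise θ = 0.3) and two injected swaps. Weir–Cockerham, TN93, NJ
and Hind/HE are each validated against an independently coded oracle
(exhaustive enumeration, direct formula evaluation, or patristic-distance
reconstruction on random additive trees); Welch's ANOVA and Games–Howell are
additionally cross-checked against an independent implementation and their
type-I error calibrated on 2,000 heteroscedastic null replicates.

## Known limitations

* The Hind/HE filter interacts strongly with population structure (see above);
  users analysing multi-species panels should treat the filtered SNP set as a
  within-species-quality set, not a taxonomy set.
* The dosage caller has no population prior, so low-coverage heterozygotes are
  under-called relative to hierarchical-Bayes callers.
* Mislabel flagging assumes species form compact clusters; between sister
  species whose separation is comparable to within-species spread it
  deliberately abstains.
* TN93 distances saturate for highly divergent sequence pairs; such pairs are
  pruned, so extremely divergent samples can drop out of the tree.
* FST between groups with very few genotyped individuals (2–3) is noisy; the
  source-vs-source table reports "–" where a pair lacks data but small-n
  estimates it does report should be read with that caveat.
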