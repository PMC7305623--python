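# Methods

`ncatspipe` re-implements the downstream, post-alignment analysis of a
Cas9-targeted nanopore panel that simultaneously reads out *MGMT* CpG
methylation and *IDH1/2* genotype. Everything upstream of the per-read call
tables — basecalling, alignment, and the signal-level HMMs that emit
per-read methylation log-likelihood ratios (LLRs) and re-evaluate variant
candidates — is out of scope; their *outputs* are the modelled interfaces.
A seeded synthetic-data layer (`simdata`) generates every input the
pipeline consumes, so the whole analysis is reproducible at the desk.

## Per-read methylation calls and aggregation

A methylation caller emits, per read and CpG group, a base-e LLR: positive
favours 5mC, negative favours unmodified cytosine. Aggregation (`methio`)
follows the semantics of the standard frequency-calculation step:

- a call is **qualifying** iff `|LLR| >= llr_cutoff` (default 2.5);
  ambiguous calls are excluded from numerator *and* denominator;
- a qualifying call is methylated iff `LLR >= +llr_cutoff`;
- a site is reported only with `>= min_reads` (default 10) qualifying
  calls; per-site frequency = methylated / qualifying.

The magnitude filter is applied **per call**, not per site: a site-level
mean-LLR filter would leave "frequency" ill-defined. Depth for the
`min_reads` gate counts qualifying calls only, consistent with the
`called_sites` column of the frequency dialect. Calls spanning a group of
several CpG motifs contribute the same state to every motif in the group
(positions recovered from the CG offsets of the call's sequence context).
CpGs are palindromic; minus-strand calls are collapsed onto the
plus-strand C. Coordinates are 0-based half-open internally and 1-based
only in rendered reports.

Read-level QC keeps reads with mean Phred quality strictly above 8 and
length strictly above 200 bases; mean quality is computed on the error
scale, `-10*log10(mean per-base error probability)`, so one terrible base
weighs more than the arithmetic mean of Q-scores would suggest.

The clinical 3-category readout bins a methylation fraction as
not detected (< 10%), low (10–30%, both boundaries inside the band) and
detected (> 30%). Boundary inclusivity is config-exposed because the
printed convention ("10–30%") is inclusive while the outer bands are
strict.

## Synthetic data model

**Standards.** The quantitative control is a linear 897-bp molecule with
exactly 52 CpG sites, sequenced fully methylated and fully unmethylated.
The generator places the requested number of disjoint CG dinucleotides
uniformly at random among feasible layouts (a bijection onto n-subsets
makes tight packings exact: 3 CpGs in 6 bp can only be `CGCGCG`), fills
the remainder with random bases and deterministically breaks any
accidental CG, so the CpG count is exact, not approximate. The
methylated/unmethylated *assessment* standards are emulated with per-CpG
truth 0.98 / 0.02 (the products are specified as > 95% and < 5%
methylated).

**LLR model.** A truly methylated call draws `+|N(mu_meth, sigma)|`, an
unmethylated one `-|N(mu_unmeth, sigma)|`, and the sign is flipped with
probability `miscall_rate`. Defaults `mu = 4.0`, `sigma = 1.5`,
`miscall_rate = 0.03` give ~16% ambiguous calls at the 2.5 cutoff and a
control readout of ~95% / ~5% — usable calls at 10–20X with measurable
dispersion, matching the qualitative behaviour of the real assay. The
real per-read LLR distribution of the deposited standards was never
characterised; these defaults are a modelling choice, configurable
everywhere. Simulated reads have no length model; a read id links the
calls of one simulated molecule across the sites of a region.

**Panel.** The capture panel is synthetic but honours the assay's
geometry exactly: the *MGMT* region carries 98 CpGs in the promoter/exon-1
subregion (1000 bp) and 121 CpGs in the 5' portion of intron 1 (1400 bp);
CpGs are numbered 1..219 from the 5' end of the capture, which places the
clinically relevant DMR2 at panel indices 70–81 (12 CpGs). The *IDH1* and
*IDH2* exon-4 amplicons (400 bp each) carry their wild-type hotspot
codons — CGT (R132) and AGG (R172) — forced verbatim at a fixed offset so
the canonical CGT→GGT and AGG→AAG substitutions can be planted. Which
genomic CpG is literature-CpG #1 is configured via the captured interval,
never hard-coded: real coordinates would come from the reference genome,
which this desk-scale package does not download.

**Pileups.** Per read and position, the true base is the planted alt with
probability `allele_fraction`; the read then deletes the base
(`del_rate`, default 0.03) or substitutes it uniformly to one of the
other three bases (`sub_rate`, default 0.05). Substitution error is
multiplied (default 2.0, capped at 0.75) inside homopolymer runs of
length >= 5, reflecting the dominant error mode of the pore chemistry.
Insertions do not alter column counts.

**Cohort.** Per sample a latent exon-1 methylation mean is uniform on
[0.1, 0.9] and the intron-1 mean mirrors it (`1 - exon_mean`) —
the anti-correlated block structure the assay observed across cell lines
and tumours. Each CpG scatters N(block mean, 0.05) clipped to [0, 1]
(12 exon CpGs at panel indices 70–81, 34 intron CpGs from 99), and
log2 relative expression is
`intercept + exon_effect*exon_mean + intron_effect*intron_mean + N(0, noise_sd)`
with defaults −1 / +1 / 0.3. The generator plants structure; it does not
model cellular heterogeneity, bimodal allele-specific methylation, batch
effects, or the tail behaviour of real qRT-PCR — so recovery of the
planted signs and blocks demonstrates correctness of the estimators, not
performance on tissue.

## Limit of detection by subsampling

Mixtures at level `p` draw `round(p*depth)` calls per site without
replacement from the 100% pool and the rest from the 0% pool; replicates
use independent RNG streams fanned out from one master seed, making the
full titration bit-reproducible. The default design titrates levels
{0, 10, 25, 50, 75, 100}% over depths {5, 10, 15, 20, 25, 50} with 100
replicates per cell (the original figure does not state its replicate
count or depth grid; these are recorded in the output metadata). Each
replicate is aggregated with the clinical filters and summarised by its
mean frequency across reported CpGs; a replicate losing every site to the
10-read filter is recorded unusable, never silently dropped (at 5X every
site fails the filter, so those cells are marked unusable — the same
forcing that renders a 5X sample's methylation "unusable" in reports).

Dispersion is CV = SD/mean per cell (undefined at mean 0 and reported
missing). Distinguishability uses two-sided Welch t-tests between all
C(5,2) = 10 pairs of the canonical levels {0, 25, 50, 75, 100}% at each
depth, Bonferroni-corrected over the 10 pairs; Welch because replicate
variance differs strongly across levels, with a closed-form guard for the
zero-variance degenerate case. The 10% mixture is titrated but excluded
from the 5-level separation claim, which the assay states for the five
canonical levels. `lod_depth` is the smallest depth at which every pair
separates at alpha (0.05). Because the mixture fixes the read composition
exactly, replicate CV sits *below* the binomial closed form
`sqrt((1-p)/(p * depth * n_sites))`; the tests use that closed form as an
upper envelope and check that dispersion shrinks with depth. At odd
depths the composition granularity (`round(p*depth)/depth`) biases the
recovered level by up to 1/(2*depth); at 20X and 50X the 50% mixture is
exact.

## Diploid SNV calling

The caller consumes base-count pileup columns. Gates mirror the assay's
settings: no call below candidate depth 10; the candidate alt is the most
frequent non-reference base, considered only at frequency >= 0.15. The
genotype is the argmax over {0/0, 0/1, 1/1} of a binomial likelihood of
the alt count at depth with expected alt fractions {e, 1/2, 1−e},
`e = error_rate/3` (uniform priors, default error 0.05, configurable);
call quality is the log-likelihood margin between the best and
second-best genotype. This replaces the signal-level re-evaluation of the
original caller with a transparent count model — the reported outputs
(genotype + allele frequency) are the same surface. Indels and
multi-allelic sites are out of scope; the panel targets are SNVs.

Methylation-awareness: at known panel CpGs, C→T (and the minus-strand
image G→A) candidates are excluded as 5mC-context artifacts before the
candidate is chosen. The homopolymer flag marks calls within or
immediately adjacent to single-base runs >= 5 (the problematic *MGMT*
locus sits in a 6-G run); it is advisory metadata and never suppresses a
call — consequently, the >= 99% planted-genotype recovery guarantee is
stated for uniform error <= 0.10 and does not extend to
homopolymer-inflated loci. Somatic classification against a matched
normal: variant in tumour + reference in normal → somatic; variant in
both → germline; reference in tumour → absent; any no-call →
inconsistent. Cross-platform allele-frequency agreement uses Pearson's
chi-squared on the 2x2 ref/alt table without continuity correction.

## Methylation–expression association

Relative expression from qRT-PCR is `2^(-dCt)` with
`dCt = mean(target Ct) - mean(ACTB Ct)` over technical triplicates
(missing replicates are dropped and flagged). The normalisation formula is
a design choice (the assay names the instrument chemistry, not the
formula); correlations are taken against **log2** expression, the scale on
which the generative model is linear, with raw-scale correlation available
via config.

Per-CpG Pearson correlations are pairwise-complete with a minimum of 4
samples; zero-variance CpGs are flagged and never selected. Selection is
strict (`|r| > 0.7`); p-values are reported for transparency but not used
for selection, and no multiple-testing correction is applied — the
analysis selects on effect size. Clustering of the selected matrix is
agglomerative on Euclidean distance with average linkage (the common
heatmap default; linkage and distance are config-exposed), missing values
handled with pairwise-complete distances; a 2-cluster cut labels the
exon/intron partition. Leaf ordering is scipy's deterministic ordering
with ties broken by input order.

## Pipeline orchestration

One YAML config drives the end-to-end run; every parameter defaults to
the assay's stated value where one exists. A single master seed is
hashed into per-stage, per-sample child streams (SHA-256 of the stage/
sample tags mixed into a `SeedSequence`), so identical config + seed
reproduce byte-identical TSV/VCF outputs while any stage can be re-run in
isolation. Per-sample failures are logged and recorded in the manifest
without aborting other samples. Reports are emitted as machine-readable
JSON and rendered text; the manifest records every effective parameter.

## Problem sizes

The shipped analyses run the full titration grid (6 levels x 6 depths x
100 replicates on the 52-CpG standard), 1000 seeded genotype-recovery
trials at 50X, and 200 synthetic cohorts of 50 samples for
sign-recovery — sizes chosen so the complete analysis reruns from scratch
in a few minutes on one core. The assay's real-data correlations
(r = −0.77/+0.78 on 8 samples; −0.51/+0.67 on 12) depend on raw signal
data and unpublished qRT-PCR values and are not reproducible from this
repository; parameter recovery on synthetic cohorts is the corresponding
validation surface here.

## Known limitations

- The LLR model is parametric and symmetric; real per-read LLRs are
  heavier-tailed and context-dependent.
- The caller's binomial model ignores strand and base-quality information
  and cannot represent indels.
- The cohort generator's exon/intron mirror coupling is exact; real
  samples decouple the two regions to varying degrees.
- CpG enumeration assumes an unambiguous reference; ambiguity codes never
  match, so reference gaps silently reduce the panel count.
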