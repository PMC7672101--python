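# Methods

## The model

A tumor with defective global-genome nucleotide excision repair accumulates
bulky DNA lesions — taken here to sit on purine bases — everywhere except
where transcription-coupled repair (TC-NER) reaches them: the template
strand of transcribed genes. During S phase, lesions on the strand
replicated as lagging template are bypassed by error-prone translesion
synthesis more often than on the leading strand. Three multiplicative
effects on the per-site mutation probability follow, and they are both what
the synthetic generator injects and what the analysis modules estimate:

- a **transcriptional factor** F_t: conversion of template-strand purine
  lesions is divided by 1 + (F_t − 1)·c_b in a gene of expression bin b,
  where c_b is the repair coupling of that bin (default 0, 0.25, 0.6, 1.0
  across the four RPKM bins 0–0.1, 0.1–1, 1–10, 10–20,000; default F_t = 2);
- a **replication factor** F_r: conversion is multiplied by
  1 + (F_r − 1)·P(lesion strand replicated as lagging), with
  P = (1 ∓ f)/2 from the fork-direction value f ∈ [−1, 1] at the site
  (default F_r = 1.4);
- a **timing gradient** F_g: rate scales linearly from 1 at the earliest
  timing value (10) to F_g at the latest (85) (default F_g = 1.5).

Strand convention, used consistently everywhere: an SBS is represented
pyrimidine-centrically; inside a gene it is labeled *untranscribed* when the
pyrimidine of the mutated pair lies on the coding strand (its purine partner
is then on the template strand and is the repaired lesion) and *transcribed*
otherwise. Regions covered by genes on both strands are excluded as
ambiguous. Under this convention TC-NER depletes the untranscribed label,
so the transcribed/untranscribed count ratio estimates the effective repair
factor.

## Synthetic scenes

`synthetic.make_genome` draws an i.i.d. genome (default 2 × 5 Mb, GC 0.42)
and places non-overlapping genes (default 100, log-uniform 10–60 kb) with
random strands and log-uniform expression spanning 10⁻²–10³ RPKM.
`make_tracks` builds a sinusoidal replication-timing surface (period 2 Mb,
range 10–85) observed by several "cell lines" with Gaussian noise (sd 3) and
a configurable fraction of discordant regions (to exercise the sd ≤ 15
consensus filter); fork direction is the tanh-saturated gradient of the
surface observed twice with noise 0.05 (exercising the ≤0.4 concordance
filter); one active-like mark tracks early timing plus log-expression over
gene bodies, one repressive-like mark tracks late timing; mappability is 1
outside a few planted 50-kb zero stretches; chromatin states are timing
terciles.

`make_catalog` is lesion-first: each mutation's channel is drawn from a
signature mixture, a genomic site with the matching pyrimidine-centric
trinucleotide (on either strand) is drawn uniformly and accepted with
probability proportional to the three factors above. The factors apply to
the lesion-driven signatures only (default: the first); background
signatures see the timing gradient but are strand-symmetric, which is what
lets strand-resolved signature refitting show a contrast. Per-sample counts
default to 5,000 SBS plus 0.6% DBS and 7% indels (dominated by 1-bp C:G
deletions in homopolymers); 0.3% of SBS are planted as short clusters
(second mutation 1–16 bp from an anchor). VAFs are binomial at depth 45
around mean 0.45 with the alt reads split between read orientations. Every
variant carries its latent truth (signature, lesion strand, strand label,
timing/fork value, cluster id) in a truth table and in `XSIM_*` INFO fields.

What the generator does **not** emulate: real genome composition and repeat
structure, germline variation, subclonal architecture, FFPE or sequencing
artifacts beyond binomial depth sampling, gene-dense overlapping loci, and
double-strand-break-driven structural events. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
mechanism, not robustness to every artifact of real data.

## Estimators and numerical choices

**Exact 2×2 machinery.** The two-sided p sums central hypergeometric
probabilities ≤ the observed one (relative tie tolerance 1e-7). The odds
ratio is the conditional MLE (E_ψ[a] = a) and the CI inverts the one-sided
noncentral hypergeometric tests at α/2, all in log space so margins in the
hundreds are safe. Default mode mirrors R's `fisher.test` computational
path — Brent root-finding at `uniroot`'s default tolerance on the
reciprocal scale — so results agree digit-for-digit with the reference
environment; `mode="exact"` instead bisects on log-odds to 1e-10 and
satisfies the inversion identity (one-sided p at each endpoint = 0.025
within 1e-6). The two differ in the third significant digit at extreme
endpoints (e.g. CI upper 2872.05 vs 2930.36 on the table (5,1;15,185)).

**NMF.** Multiplicative updates for generalized KL divergence
(Brunet variant), 500 iterations max, relative tolerance 1e-6, objective
asserted non-increasing each iteration; best of n random restarts
(seed mandatory); signatures column-normalized with exposures rescaled so
the reconstruction is unchanged. A Frobenius variant is available. Two
notes on identifiability at desk scale: with identical mixtures across
samples the count matrix is rank-1 and no optimizer can separate the
signatures (the simplicial-cone ambiguity); recovery at cosine ≥ 0.99
requires a cohort containing near-pure samples of each process, which is
also the real design (sporadic tumors carry little of the dominant
signature). Refitting solves per-sample NNLS; bootstrap CIs resample
channel counts multinomially.

**TRB factor estimation.** The per-bin transcribed/untranscribed ratio is
unbiased but, with ~100 genes, over-dispersed: a gene lies within one
replication domain, so lagging-strand mutagenesis shifts its strand ratio
coherently, and per-gene context availability fluctuates. The factor
estimator therefore (i) opportunity-normalizes per trinucleotide context by
the coding/template site availability of the genic territory, (ii)
down-weights each mutation by its expected replication multiplier given the
fork-direction consensus and the separately estimated replication factor,
and (iii) pools the per-expression-bin estimates 1 + (ratio_b − 1)/c_b by
inverse variance. Across seeds this is unbiased with ~4% sd at 20,000
mutations.

**Replication factor estimation** uses the class-pooled pyrimidine/purine
count ratios in the two extreme fork-direction bins:
sqrt(ratio_leading/ratio_lagging). Because |f| < 1 even in the extreme
bins, the estimate is mildly attenuated (≈3–5% at the default tracks).

**Timing gradient** regresses per-bin density (intergenic category, immune
to TRB) on the length-weighted mean timing per bin and evaluates the fitted
line at the scale ends.

**Cluster scan.** Random catalogs preserve each sample's context spectrum
exactly. The default sampler draws each context's quota uniformly from that
context's eligible sites — distributionally identical to the published
rejection loop (uniform draws conditioned on a context are uniform over the
context's sites), which is also implemented verbatim (`literal=True`) and
used as the equivalence oracle in tests. Context width is 0/3/5 bp
(default 3). Per 5-bp window (step 1, d = 2–10,000), each sample
contributes an add-one empirical two-sided tail probability of its observed
pair count under its own simulation null; the per-window p combines these
with Fisher's method and Bonferroni corrects over the 9,995 windows. The
add-one estimator makes per-sample p-values conservative at any replicate
count, so the combined test is calibrated (verified: 0/20 null runs with
any significant window). A signed-rank test across samples on
(observed − simulated mean) is reported alongside for reference; with few
samples its granularity (minimum two-sided p = 2/2ⁿ) cannot clear a
genome-wide Bonferroni bar, which is why it is not the primary statistic.
Detection power depends on the chance-pair background: at desk-scale
density (one SBS per ~2 kb) a 0.3% planted fraction is below the detection
limit while 1% is comfortably detected; at whole-genome density 0.3% is a
large excess.

**Timing of mutations vs copy-number events.** Eligible segments have a
duplicated allele (gain with major ≥ 2, or copy-neutral LOH). With
v_m = p·m/(2(1−p) + p·T), a mutation is *before* when
VAF ≥ v₂ − margin·(v₂−v₁) and *after* when VAF ≤ v₁ + margin·(v₂−v₁)
(default margin 0.25; margin 0 reduces to the midpoint rule with no
ambiguous class). Copy normalization divides pre-event counts by the single
duplicated lineage copy on which they could arise and post-event counts by
the T copies present afterwards; this convention is an explicit
interpretation of "per haploid copy" and is stated here because alternative
normalizations change the fraction. The simulator draws raw epochs so that
the copy-normalized expectation equals the requested fraction.

**Exact small-sample tests.** Signed-rank: zeros dropped, ties mid-ranked,
exact distribution by dynamic programming over doubled ranks for n ≤ 25,
normal approximation with tie and continuity corrections beyond.
Mann–Whitney: exact rank-sum DP for tie-free samples with n·m ≤ 400, exact
permutation enumeration for small tied samples (C(n+m,n) ≤ 20,000), normal
approximation with tie correction otherwise. Poisson pair: conditional
binomial with the minimum-likelihood two-sided rule.

## Degenerate inputs and tie-breaks

Uncovered positions fail mappability filtering; empty strand classes and
empty bins report NA rather than raising; mark-quantile grouping breaks
intensity ties by window order so group sizes differ by at most one; MDS of
identical profiles returns the origin with a warning; zero channel vectors
are rejected for cosine similarity and profile normalization; all-zero NMF
sample rows are excluded with a warning.

## Problem sizes

Defaults were chosen so each analysis runs in seconds to a couple of
minutes on one core: 2 × 5 Mb genome, 4–6 samples × 3,000–5,000 SBS for
asymmetry and cluster analyses, 30,000 mutations per sample for signature
recovery, 1,000 Monte Carlo replicates (with 20 seeded runs for null
calibration), 8 copy-number segments × 300 mutations at 45× for timing.

## Known limitations

The fork-direction and timing surfaces are smooth and periodic, so fork
domains and timing bins are more regular than in real genomes; the
replication-factor estimator inherits a small attenuation from unsaturated
fork values; ID83 microhomology uses the maximum of 5'- and 3'-flank
partial matches on the reference, which matches the standard scheme's
intent but not necessarily every tool's tie-breaking; DBS canonicalization
for palindromic reference doublets picks the lexicographically smaller
alternate, a documented convention choice; the read-level co-localization
of clustered mutations (same sequencing read) requires alignments and is
out of scope — `cluster_membership` accepts positions only.
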