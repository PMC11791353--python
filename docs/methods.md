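# Methods

## Model and rationale

A gene fusion that keeps a gene's 3′ exons on a highly expressed chimeric
transcript decouples the expression of the two parts of that gene. In
bulk RNA-seq this appears as a changepoint in the per-exon coverage
profile: exons downstream of the breakpoint (in transcriptional order) are
covered at a different per-base rate than exons upstream. Unlike chimeric
junction reads, this signal survives heavy RNA fragmentation, which makes
it attractive for FFPE material where junction-read callers lose
sensitivity. The package formalizes the visual inspection of such
profiles as a single-changepoint scan with an exact permutation test.

### Union-exon coordinate system

All coverage work uses a per-gene *union-exon* model: the union of all
annotated transcript exons, merged where overlapping, ranked 1..E from the
5′ end (strand-aware, so rank 1 of a minus-strand gene is the exon with
the largest genomic coordinate). A single coverage profile per gene is the
right resolution for this method, which asks where along the gene coverage
changes, not which isoform carries it. The trade-off: for genes with many
isoforms, union ranks can differ from any single transcript's exon
numbering, so a reported breakpoint rank should be interpreted against the
union model that produced it. Internally coordinates are 0-based
half-open; GTF conversion happens at the boundary.

### Scan statistic and standardization

With normalized coverage c_e = n_e / L_e, the signed statistic at cut
point k is

    S(k) = log2( (mean(c_k..c_E) + ε) / (mean(c_1..c_{k−1}) + ε) ),  k = 2..E.

S(k) is directly interpretable as the log2 fold of the 3′ segment over the
5′ segment; ε (default 0.01 counts/base) is a pseudocount that keeps the
ratio finite for read-free segments. A log-ratio of segment means was
chosen over a parametric (e.g. negative-binomial likelihood-ratio)
statistic because it is robust to dispersion misspecification and needs no
fitted noise model.

Raw |S(k)| values are not comparable across k: a cut isolating a single
exon has a segment mean with ~E−1 times the variance of a central cut, so
max_k |S(k)| under the null is dominated by edge cuts. Estimation and
testing therefore use the standardized scan

    Z(k) = |S(k)| / sqrt(1/(k−1) + 1/(E−k+1)),

the usual CUSUM-type weighting under a variance-∝-1/size approximation.
This mattered in practice: at the reference operating point (29 exons,
4-fold step, ~90 counts/exon, dispersion 0.1) the unstandardized scan
reached p ≤ 0.01 in only about a third of replicates, while the
standardized scan detects essentially all of them, at identical type-I
error (the permutation test is exact for any statistic). The breakpoint
estimate k̂ = argmax_k Z(k) takes the smallest k on ties (5′-most
breakpoint); the reported effect size s_max is the raw S(k̂).

### Permutation test and multiplicity

Shuffling exon order destroys the 5′/3′ contiguity that defines a
changepoint while preserving the coverage value multiset, so the null
reference for max_k Z(k) is obtained by rescanning B random exon
permutations (default B = 1000); p = (1 + #{null ≥ observed})/(B + 1).
Note the p-value floor 1/(B+1): when Benjamini–Hochberg adjustment across
m gene × sample scans must resolve calls at q ≤ α, B must exceed roughly
m/α for the floor to be rejectable — batch analyses of hundreds of genes
should raise `n_permutations` accordingly. Batch mode (`cohort_scan`)
applies BH across all scanned pairs and calls at q ≤ α (default α = 0.05);
single-profile mode calls at raw p ≤ α.

Genes with fewer than `min_exons` (default 6) exons or fewer than
`min_total_reads` (default 50) reads are reported as *not scanned* with a
reason code, never as negative calls. Both directions are scanned:
`3prime_elevated` is the kinase-retention pattern; `5prime_elevated` is
the mirror case (3′ partner lowly expressed, or the gene is the 5′ donor).

Per-profile permutation streams are seeded by a CRC of
(seed, sample_id, gene_id), so batch results are bit-for-bit reproducible
and independent of scan order.

### Positional-bias correction

Degraded RNA produces a systematic coverage trend along the transcript
that can mimic asymmetry in every gene at once. `correct_positional_bias`
estimates a per-sample baseline — the median of log2(c + ε) in bins of
relative exon position (e − 0.5)/E, default 20 bins, centred to mean zero,
linearly interpolated — and divides it out of every profile. The median
across ≥ 50 scannable genes (fewer → warning, no correction) makes the
baseline robust to a handful of genuinely fused genes, so a real
breakpoint survives correction while a sample-wide 2× 3′ ramp is removed
and the null call rate returns to nominal. The correction assumes the bias
is a function of relative position only; gene-length-dependent or
GC-dependent degradation is not modelled.

## Evidence filtering, annotation, locus classes

Caller tables are filtered by the rule *junction reads ≥ 2 OR spanning
fragments ≥ 2* (i.e. either count "greater than 1"), a threshold that in
FFPE practice retains nearly all PCR-validatable calls while discarding
single-read artifacts; both thresholds and the OR/AND combination are
configurable. Exact duplicate rows (same sample, gene pair and both
breakpoints) collapse with summed evidence; distinct breakpoints for the
same gene pair are retained as variants sharing a group key, since
alternative splice variants of one fusion are common.

Known/novel annotation matches the *ordered* (5′, 3′) gene pair against a
local catalog, optionally after collapsing symbols through an alias map
(so ARL17A/ARL17B variants count as one fusion). Orientation-sensitive
matching was chosen because the 5′/3′ roles are biologically distinct.
A fusion is classed `coding` when at least one partner is protein-coding
— any chimera carrying a protein-coding fragment can encode a product —
and `non_coding` otherwise; this is one of two defensible readings of the
coding/non-coding dichotomy and is stated here as the package's
convention.

Locus classification uses breakpoint coordinates only: different
chromosomes → `translocation`; same chromosome within
`max_local_distance` (default 1 Mb) → `local`; otherwise
`intrachromosomal_distal`. The 1 Mb default is a judgment call: wide
enough to contain same-cytoband partner pairs, narrow enough to separate
distant same-chromosome events; no annotation defines where "the same
genomic region" ends. For local pairs, a `read_through` hint is emitted
when both breakpoints share a strand and the 5′ partner's breakpoint lies
upstream of the 3′ partner's in that strand's reading direction —
transcription running through into the downstream neighbour. The hint is
heuristic; duplication-mediated fusions can produce the same geometry, and
proof of mechanism needs DNA evidence.

## Cohort concordance

Matched FF/FFPE libraries behave as two noisy observers of one event set.
Per patient, the FF and FFPE fusion-key sets (alias-collapsed ordered gene
pairs — breakpoint-level identity would split variants of one fusion) are
partitioned into shared/FF-only/FFPE-only with a Jaccard index. Cohort
recurrence counts a patient as harbouring a fusion if it appears in
*either* material. Percentages round to the nearest integer, half away
from zero. Paired comparisons (fusion counts per patient, uniquely mapped
reads, median insert size) use the closed-form paired Student's t-test on
differences (all-zero differences return t = 0, p = 1 with a degeneracy
flag rather than 0/0); rank association uses Spearman's rho with mid-rank
ties, flagged undefined for constant input. TPM and quantile normalization
(mean-of-sorted-columns reference, ties receiving the mean of the spanned
reference values) are provided for expression-matrix QC.

## Synthetic data: what it emulates, and what it does not

`simulate_exon_profile` draws exon lengths uniformly on 50–300 bp and
counts from a negative binomial with mean
depth · L_e · ramp(e) · fold^{[e ≥ k]}, dispersion 0.1 (variance
= m + 0.1 m²) — overdispersed counts keep the permutation-test calibration
check honest, where Poisson noise would be too easy. Default mean depth
0.5 counts/base gives ≈ 90 counts per exon, a realistically modest depth
for a single gene in a 15 M-read library. The degradation model is a
log-linear ramp over relative exon position with configurable endpoint
ratio — the simplest monotone confounder that defeats an uncorrected scan.

`simulate_cohort_calls` draws each patient's true fusions from a
prevalence-weighted catalog whose defaults mirror a 29-patient colorectal
cohort (one ~69%-prevalence read-through, several 2–7 patient recurrents,
one rare interchromosomal pair, one rare ALK-type fusion; fixture
breakpoints are synthetic but genomically plausible, with the minus-strand
read-through pair oriented so the 5′ partner lies upstream in reading
direction). Detection on each platform is an independent Bernoulli
(defaults 0.6/0.6), evidence counts are Poisson(6) rejection-sampled to
clear the evidence filter (keeping detection dropout and filter survival
separate effects), FFPE libraries carry 2× the FF read count, and insert
medians default to 206 (FF) vs 186 (FFPE) bases.

What passing tests on these data show: correct arithmetic, calibration and
recovery under the stated generative model. What they do not show:
performance under correlated platform dropout, isoform switching,
GC/mappability artifacts, tumour heterogeneity, or real FFPE chemistry —
the generators model none of these.

## Problem sizes and numerical choices

Statistical checks run at sizes chosen to make their tolerances
meaningful on a single CPU in seconds: 200 replicates for breakpoint
recovery, 1 000–2 000 null profiles for calibration bounds (central 99%
binomial intervals), ~2 000 true events for the dropout-arithmetic check,
B = 1000 permutations per scan (2 500 where BH must reject at the p-value
floor). Ties in the scan break toward the 5′-most cut; argmax uses the
first maximum, making results exactly reproducible across platforms. The
scan is vectorized over permutations (cumulative sums over a B × E
matrix), so a full scan of one profile costs about a millisecond.

## Known limitations

The method cannot identify the fusion partner, assess reading-frame
preservation, or distinguish a fusion from other causes of sharp
within-gene coverage change (alternative promoters, intragenic deletions,
isoform switches); it localizes a candidate breakpoint to exon resolution
and flags cases for orthogonal follow-up. Single-changepoint scanning
will blur multi-breakpoint rearrangements. BAM counting attributes a read
to every exon it overlaps (no fractional splitting), which double-counts
junction-spanning reads relative to fragment-level quantification — a
deliberate, monotone convention, not an estimator of expression.
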