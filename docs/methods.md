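# Methods

## Scope and model

apakit implements the statistics used to quantify alternative cleavage
and polyadenylation (APA) from 3'-end sequencing counts, downstream of
read alignment. The unit of analysis is the PASS read — a read whose ≥2
unaligned 5' Ts evidence a genuine poly(A)-tail junction — and the unit
of inference is the APA event: two disjoint sets of pA clusters of one
gene compared between a test and a control sample.

Coordinates are 0-based half-open throughout (BED convention); a pA
position is the cleaved nucleotide, and all windows around a pA are
reported in transcript (sense) orientation with the pA at position 0.

## PASS processing

Distinct PASS 3'-end positions within 24 nt on the same chromosome and
strand are chained into clusters (single linkage). The chain rule means
a cluster's span can exceed 24 nt; no cap is applied. The cluster
representative is the modal position by read count, ties broken toward
the 3'-most position in transcript orientation — the conventional
summary of a cleavage-site distribution. The unaligned-T rule is the
only internal-priming filter; genomic A-rich filtering is deliberately
not applied.

Clustering operates on unique positions, not read-weighted positions;
this is the simpler reading of the distance rule and makes clustering
idempotent (clustering the representatives reproduces the clusters).

## Classification

Structural classes partition the clusters: `utr3` (in the host gene's
3'-most exon), `intron`, `internal_exon`, `uaRNA` (antisense within
2 kb upstream of a TSS, not overlapping any same-strand gene body),
`intergenic`. Two non-exclusive flags ride along: `sp_flag` (sense,
0 < TSS distance ≤ 2 kb, multi-exon host, outside the 3'-most exon) and
`ua_flag`. The flags exist because the TSS-proximal sense set and the
intronic set overlap by construction — an intron-1 pA near the TSS is
legitimately both — so the TSS-proximal analyses select sites without
disturbing the structural partition.

The TSS of a multi-isoform gene is the 5'-most transcript start (the
conservative choice for "within 2 kb"). Intron ordinals +1, +2, M, −2,
−1 are defined only for genes with ≥4 introns; introns of shorter genes
are excluded from ordinal analyses. Intron structures use all isoforms'
exons unioned per gene.

## SAAP

For event counts (a1, a2) and (b1, b2) (set 1 = proximal/focal, set 2 =
distal/reference; sample a = test):

    RED = log2(a2/a1) − log2(b2/b1)

Positive RED means the distal/reference isoform gained in the test
sample — 3'UTR lengthening for tandem pairs. RED is antisymmetric under
sample swap and invariant under per-sample depth scaling.

Zero handling (Haldane policy): 0.5 is added to all four counts if and
only if at least one is zero, applied identically to observed counts
and bootstrap replicates. Pseudocount-free events are left untouched.

The null hypothesis is that both samples share the pooled relative
abundance p1 = (a1+b1)/(a1+a2+b1+b2). Each of m = 20 replicates redraws
a1* ~ Binomial(a1+a2, p1) and b1* ~ Binomial(b1+b2, p1) and computes an
expected RED. The per-event mean and SD (ddof = 1) of the m expected
REDs standardize the observed RED to Zo and the replicates to Ze.
Events with an empty sample or zero bootstrap SD are untestable and
reported with q = 1.

FDR at cutoff Zc counts over the whole event collection:

    FDR(Zc) = (#{|Ze| ≥ Zc} / m) / #{|Zo| ≥ Zc}

capped at 1; an event's q-value is the FDR at its own |Zo|, then made
monotone non-increasing in |Zo| (cumulative minimum from the least to
the most significant event — standard q-value hygiene). The ≥ (rather
than >) convention keeps the denominator nonzero at the top event and
counts an event as called at its own cutoff.

Standardization is per event (each event has its own m expected REDs),
not pooled across events; with m = 20 the Z values carry estimation
noise at the 1/√(2(m−1)) scale, which the randomization FDR absorbs.

Determinism: events are processed in canonical order (sorted by
event_id) from one seeded Philox stream, so results are independent of
input row order.

Direction labels: for tandem 3'UTR events, Le (lengthened) iff RED > 0
and q below threshold, Sh iff RED < 0. For focal-class events (CDS,
uaRNA, spRNA), set 1 is the focal class, so focal upregulation gives
RED < 0 and is labelled UP.

## GAAP

Read sets are per-cluster PASS count vectors. Per round i ∈ 1..n
(n = 20): the observed pair bootstraps p reads from each of A and B
(multinomial over cluster proportions); a fresh label permutation
splits the pooled counts A+B into sets of sizes |A| and |B| without
replacement (multivariate hypergeometric) and is bootstrapped the same
way; SAAP (with the ≥20-combined-reads event filter) runs on both
pairs, and significant events are counted per direction. The count-
vector formulation is exactly equivalent in distribution to permuting
and resampling individual reads carrying cluster identities, and scales
to p = 1.5M.

The normalized count per direction is the mean over rounds of
(observed − expected), floored at zero at the mean (per-round values are
retained unfloored for diagnostics), with the SD over rounds as the
error estimate. Observed round i is paired with permutation i for the
subtraction, which gives the per-round normalized counts whose SD is
reported. log2(Le/Sh) uses the floored means, with ±inf sentinels when
one direction is zero and NaN when both are. Defaults: n = 20,
p = 50,000 at desk scale (1.5M remains available), q < 0.05.

## Cis elements

Windows: U100_41 = −100..−41 (60 nt), U40_1 = −40..−1 (40 nt), D1_100 =
+1..+100 (100 nt); on the plus strand with the pA at genomic g, U40_1 =
[g−40, g) half-open, and minus-strand windows are mirrored and
reverse-complemented. Windows truncated by a contig edge are flagged
and excluded from counting.

K-mer enrichment uses per-sequence containment (≥1 occurrence) in a
2×2 table against a background window set, two-sided Fisher's exact
test, and SS = −log10(P)·S with S = +1 when the foreground containment
rate is at least the background's. |SS| ≥ 3 corresponds to P ≤ 0.001.
Foreground and background must come from the same positional stratum
(proximal vs proximal, distal vs distal) and are kept disjoint —
foreground sites are removed from the background.

The tandem-pair grouping splits pairs by aUTR size (<120 vs ≥120 nt,
boundary in the ≥ branch) and by exact AATAAA on the sense strand
within +1..+100 of the proximal pA (variants are not searched), and
compares group RED distributions with the two-sided two-sample K-S
test.

## Intron context

Expression changes of intronic pA isoforms are log2 ratios of RPM
(reads per million total PASS reads) between test and control, with the
≥10-combined-reads filter and the Haldane policy for zeros. Group means
over the five ordinals are mean-centered by subtracting the mean of the
(non-empty) group means; the centered profile sums to zero.

Background introns are intronic pAs detected in control samples with
isoform relative abundance ≥5% in ≥2 samples and ≥2 reads in ≥2
samples. Feature scores compare a foreground intron set to background
introns of the same ordinal stratum with the two-sided Wilcoxon
rank-sum test (exact enumeration for tie-free samples with min(n) ≤ 25,
otherwise the normal approximation with continuity correction), signed
+1 when the foreground median is larger; fully tied data give P = 1,
SS = 0. Splice-site strengths are consumed as numeric columns from
external scoring tools.

## Downstream summaries

RED matrices set an event's RED to 0 when q exceeds the threshold
before any distance computation. Hierarchical clustering uses 1 −
Pearson correlation with average linkage; zero-variance profiles are
dropped. aUTR quintiles are equal-sized with ties resolved by stable
sort on gene id; bin 1 vs bin 5 REDs are compared with the two-sided
Wilcoxon rank-sum test. The ten-group partition enumerates the 3×3
direction combinations of two focal factors (Sh/Sh = 1, Sh/ns = 2,
Sh/Le = 3, ns/Sh = 4, ns/Le = 5, Le/Sh = 6, Le/ns = 7, Le/Le = 8) at
q < 0.1, routing doubly-unregulated genes to group 9 when any other
factor regulates them and group 10 otherwise; the code mapping is
configurable. Gene-set enrichment is one-sided (enrichment only) Fisher,
per GO-analysis convention — independent of the two-sided choice in the
k-mer scan. Gene expression is RPM over 3'-most-exon PASS reads, with a
strict >20-total-reads rule for log2 changes.

## Synthetic data generator

The generator emulates the data shape the statistics assume: multi-exon
genes on both strands laid out on one contig with ≥2 kb flanks; tandem
3'UTR pAs (default two, spaced 150–1500 nt); optional intronic pAs
(uniform intron, 30% of genes), upstream antisense pAs at distances
~Normal(700, 300) nt clipped to [100, 2000] (matching the reported mode
of uaRNA-to-TSS distances), and TSS-proximal sense pAs in intron 1;
genome sequence i.i.d. uniform ACGT with motifs overwritten in named
windows at configurable insertion probabilities.

Usage is multinomial per gene: tandem pAs share a Dirichlet(2) draw of
the non-minor mass, intronic/ua/sp pAs take weights 0.20/0.10/0.10. A
planted effect multiplies the odds of targeted pAs by a fold change and
renormalizes (4-fold on a 50/50 pair gives 0.8/0.2); effects can target
single conditions in multi-condition designs. Read counts are
multinomial over genes (log-normal abundances, σ = 1, shared across
conditions so expression is condition-independent) and then over pAs;
3'-end positions get discrete uniform ±8 nt jitter (inside one 24-nt
cluster, exercising the chain rule); 5% of reads are internal-priming
decoys with <2 unaligned Ts at uniform gene-body positions.

What the generator does not emulate — and hence what passing tests do
not show about real data: overlapping and nested genes, sequencing
error, non-uniform genomic base composition and A-rich internal priming
hotspots, isoform-specific expression changes, replicate structure, and
microheterogeneity wider than the jitter. Tests on synthetic data
validate the statistics' calibration and the pipeline's bookkeeping,
not biological discovery on real libraries.

## Controlled scenarios and problem sizes

`apakit.scenarios` freezes the designs used by the test suite and the
acceptance script. Each isolates one stage and switches off nuisance
variation the stage is not responsible for:

- SAAP null calibration: 2,000 events, shared usage in [0.2, 0.8],
  50–300 reads per sample, m = 20. Expected false-call rate at q < 0.05
  stays below 0.10 given m-granularity.
- SAAP power: 4-fold odds shifts on balanced pairs at 600 reads per
  sample (≥100 per isoform per sample), pooled over 20 seeds.
- GAAP designs: 1,000 tandem-pair-only genes, balanced control usage
  (Dirichlet concentration 1000), uniform gene abundance, no decoys,
  original depth 500,000 with p = 50,000 and n = 20. The deep original
  sets reflect that real libraries are much deeper than the bootstrap
  draw — the reason depth-matching exists. Under these conditions a
  4-fold planted shift is recovered for ~80% of events, so 200 planted
  lengthening events yield a mean normalized Le count near 160. With
  heterogeneous abundances and minor pA classes at the same depth,
  per-event power drops to ~50–65% — a depth limit, not a property of
  the statistic, which is why the recovery design controls it.
- K-mer specificity: UGUA planted in U100_41 of 50% of a 200-pA
  foreground vs 10% of a 1,000-pA background of single-pA genes.
- Intron-position bias: 600 genes with 6–9 exons, one intronic pA each,
  2-fold upregulation planted on genes whose intronic pA lies in intron
  1 or 2.
- RED profiles: four conditions against a shared control; two shorten
  and two lengthen the same 150-gene responsive set, mimicking a shared
  cis-element-driven mechanism; profiles are clustered after zeroing
  non-significant REDs.

## Numerical choices

- Sample SD with ddof = 1 throughout.
- Fisher P values floored at 1e-300 before −log10.
- SAAP binomial draws use one Philox stream in canonical event order.
- Per-stage pipeline seeds derive from (global seed, stage name) so
  enabling a stage never perturbs another; all derived seeds < 2^31.
- Quintile ties: stable sort on gene id keeps bins equal-sized.
- Hierarchical clustering distance matrices are symmetrized and clipped
  at 0 before linkage to absorb floating-point asymmetry.

## Known limitations

- Two-sample designs only; no replicate-aware shrinkage or >2-sample
  contrasts.
- The randomization FDR at m = 20 has granularity ~1/(20·N); q-values
  below that resolution are reported as 0.
- Internal-priming filtering is limited to the unaligned-T rule.
- The generator's single-contig, non-overlapping gene layout makes
  classification unambiguous; real annotations require the precedence
  rules to do more work than the tests exercise.
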