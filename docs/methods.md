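# Methods

`apa_landscape` analyses alternative cleavage and polyadenylation (APA)
from 3'-end anchored RNA-seq and relates it to RNA-binding-protein
occupancy measured by CLIP-seq. This note records the models, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Peak calling and classification

A read is *poly(A)-evidenced* when it carries at least `a_min`
(default 4) non-templated adenosines past its last templated base; the
threshold separates genuine tails from genomic A-runs and is exposed as
a flag. Retained 1-based end positions are single-linkage clustered per
chromosome and strand, joining neighbours at most `merge_gap` (default
10 nt) apart; clusters with fewer than `min_reads` (default 10) reads
summed over all samples are discarded. The peak summit is the modal end
position, ties broken toward the smaller genomic coordinate so the rule
is deterministic.

Peaks are classified by their summit — a point rule keeps the priority
scheme unambiguous — against the annotation with strict precedence:

1. `utr3`: summit in an annotated 3'UTR, or up to `downstream_allowance`
   (default 2000 nt) downstream of a 3'UTR end in transcript orientation
   provided it is not inside another same-strand gene;
2. `exon`: summit in an exon of a same-strand gene;
3. `ncrna_downstream`: summit within the same allowance downstream of a
   non-coding gene end (the same 2000 nt is applied for symmetry; no
   separate distance is defined for non-coding genes);
4. `intron`: inside a same-strand gene but no exon;
5. `antisense`: inside an opposite-strand gene;
6. `unassigned`.

The six categories always partition the peak set. Ties across candidate
genes break by nearest annotated 3'UTR end, then lexicographic gene id.

## The APA shift statistic

For a gene with m ≥ 2 3'UTR peaks ordered proximal→distal, peak j gets
the rank position score s_j = j/(m−1) ∈ [0,1]. With replicate-pooled
counts n_cj for condition c and usage u_cj = n_cj/Σ_j n_cj, the *distal
usage index* is

    D_c = Σ_j u_cj · s_j ,

and the effect size is Δ = D_treatment − D_control ∈ [−1,1]. Positive Δ
means a shift toward distal cleavage (3'UTR lengthening), negative
toward proximal (shortening). Rank-based scores were chosen over
genomic-distance weights for insensitivity to UTR-length outliers and
exact bounds; for m = 2, Δ reduces to the difference in distal-usage
proportion. Exact properties (verified in tests): antisymmetry under
condition swap, invariance to per-sample library scaling, and the
two-peak reduction.

Significance is a G-test (likelihood-ratio chi-squared, df = m−1) of
homogeneity on the 2 × m condition-by-peak table of pooled counts,
followed by Benjamini–Hochberg FDR across tested genes. Peaks with zero
pooled counts in both conditions are dropped (m reduced); genes with an
all-zero condition or m < 2 are skipped with a logged reason. A call
(`lengthening`/`shortening`) additionally requires |Δ| ≥ `min_effect`
(default 0.1) so significant-but-negligible shifts stay uncalled.
Replicates are pooled rather than modelled with an overdispersion term;
a dispersion model is out of scope here and the pooled G-test is exact
to verify. Per-replicate indices are available for QC.

## Tail-length and expression tests

Per gene and sample the poly(A) tail statistic is the read-weighted mean
tail length; conditions are compared with a Welch two-sample t-test
across replicate means, BH-corrected. A degenerate statistic (identical
constant tails) reports p = 1. The per-sample global mean tail length is
always emitted, since a negative per-gene scan is only interpretable
alongside stable global means.

Gene expression is the sum of the gene's peak counts per sample,
converted to counts per million (CPM over the included genes) and tested
on log2(CPM + 0.5) with Welch t-tests and BH correction; log2FC is the
treatment-minus-control mean of log2 CPM. This is deliberately a plain
t-test, not a negative-binomial fit: differential expression is a
supporting output, and the simple estimator is exactly checkable.

## CLIP consensus and shortlisting

Peaks from each experiment are first restricted to those whose centre
(floor of the interval midpoint) lies in a same-strand annotated 3'UTR.
All surviving peaks are pooled per chromosome and strand and merged
transitively wherever they share at least `min_overlap` (default 1) nt.
Each merged consensus region records its *support* — the number of
distinct experiments contributing at least one member peak (an
experiment with several overlapping peaks counts once). Experiments are
treated exchangeably regardless of protocol. Shortlisting keeps regions
with support ≥ `min_support` (default 4 of 7) and emits both the region
list and the distinct transcript/gene companion table; region counts are
non-increasing in the threshold.

## CPA proximity and metaprofiles

Region-to-atlas distances use the region centre: 0 when the centre falls
inside a cluster, otherwise the gap to the nearest cluster edge, signed
by transcript orientation (positive = downstream of the CPA). The
within-window rule is boundary-inclusive (|d| ≤ 100 nt by default).

The metaprofile anchors each targeted 3'UTR at the midpoint of its
highest-TPM overlapping atlas cluster; TPM ties break toward the most
distal cluster because productive distal sites are the biological focus.
Coverage is binary per UTR — 1 at an offset when any peak of the set
covers that genomic position — averaged over anchored UTRs, so values
lie in [0,1] and a UTR with many stacked peaks is not over-weighted.
UTRs without an overlapping atlas cluster are excluded and logged.

## Integration statistics

The target-set enrichment is the upper-tail hypergeometric probability
P(X ≥ k) of the observed overlap k between the APA-changed set (n drawn)
and the CLIP target set (K marked) within the expressed universe (N),
where the universe is every id with a read count > 0 in any sample of
either compared condition (OR rule). The tail is summed in log space
(gammaln + logsumexp) so genome-scale N is exact, and the implementation
is cross-checked in tests against exhaustive enumeration and
`scipy.stats.hypergeom.sf`. Marked/drawn ids outside the universe are
dropped with a warning, and id spaces are never mixed.

The direction analysis takes genes significant for both APA and
expression (FDR < 0.05), ranks by expression FDR (ties: |log2FC|
descending; the ranking key is a flag since "top differentially
expressed" admits readings), truncates to `top_n` = 50, and applies a
one-sample two-sided t-test of log2FC against zero with a t-based 95%
CI. Fewer than 3 qualifying genes yields a not-computable flag rather
than a p-value. Isoform ratios (distal/total in [0,1]; long/short ≥ 0)
return NaN on zero denominators, and the ratio-vs-regulator Pearson
correlation (optionally log2 with pseudocount 0.01) requires ≥ 3
complete pairs and reports slope/intercept for plotting.

## The synthetic world

The generator states a two-condition study shaped like the motivating
design: 3 replicates per condition ("epithelial" vs "mesenchymal"),
genes with 1–4 CPA sites ≥ 50 nt apart in 500–2000 nt 3'UTRs, ~10% of
genes non-coding, and 7 CLIP experiments. Defaults the source material
does not fix were chosen once as field-plausible and not revisited:
200 genes on 2 chromosomes, 300 reads/gene mean (negative binomial,
dispersion 10, per-sample lognormal library factors), poly(A) tails
truncated-normal 70 ± 20 nt, 15% of multi-site genes truly shifted with
|δ| ∈ [0.1, 0.6] (two-thirds distal, mirroring the predominance of
lengthening in the studied transition), 30% of coding genes CLIP-bound
with per-experiment detection probability 0.7, peak-centre jitter
Normal(0, 30 nt) and 50 noise peaks per experiment.

Ground truth is exact by construction: the usage shift moves probability
mass |δ| between the proximal-most and distal-most sites (rank scores 0
and 1), so the true distal-index difference equals δ identically, and
the baseline guarantees the donor site has enough mass. Read-end jitter
(≤ 2 nt, documented bound ≤ 5) stays below the merge gap so true site
counts are recovered exactly; 5% of reads draw sub-threshold
non-templated A counts so the evidence filter is observable. CLIP peak
*centres* (not whole intervals) are clipped into the 3'UTR — clipping
the interval would shift distal-anchored peaks upstream by about half a
peak width and bias the metaprofile mode. The atlas contains one cluster
per true site (± 10 nt span) with TPM proportional to mean usage.

Not emulated: sequence content (no FASTA/FASTQ, no internal-priming
artifacts beyond the A-count filter), fragment-length/GC bias,
overlapping gene models, multi-transcript genes, and biological
correlation between APA and expression change. A green test therefore
establishes correctness of the statistics and bookkeeping on a stated
world, not robustness to alignment artifacts or annotation ambiguity.

## Determinism and degenerate inputs

Every stochastic stage derives an independent stream from
`SimConfig.seed` via `numpy` `default_rng([seed, stage])`; identical
configs give byte-identical output files. Coordinates are 0-based
half-open internally (GTF converts at the boundary; point positions in
TSVs are 1-based). Degenerate cases are defined, not errors: empty BED
files parse to empty tables, an empty atlas flags every region outside
the window with a warning, zero-variance t-statistics report p = 1, and
zero denominators in ratios report missing.

## Known limitations

Pooling replicates makes the G-test anti-conservative under strong
biological overdispersion; the null false-call rate is verified at the
stated world's dispersion only. The classifier's gene assignment uses
one transcript per gene (the simulated world's shape); annotations with
many overlapping isoforms will exercise the tie-break rules more than
the tests do. The consensus builder is exact but O(total peaks log
total peaks) per chromosome, adequate for CLIP-scale inputs, not for
billions of intervals.
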