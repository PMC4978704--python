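# Methods

## Crosslink events and deduplication

iCLIP reads truncate at the protein–RNA crosslink, so the crosslink
nucleotide is taken to be immediately 5' of the read start on the read's
strand: a plus-strand read `[s, e)` yields an event at `s − 1`, a
minus-strand read at `e`. Events at negative coordinates are dropped and
counted. PCR duplicates are removed by collapsing identical
(chromosome, strand, position, UMI) tuples; the ratio raw/unique is the
overamplification rate the random-barcode protocol monitors. RPM is
always per library: unique events in an interval × 10⁶ / total unique
events of that library. Replicates are pooled (events summed) before
peak calling but never for RPM.

Per-gene counting follows the HTSeq *union* idea on crosslink events: an
event inside exactly one gene's exonic union (same strand) counts for
that gene; events exonic in ≥2 genes are ambiguous; non-exonic events in
exactly one gene span are tracked as intronic. The four buckets conserve
the library total. Whether the original analysis counted crosslink
positions or whole-read overlaps is not recoverable from its description;
counting events keeps a single unit throughout the package and is noted
as a possible divergence.

## Permutation peak calling

Peaks are called per gene segment (the genomic span of a gene, strand
specific; intergenic events are never peak-called). Every occupied
position gets a flank score: the sum of events within ±`flank` nt
(default 15), clipped to the segment. The null re-places the segment's
total unique events independently and uniformly over segment positions;
over `n_perm` permutations (default 100) the FDR of a score `s` is

    FDR(s) = min(1, E_perm[#occupied positions with score ≥ s] /
                    #observed occupied positions with score ≥ s)

and each position inherits the FDR of its score (a step function in the
score). Significance uses a strict `FDR < 0.05`. Significant positions
within ≤ flank nt of each other merge into one peak; the summit is the
highest-count member (ties toward 5' in transcript orientation) and the
motif anchor is the midpoint `floor((start+end−1)/2)`. The published
workflow delegates the null to its peak-calling toolchain without
restating it; the uniform within-segment re-placement implemented here is
a declared choice, and the permutation stream is specified exactly (one
`integers(0, L, n)` draw per permutation) so an independent brute-force
implementation reproduces it bit for bit.

## Motif analysis

All 1,024 5mers are tallied around peak midpoints on the transcribed
strand; a 5mer is counted at the offset of its central base, within ±40
nt for enrichment and across ±100 nt for positional vectors. The null
re-draws each midpoint uniformly within its gene segment 100 times;
Z = (observed − null mean)/null SD, with Z = 0 flagged when the shuffle
SD is zero (e.g. a single shuffle). Whether the original Z used the
shuffle SD or a Poisson approximation is unstated; shuffle SD is the
implemented choice. Positional vectors are normalized by the 5mer's mean
per-offset shuffle count averaged over the ±100 nt region (region mean,
pseudo-denominator 0.5 when the null is empty) — the region-mean reading
of an ambiguous normalization sentence, recorded as such. 5mers
containing "GT" form the junction class; top-k ranking is by Z, ties by
observed count then lexicographic. Greedy maximal-overlap assembly
(minimum overlap 4 for 5mers) merges the top GT motifs into a consensus
and flags inputs that do not chain.

## High-confidence sites, candidates, exon filters

Peaks from all EJC proteins are merged transitively wherever they overlap
by ≥1 nt; merged clusters supported by fewer than two distinct proteins
are dropped, and sites overlapping any GFP-background peak are removed
(the source description says only "filtered by GFP reads"; the
peak-overlap rule is the default, with per-site GFP counts recorded for a
count-ratio alternative). Site summits are the maximum of the pooled
supporter counts. Candidate exons are BTZ peaks with zero overlap with
annotated exons, BTZ signal > 2 RPM, a confirming overlapping peak from
another EJC protein, and AGGTAAG or AGGTGAG starting within 25 nt
3'/downstream of the peak end — downstream because the EJC sits upstream
of the donor it marks. Expression thresholds are inclusive ("above a
threshold of 10 reads" → ≥10); the low-expression filter (BTZ and one
other protein > 1 RPM, RNA-seq < 0.5 RPM) uses a strict less-than on the
RNA-seq side, and its percentages are reported against all annotated
exons of a category, not only expressed ones.

## Exon classification and region map

Distinct genomic exons of protein-coding genes get exactly one of seven
categories. Terminal status wins: an exon that is first (last) in any
isoform is 5' (3') terminal, and 3' terminal outranks 5' terminal when
both apply (single-exon transcripts) — the source does not define these
conflicts, so the precedence is a package decision. Internal exons are
compared against genomically overlapping internal exons of the same
gene: a varying donor (3' boundary in transcript sense) gives alt_donor,
a varying acceptor alt_acceptor, both alt_both; otherwise constitutive
when present with identical boundaries in every isoform, variant when
skipped by at least one. The region map paints each strand position by
ascending precedence intergenic < intron < ncRNA < 3'UTR < 5'UTR < ORF
(UTRs from CDS-flanking exon parts; exons of transcripts without a CDS at
the ncRNA tier), so the labels partition each strand and cumulative
lengths sum to twice the genome length. Antisense positions of a gene
stay intergenic: iCLIP is strand-specific.

## Profiles

Exon matrices rescale each exon to 100 % of its length over 100 bins;
events map to bin `floor(offset·n_bins/length)` so binned counts are
conserved exactly, and rows are ordered by absolute exon length.
Junction metaplots use transcript-orientation offsets with the first
intronic base at 0 (last exonic base −1), so canonical deposition reads
as −24..−20. The iCLIP-vs-RNA-seq ranking normalizes each matrix by its
global mean, orders by (RNA-seq − iCLIP) row means, and labels the 2×2 of
above/below the median among expressed exons (ties on the iCLIP median
count as weak signal). Log2 fold differences compare per-exon bin maxima
on the RPM scale with a 0.5 pseudo-count (the source does not state
one); category aggregates are medians with percentile-bootstrap CIs.
Peak region assignment uses the summit so percentages form a partition.

## Statistics

The enrichment test is the exact one-sided hypergeometric upper tail,
summed in log space (gammaln + logsumexp) so values far below the double
underflow limit are exact; the test behind the published enrichment
p-value is unnamed there, and one-sided hypergeometric is the declared
choice. Welch's t uses the Welch–Satterthwaite degrees of freedom.
Benjamini–Hochberg is the standard step-up with monotone enforcement.
The differential-binding stand-in is deliberately not a
negative-binomial GLM: group means on CPM with a 0.5 pseudo-count give
the log2FC, an exact binomial test of the pooled group-A count against
the library-size-implied proportion gives the p-value, BH adjusts, and
"strongly bound" is log2FC > 3. Raw gene × library count matrices are
exportable so an NB-based tool can be run externally.

## Simulator: what it emulates and what it does not

The generator builds 60 genes by default (two chromosomes, random
strands) with 2–5 internal exons of 60–240 nt, introns of 150–400 nt,
and per-gene isoform plans realizing skipped exons and alternative
donors/acceptors/both, plus a few single-isoform ncRNA genes; every
junction carries AGGTAAG across the exon–intron boundary (last 2 exonic
+ first 5 intronic nt). Transcript abundances are log-normal (log-mean
1.5, log-SD 0.8). EJC-like libraries deposit at offsets −24..−20 from
the junction with weights declining from −24 (where real BTZ crosslinks
cluster); every junction-bearing exon end of a coding gene is eligible,
with a configurable deposited fraction. A weak GA-rich 5mer (GAAGA, the
top non-GT motif reported for several EJC proteins) is planted at the
modal crosslink of each deposition site so the motif analysis sees a
crosslink-site motif class in addition to the junction GT class;
mechanically these classes separate by the 20–24 nt deposition distance,
which is what the class-profile tests assert. PTB-like libraries bind
planted 25-nt intronic C/T tracts; GFP-like libraries are uniform over
gene spans. 15 % of coding genes are flagged TOP-like/ribosomal-like
with a 0.1 deposition multiplier. Each library draws 30,000 unique
molecules (background fraction 0.2 by default), attaches 8-nt UMIs, and
amplifies with geometric copy numbers (rate 0.35) — a distributional
choice; the source only monitors overamplification. RNA-seq coverage is
abundance-proportional and uniform along exons with Poisson noise,
essentially zero in introns. One RNG stream per (seed, library) keeps
libraries independent. Not modeled: sequencing errors, RT-stop/fragment
artifacts, splice-junction-spanning reads, mappability, GC or
crosslinking sequence bias, and isoform-level coverage non-uniformity —
so passing tests demonstrate correctness of the analysis logic under the
stated generative assumptions, not robustness to every real-data
artifact.

## Problem sizes and numerical notes

The calibration experiment uses 200 genes, 40,000 unique events, a 0.5
deposited fraction and 1:1 signal:noise with 100 permutations; the
integration experiment uses 60 genes and 30,000 events per library for
four EJC proteins plus GFP, sizes at which every quantity of interest is
stable across seeds while a full run stays in the tens of seconds.
Degenerate inputs are defined throughout: empty segments yield no
positions, zero-SD nulls yield flagged Z = 0, empty site sets raise, RPM
of an empty library raises, and single-transcript single-exon genes
classify as 3' terminal. All coordinates are 0-based half-open
internally; GTF I/O converts to and from 1-based inclusive.
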