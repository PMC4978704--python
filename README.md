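# ejckit

Transcriptome-wide analysis of exon junction complex (EJC) deposition from
iCLIP crosslink data.

The EJC is deposited during splicing roughly 20–24 nt upstream of
exon–exon junctions. Given per-library crosslink-site BED files (one
record per read, UMI in the name field), a GTF annotation, a genome FASTA
and optional RNA-seq coverage, `ejckit` reconstructs the full analysis
that turns raw crosslink events into biology:

* **crosslinks** — read-truncation geometry (crosslink = nucleotide 5' of
  the read start), random-barcode (UMI) deduplication, RPM normalization,
  HTSeq-union-style per-gene counting;
* **peakcalling** — iCount-style permutation peak calling: flank scores
  (±15 nt), a within-gene uniform re-placement null (100 permutations),
  per-score FDR with a strict <5 % cut, clustering into peaks;
* **motifs** — positional 5mer enrichment around peak midpoints (±40 nt
  counting window, ±100 nt normalization window, shuffled nulls, Z
  scores), GT vs non-GT motif classes, splice-donor profiling, and
  greedy overlap assembly of top motifs into a consensus;
* **sites** — high-confidence EJC sites (peaks of ≥2 different EJC
  proteins overlapping by ≥1 nt, filtered against a GFP background
  library), BTZ marking statistics, candidate-exon discovery
  (unannotated BTZ peaks >2 RPM confirmed by a second protein with
  AGGTAAG/AGGTGAG within 25 nt downstream), and per-exon RPM/read-count
  filters;
* **annotation / profiles** — seven-category exon classification
  (5'/3' terminal, constitutive, variant, alt donor/acceptor/both),
  strand-specific region maps (ORF > UTR > ncRNA > intron > intergenic),
  relative-length exon matrices and junction metaplots;
* **stats** — exact log-space one-sided hypergeometric enrichment,
  Welch's t test, Benjamini–Hochberg adjustment, and a self-contained
  differential-binding stand-in (CPM + exact binomial + BH) with raw
  count export for external NB-GLM tools;
* **simulate** — a synthetic transcriptome/iCLIP generator with ground
  truth: planted AGGTAAG donors at every junction, EJC deposition at
  offsets −24..−20, PTB-like pyrimidine-tract binding, uniform GFP
  background, PCR duplication with UMIs, abundance-proportional RNA-seq,
  and TOP-like/ribosomal-like EJC-depleted gene classes.

## Worked example

```python
from ejckit.workflows import ejc_pipeline_experiment

r = ejc_pipeline_experiment(seed=1)
print(f"high-confidence sites : {r['n_sites']}")
print(f"BTZ-marked sites      : {r['n_btz']}  ({100*r['btz_fraction']:.1f}%)")
print(f"canonical (-24..-20)  : {r['canonical_pct']:.1f}%")
print(f"top GT motifs         : {', '.join(r['top_gt_downstream'])}")
print(f"assembled consensus   : {r['donor_consensus']}")
```

prints

```
high-confidence sites : 262
BTZ-marked sites      : 252  (96.2%)
canonical (-24..-20)  : 95.8%
top GT motifs         : AGGTA, GGTAA, GTAAG
assembled consensus   : AGGTAAG
```

i.e. on a 60-gene simulation with four EJC-like libraries plus GFP, 262
merged ≥2-protein sites survive the GFP filter; 96 % are BTZ-marked; 96 %
of site summits sit 20–24 nt upstream of an annotated junction; and the
three GT-class 5mers most enriched in the downstream donor window
assemble to the canonical splice-donor consensus AGGTAAG. The BTZ
junction metaplot peaks at offset −24.

A shell interface chains the same stages over files:

```bash
ejckit all --seed 3 --outdir run/     # FASTA+GTF+BEDs -> peaks, motifs,
                                      # sites, candidates, profiles
```

Each stage writes a manifest with sha256 checksums; identical configs and
seeds reproduce identical checksums.

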