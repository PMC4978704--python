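"""Gene models, genomic region maps, and exon classification.

iCLIP crosslink analysis needs three things from a gene annotation: the gene
models themselves (to define the segments inside which peaks are called and
positions are shuffled), a strand-specific labeling of every genomic position
with a single functional region (5'UTR / ORF / 3'UTR / ncRNA / intron /
intergenic), and a catalog of distinct exons classified by how they behave
across a gene's isoforms (terminal, constitutive, variant, alternative
donor/acceptor/both).

Coordinates are 0-based half-open throughout; GTF I/O converts to and from
the 1-based inclusive convention.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import gffutils
import numpy as np

# Region labels in ascending precedence. Painting the map in this order means
# a position covered by several features ends up with the highest-precedence
# label (ORF beats UTR beats ncRNA beats intron beats intergenic).
REGION_LABELS = (
    "intergenic",
    "intron",
    "ncRNA",
    "three_prime_utr",
    "five_prime_utr",
    "orf",
)

EXON_CATEGORIES = (
    "five_prime_terminal",
    "constitutive",
    "variant",
    "alt_donor",
    "alt_acceptor",
    "alt_both",
    "three_prime_terminal",
)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[tuple[int, int]]  # genomic order, non-overlapping
    cds: tuple[int, int] | None = None  # genomic span; endpoints fall in exons

    def sorted_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for t in self.transcripts for s, _ in t.exons]
        ends = [e for t in self.transcripts for _, e in t.exons]
        return min(starts), max(ends)


@dataclass
class GenomeAnnotation:
    genes: list[Gene]
    chrom_lengths: dict[str, int]

    def validate(self) -> None:
        for g in self.genes:
            if g.strand not in "+-":
                raise ValueError(f"gene {g.gene_id}: bad strand {g.strand!r}")
            clen = self.chrom_lengths.get(g.chrom)
            if clen is None:
                raise ValueError(f"gene {g.gene_id}: unknown chrom {g.chrom}")
            for t in g.transcripts:
                exons = t.sorted_exons()
                prev_end = -1
                for s, e in exons:
                    if not (0 <= s < e <= clen):
                        raise ValueError(
                            f"exon [{s},{e}) of {t.transcript_id} outside "
                            f"chromosome {g.chrom} (length {clen})"
                        )
                    if s < prev_end:
                        raise ValueError(
                            f"overlapping exons in {t.transcript_id}"
                        )
                    prev_end = e
                if t.cds is not None:
                    cs, ce = t.cds
                    if not any(s <= cs < e for s, e in exons) or not any(
                        s < ce <= e for s, e in exons
                    ):
                        raise ValueError(
                            f"CDS span [{cs},{ce}) of {t.transcript_id} does "
                            "not start/end inside an exon"
                        )

    def protein_coding_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.biotype == "protein_coding"]

    def gene_segments(self) -> list[tuple[str, str, str, int, int]]:
        """(gene_id, chrom, strand, start, end) spans; the peak-calling segments."""
        return [(g.gene_id, g.chrom, g.strand, *g.span) for g in self.genes]

    def junctions(self) -> list[tuple[str, str, int, str]]:
        """Distinct exon-exon junctions as (chrom, strand, j, gene_id).

        ``j`` is the genomic coordinate of the first intronic base in
        transcript orientation (plus strand: donor exon end; minus strand:
        donor exon start - 1).  Every non-3'-terminal exon end of every
        transcript contributes; duplicates across isoforms are collapsed.
        """
        seen: dict[tuple[str, str, int], str] = {}
        for g in self.genes:
            for t in g.transcripts:
                exons = t.sorted_exons()
                if g.strand == "+":
                    donors = [e for _, e in exons[:-1]]
                else:
                    donors = [s - 1 for s, _ in exons[1:]]
                for j in donors:
                    seen.setdefault((g.chrom, g.strand, j), g.gene_id)
        return [(c, st, j, gid) for (c, st, j), gid in sorted(seen.items())]


def junction_offset(pos: int, junction: int, strand: str) -> int:
    """Signed transcript-orientation offset of ``pos`` from a junction.

    The first intronic base is offset 0; the last exonic base is -1; the
    canonical EJC deposition window is -24..-20.
    """
    return pos - junction if strand == "+" else junction - pos


@dataclass
class ExonRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    category: str

    @property
    def length(self) -> int:
        return self.end - self.start


class ExonCatalog:
    """Distinct genomic exons of protein-coding genes with one category each."""

    def __init__(self, exons: Iterable[ExonRecord]):
        self.exons = list(exons)

    def __len__(self) -> int:
        return len(self.exons)

    def __iter__(self) -> Iterator[ExonRecord]:
        return iter(self.exons)

    def by_category(self, category: str) -> list[ExonRecord]:
        if category not in EXON_CATEGORIES:
            raise ValueError(f"unknown exon category {category!r}")
        return [x for x in self.exons if x.category == category]

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in EXON_CATEGORIES}
        for x in self.exons:
            out[x.category] += 1
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (x.gene_id, x.chrom, x.strand, x.start, x.end, x.length, x.category)
                for x in self.exons
            ],
            columns=["gene_id", "chrom", "strand", "start", "end", "length", "category"],
        )


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def read_gtf(path: str, chrom_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    If ``chrom_lengths`` is omitted the per-chromosome maximum feature end is
    used (adequate for simulated genomes; pass real sizes for real ones).
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"malformed GTF {path}: {exc}") from exc

    genes: dict[str, Gene] = {}
    for gf in db.features_of_type("gene"):
        gid = gf.attributes["gene_id"][0]
        biotype = (
            gf.attributes.get("gene_biotype", ["protein_coding"])[0]
        )
        genes[gid] = Gene(gid, gf.seqid, gf.strand, biotype)

    transcripts: dict[str, Transcript] = {}
    for tf in db.features_of_type("transcript"):
        tid = tf.attributes["transcript_id"][0]
        gid = tf.attributes["gene_id"][0]
        if gid not in genes:
            genes[gid] = Gene(gid, tf.seqid, tf.strand, "protein_coding")
        transcripts[tid] = Transcript(tid, gid, [])
        genes[gid].transcripts.append(transcripts[tid])

    cds_bounds: dict[str, list[int]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        if tid not in transcripts:
            gid = feat.attributes["gene_id"][0]
            transcripts[tid] = Transcript(tid, gid, [])
            genes[gid].transcripts.append(transcripts[tid])
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        if feat.featuretype == "exon":
            transcripts[tid].exons.append((start, end))
        else:
            b = cds_bounds.setdefault(tid, [start, end])
            b[0] = min(b[0], start)
            b[1] = max(b[1], end)

    for tid, (cs, ce) in cds_bounds.items():
        transcripts[tid].cds = (cs, ce)
    for t in transcripts.values():
        t.exons = t.sorted_exons()

    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes.values():
            _, end = g.span
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), end)

    ann = GenomeAnnotation(sorted(genes.values(), key=lambda g: g.gene_id), dict(chrom_lengths))
    ann.validate()
    return ann


def write_gtf(ann: GenomeAnnotation, path: str) -> None:
    """Write gene/transcript/exon/CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in ann.genes:
            gs, ge = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tejckit\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                exons = t.sorted_exons()
                ts, te = exons[0][0], exons[-1][1]
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\tejckit\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in exons:
                    fh.write(
                        f"{g.chrom}\tejckit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )
                    if t.cds is not None:
                        cs, ce = max(s, t.cds[0]), min(e, t.cds[1])
                        if cs < ce:
                            fh.write(
                                f"{g.chrom}\tejckit\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t.\t{tattrs}\n"
                            )


def read_chrom_sizes(path: str) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split()[:2]
            out[chrom] = int(length)
    return out


def write_chrom_sizes(chrom_lengths: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# Region map
# ---------------------------------------------------------------------------

class RegionMap:
    """One region label per strand-specific genomic position.

    Labels partition each strand of the genome, so cumulative lengths sum to
    twice the genome length. Positions antisense to a gene stay intergenic
    unless an antisense gene covers them (iCLIP is strand-specific).
    """

    def __init__(self, labels: dict[tuple[str, str], np.ndarray]):
        self.labels = labels

    def label_at(self, chrom: str, strand: str, pos: int) -> str:
        return REGION_LABELS[self.labels[(chrom, strand)][pos]]

    def cumulative_lengths(self) -> dict[str, int]:
        out = {lab: 0 for lab in REGION_LABELS}
        for arr in self.labels.values():
            counts = np.bincount(arr, minlength=len(REGION_LABELS))
            for i, lab in enumerate(REGION_LABELS):
                out[lab] += int(counts[i])
        return out


def build_region_map(ann: GenomeAnnotation) -> RegionMap:
    """Label every strand-position with one region.

    Precedence orf > 5'UTR > 3'UTR > ncRNA > intron > intergenic; painting
    proceeds in ascending precedence so later tiers overwrite earlier ones.
    UTRs are the CDS-flanking exon parts of coding transcripts; exons of
    transcripts lacking a CDS are painted at the ncRNA tier; intron = inside
    a gene span but not exonic.
    """
    code = {lab: i for i, lab in enumerate(REGION_LABELS)}
    labels = {
        (chrom, strand): np.zeros(length, dtype=np.uint8)
        for chrom, length in ann.chrom_lengths.items()
        for strand in "+-"
    }

    def paint(chrom, strand, s, e, lab):
        labels[(chrom, strand)][s:e] = code[lab]

    # tier 1: introns (whole gene spans; exonic tiers overwrite)
    for g in ann.genes:
        s, e = g.span
        paint(g.chrom, g.strand, s, e, "intron")
    # tier 2: non-coding exons (ncRNA genes, and coding transcripts w/o CDS)
    for g in ann.genes:
        for t in g.transcripts:
            if g.biotype != "protein_coding" or t.cds is None:
                for s, e in t.exons:
                    paint(g.chrom, g.strand, s, e, "ncRNA")
    # tiers 3-5: UTRs then ORF from coding transcripts with a CDS
    for tier in ("three_prime_utr", "five_prime_utr", "orf"):
        for g in ann.genes:
            if g.biotype != "protein_coding":
                continue
            for t in g.transcripts:
                if t.cds is None:
                    continue
                cs, ce = t.cds
                for s, e in t.exons:
                    if tier == "orf":
                        a, b = max(s, cs), min(e, ce)
                        if a < b:
                            paint(g.chrom, g.strand, a, b, tier)
                        continue
                    # exon parts 5' of the CDS start / 3' of the CDS end,
                    # in transcript orientation
                    if g.strand == "+":
                        five = (s, min(e, cs))
                        three = (max(s, ce), e)
                    else:
                        five = (max(s, ce), e)
                        three = (s, min(e, cs))
                    part = five if tier == "five_prime_utr" else three
                    if part[0] < part[1]:
                        paint(g.chrom, g.strand, part[0], part[1], tier)
    return RegionMap(labels)


def cumulative_region_lengths(rm: RegionMap) -> dict[str, int]:
    """Per-label nucleotide totals; sums to 2x the genome length."""
    return rm.cumulative_lengths()


# ---------------------------------------------------------------------------
# Exon classification
# ---------------------------------------------------------------------------

def _donor_acceptor(start: int, end: int, strand: str) -> tuple[int, int]:
    """(donor, acceptor) boundary coordinates of an exon in transcript sense."""
    return (end, start) if strand == "+" else (start, end)


def classify_exons(ann: GenomeAnnotation) -> ExonCatalog:
    """Classify each distinct genomic exon of every protein-coding gene.

    Terminal status wins: an exon that is the first (last) exon of any
    isoform is 5' (3') terminal, with 3' terminal taking precedence when both
    apply (single-exon transcripts). Internal exons are compared against the
    other internal exons of the gene: a boundary that varies among
    genomically overlapping internal exons makes the exon alt_donor /
    alt_acceptor / alt_both; otherwise the exon is constitutive when present
    with identical boundaries in every isoform and variant when skipped by
    at least one isoform.
    """
    records: list[ExonRecord] = []
    for g in ann.protein_coding_genes():
        if not g.transcripts:
            continue
        all_exons: set[tuple[int, int]] = set()
        first_set: set[tuple[int, int]] = set()
        last_set: set[tuple[int, int]] = set()
        for t in g.transcripts:
            exons = t.sorted_exons()
            all_exons.update(exons)
            if g.strand == "+":
                first_set.add(exons[0])
                last_set.add(exons[-1])
            else:
                first_set.add(exons[-1])
                last_set.add(exons[0])
        internal = sorted(all_exons - first_set - last_set)
        for ex in sorted(all_exons):
            s, e = ex
            if ex in last_set:
                cat = "three_prime_terminal"
            elif ex in first_set:
                cat = "five_prime_terminal"
            else:
                donor, acceptor = _donor_acceptor(s, e, g.strand)
                donor_varies = acceptor_varies = False
                for os_, oe in internal:
                    if (os_, oe) == ex or oe <= s or e <= os_:
                        continue  # self or no genomic overlap
                    od, oa = _donor_acceptor(os_, oe, g.strand)
                    donor_varies |= od != donor
                    acceptor_varies |= oa != acceptor
                if donor_varies and acceptor_varies:
                    cat = "alt_both"
                elif donor_varies:
                    cat = "alt_donor"
                elif acceptor_varies:
                    cat = "alt_acceptor"
                elif all(ex in t.exons for t in g.transcripts):
                    cat = "constitutive"
                else:
                    cat = "variant"
            records.append(ExonRecord(g.gene_id, g.chrom, g.strand, s, e, cat))
    return ExonCatalog(records)
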