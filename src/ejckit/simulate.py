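"""Synthetic transcriptome and iCLIP/RNA-seq simulator with ground truth.

Generates a small genome whose genes realize all seven exon categories,
plants the splice-donor consensus (default AGGTAAG: last 2 exonic + first 5
intronic nt) across every exon-intron junction, and simulates per-protein
crosslink libraries:

* EJC-like proteins deposit 20-24 nt upstream of exon-exon junctions
  (offsets -24..-20 from the first intronic base, weighted toward -24),
  on every junction-bearing exon end of protein-coding genes;
* PTB-like proteins bind planted intronic pyrimidine tracts;
* GFP-like libraries are uniform over transcribed gene spans.

Unique crosslink molecules receive random-barcode UMIs and are PCR-amplified
with a geometric copy-number model. A configurable fraction of genes is
flagged TOP-like / ribosomal-protein-like with depleted EJC deposition.
A weak binding-site motif (GAAGA, the top non-GT 5mer reported for several
EJC proteins) is planted at the modal crosslink of deposition sites so the
motif analysis sees both a crosslink-site class and a junction (GT) class
of 5mers, separated by roughly the 20-24 nt deposition distance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, Transcript

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream per (seed, name); adding a library never
    perturbs the draws of another."""
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng([int(seed) % (2**31), h])


@dataclass
class ProteinModel:
    kind: str  # "ejc" | "ptb" | "uniform"
    non_ejc_fraction: float = 0.0  # extra 5'-biased non-junction sites

    def __post_init__(self):
        if self.kind not in ("ejc", "ptb", "uniform"):
            raise ValueError(f"unknown protein model kind {self.kind!r}")
        if not 0.0 <= self.non_ejc_fraction <= 1.0:
            raise ValueError("non_ejc_fraction must be in [0, 1]")


def default_proteins() -> dict[str, ProteinModel]:
    return {
        "BTZ": ProteinModel("ejc", 0.0),
        "eIF4A3": ProteinModel("ejc", 0.10),
        "UPF3B": ProteinModel("ejc", 0.10),
        "RNPS1": ProteinModel("ejc", 0.15),
        "PTB": ProteinModel("ptb"),
        "GFP": ProteinModel("uniform"),
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 60
    n_ncrna_genes: int = 3
    n_internal_exons: tuple[int, int] = (2, 5)   # inclusive range per gene
    exon_length: tuple[int, int] = (60, 240)
    intron_length: tuple[int, int] = (150, 400)
    spacer_length: tuple[int, int] = (200, 600)
    utr5_length: tuple[int, int] = (20, 50)
    utr3_length: tuple[int, int] = (30, 80)
    donor_consensus: str = "AGGTAAG"             # 2 exonic + 5 intronic nt
    site_motif: str = "GAAGA"                    # weak crosslink-site motif
    site_motif_fraction: float = 1.0
    pyrimidine_tract_length: int = 25
    # per-gene isoform plan: how many genes carry each alternative-splicing
    # kind; remaining genes are single-isoform. None -> weighted random mix.
    category_plan: dict[str, int] | None = None
    variant_kind_weights: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.40, "skip": 0.25, "alt_donor": 0.12,
            "alt_acceptor": 0.12, "alt_both": 0.11,
        }
    )
    abundance_lognormal: tuple[float, float] = (1.5, 0.8)  # (mean, sigma) of log
    # EJC deposition window: offsets from the first intronic base, weighted
    # toward -24 where real BTZ crosslinks cluster.
    deposition_offsets: tuple[int, ...] = (-24, -23, -22, -21, -20)
    deposition_weights: tuple[float, ...] = (0.35, 0.25, 0.18, 0.12, 0.10)
    deposit_fraction: float = 1.0     # fraction of junctions that carry an EJC
    depleted_fraction: float = 0.15   # genes flagged TOP-like/ribosomal-like
    depleted_multiplier: float = 0.1  # EJC deposition multiplier for those genes
    noise_fraction: float = 0.2       # uniform background share of events
    n_events: int = 30_000            # unique crosslink molecules per library
    n_rnaseq_reads: int = 200_000
    duplication_rate: float = 0.35    # geometric PCR copy model
    umi_length: int = 8
    proteins: dict[str, ProteinModel] = field(default_factory=default_proteins)

    def __post_init__(self):
        for name in ("deposit_fraction", "depleted_fraction", "noise_fraction",
                     "duplication_rate", "site_motif_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.deposition_offsets) != len(self.deposition_weights):
            raise ValueError("deposition offsets/weights length mismatch")
        if self.exon_length[0] < -min(self.deposition_offsets) + 6:
            raise ValueError(
                "minimum exon length must exceed the deposition window span"
            )
        if self.intron_length[0] < len(self.donor_consensus) + self.pyrimidine_tract_length + 30:
            raise ValueError("introns too short for donor consensus + pyrimidine tract")


@dataclass
class EjcSite:
    gene_id: str
    chrom: str
    strand: str
    junction: int          # genomic coordinate of the first intronic base
    positions: tuple[int, ...]  # genomic deposition window (offsets -24..-20)
    weight: float          # expected intensity (abundance x depletion)
    has_site_motif: bool = False

    def window_interval(self) -> tuple[int, int]:
        return min(self.positions), max(self.positions) + 1


@dataclass
class PyrimidineTract:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    weight: float


@dataclass
class SimulatedTruth:
    ejc_sites: list[EjcSite]
    tracts: list[PyrimidineTract]
    gene_abundance: dict[str, float]
    gene_flags: dict[str, str]  # gene_id -> "", "top_like", "ribo_like"
    transcript_abundance: dict[str, float]
    transcribed_spans: list[tuple[str, str, int, int]]  # gene spans

    def window_set(self) -> set[tuple[str, str, int]]:
        out = set()
        for s in self.ejc_sites:
            for p in s.positions:
                out.add((s.chrom, s.strand, p))
        return out


# ---------------------------------------------------------------------------
# Genome + annotation generation
# ---------------------------------------------------------------------------

def _draw_len(rng, lohi) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _gene_structure(rng, cfg: SimulationConfig, kind: str):
    """Local (gene-relative, genomic-order) exon chains for 1-2 isoforms."""
    k_int = _draw_len(rng, cfg.n_internal_exons)
    n_ex = k_int + 2
    exon_lens = [_draw_len(rng, cfg.exon_length) for _ in range(n_ex)]
    intron_lens = [_draw_len(rng, cfg.intron_length) for _ in range(n_ex - 1)]
    exons = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_ex - 1:
            pos += intron_lens[i]
    gene_len = pos

    isoforms = [list(exons)]
    if kind != "none" and k_int >= 1:
        # genomic index of the internal exon to modify
        j = int(rng.integers(1, n_ex - 1))
        alt = list(exons)
        s, e = alt[j]
        delta = int(rng.integers(12, 26))
        if kind == "skip":
            alt.pop(j)
        elif kind == "alt_donor":
            alt[j] = (s, e + delta)  # donor moved into the intron (plus-sense)
        elif kind == "alt_acceptor":
            alt[j] = (s + delta, e)
        elif kind == "alt_both":
            alt[j] = (s + delta, e + delta)
        isoforms.append(alt)
    return isoforms, gene_len


def generate_genome_and_annotation(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], GenomeAnnotation, SimulatedTruth]:
    """Deterministic genome (FASTA dict), annotation, and ground truth."""
    rng = _stream(cfg.seed, "genome")

    # decide per-gene alternative-splicing kind
    kinds: list[str] = []
    if cfg.category_plan:
        for kind, count in sorted(cfg.category_plan.items()):
            if kind not in ("none", "skip", "alt_donor", "alt_acceptor", "alt_both"):
                raise ValueError(f"unknown isoform plan kind {kind!r}")
            kinds.extend([kind] * count)
        if len(kinds) > cfg.n_genes:
            raise ValueError("category_plan requests more genes than n_genes")
    names = list(cfg.variant_kind_weights)
    w = np.array([cfg.variant_kind_weights[k] for k in names], dtype=float)
    w /= w.sum()
    while len(kinds) < cfg.n_genes:
        kinds.append(names[int(rng.choice(len(names), p=w))])
    rng.shuffle(kinds)  # type: ignore[arg-type]

    chroms = ["chr1", "chr2"]
    cursors = {c: 0 for c in chroms}
    genes: list[Gene] = []
    placements = []  # (gene, isoforms(local), offset)

    def place(gene_id: str, biotype: str, kind: str, strand: str):
        isoforms, gene_len = _gene_structure(rng, cfg, kind)
        chrom = chroms[len(genes) % len(chroms)]
        offset = cursors[chrom] + _draw_len(rng, cfg.spacer_length)
        cursors[chrom] = offset + gene_len
        g = Gene(gene_id, chrom, strand, biotype)
        for i, iso in enumerate(isoforms):
            exons = [(s + offset, e + offset) for s, e in iso]
            t = Transcript(f"{gene_id}.t{i + 1}", gene_id, exons)
            if biotype == "protein_coding":
                # CDS span leaves a 5'UTR on the first and a 3'UTR on the
                # last exon (transcript orientation)
                u5 = _draw_len(rng, cfg.utr5_length)
                u3 = _draw_len(rng, cfg.utr3_length)
                if strand == "+":
                    cs = exons[0][0] + min(u5, exons[0][1] - exons[0][0] - 5)
                    ce = exons[-1][1] - min(u3, exons[-1][1] - exons[-1][0] - 5)
                else:
                    cs = exons[0][0] + min(u3, exons[0][1] - exons[0][0] - 5)
                    ce = exons[-1][1] - min(u5, exons[-1][1] - exons[-1][0] - 5)
                t.cds = (cs, ce)
            g.transcripts.append(t)
        genes.append(g)
        placements.append(g)

    for i, kind in enumerate(kinds):
        place(f"G{i + 1:04d}", "protein_coding", kind, "+" if rng.random() < 0.5 else "-")
    for i in range(cfg.n_ncrna_genes):
        place(f"NC{i + 1:03d}", "ncRNA", "none", "+" if rng.random() < 0.5 else "-")

    chrom_lengths = {c: cursors[c] + _draw_len(rng, cfg.spacer_length) for c in chroms}
    ann = GenomeAnnotation(genes, chrom_lengths)
    ann.validate()

    # random sequence, then plant motifs
    seqs = {
        c: rng.integers(0, 4, size=chrom_lengths[c]).astype(np.uint8)
        for c in chroms
    }
    code = {b: i for i, b in enumerate("ACGT")}

    # Planted sequences are queued and applied in ascending priority so the
    # donor consensus always survives overlaps with tracts or site motifs.
    plant_queue: list[tuple[int, str, int, str]] = []

    def plant(chrom: str, start: int, motif_plus: str, priority: int = 2):
        plant_queue.append((priority, chrom, start, motif_plus))

    n_ex_nt = 2  # donor consensus: last 2 exonic nt + first 5 intronic nt
    consensus = cfg.donor_consensus
    for chrom, strand, j, gene_id in ann.junctions():
        if strand == "+":
            plant(chrom, j - n_ex_nt, consensus)
        else:
            plant(chrom, j - (len(consensus) - n_ex_nt) + 1, revcomp(consensus))

    # per-gene flags and abundances
    mu, sigma = cfg.abundance_lognormal
    gene_flags: dict[str, str] = {}
    tx_abundance: dict[str, float] = {}
    gene_abundance: dict[str, float] = {}
    coding = [g for g in genes if g.biotype == "protein_coding"]
    n_depleted = int(round(cfg.depleted_fraction * len(coding)))
    depleted_idx = set(
        rng.choice(len(coding), size=n_depleted, replace=False).tolist()
    ) if n_depleted else set()
    for i, g in enumerate(genes):
        flag = ""
        if g.biotype == "protein_coding":
            ci = coding.index(g)
            if ci in depleted_idx:
                flag = "top_like" if ci % 2 == 0 else "ribo_like"
        gene_flags[g.gene_id] = flag
        total = 0.0
        for t in g.transcripts:
            a = float(rng.lognormal(mu, sigma))
            tx_abundance[t.transcript_id] = a
            total += a
        gene_abundance[g.gene_id] = total

    # EJC deposition truth on protein-coding junction-bearing exon ends
    ejc_sites: list[EjcSite] = []
    coding_ids = {g.gene_id for g in coding}
    junction_tx_weight: dict[tuple[str, str, int], float] = {}
    junction_gene: dict[tuple[str, str, int], str] = {}
    for g in coding:
        for t in g.transcripts:
            exons = t.sorted_exons()
            donors = (
                [e for _, e in exons[:-1]] if g.strand == "+" else [s - 1 for s, _ in exons[1:]]
            )
            for j in donors:
                key = (g.chrom, g.strand, j)
                junction_tx_weight[key] = junction_tx_weight.get(key, 0.0) + tx_abundance[t.transcript_id]
                junction_gene[key] = g.gene_id
    for key in sorted(junction_tx_weight):
        chrom, strand, j = key
        gid = junction_gene[key]
        if rng.random() >= cfg.deposit_fraction:
            continue
        mult = cfg.depleted_multiplier if gene_flags[gid] else 1.0
        positions = tuple(
            j + o if strand == "+" else j - o for o in cfg.deposition_offsets
        )
        has_motif = rng.random() < cfg.site_motif_fraction
        if has_motif and cfg.site_motif:
            # center the weak crosslink-site motif on the modal offset
            o0 = cfg.deposition_offsets[int(np.argmax(cfg.deposition_weights))]
            m = len(cfg.site_motif)
            half = m // 2
            if strand == "+":
                plant(chrom, j + o0 - half, cfg.site_motif, priority=1)
            else:
                center = j - o0
                plant(chrom, center - (m - 1 - half), revcomp(cfg.site_motif), priority=1)
        ejc_sites.append(
            EjcSite(gid, chrom, strand, j, positions, junction_tx_weight[key] * mult, has_motif)
        )

    # intronic pyrimidine tracts (PTB targets), one per first-isoform intron
    tracts: list[PyrimidineTract] = []
    py = np.array([code["C"], code["T"]], dtype=np.uint8)
    for g in coding:
        t = g.transcripts[0]
        exons = t.sorted_exons()
        for (s1, e1), (s2, _) in zip(exons[:-1], exons[1:]):
            ilo, ihi = e1, s2
            margin = len(consensus) + 10
            lo = ilo + margin
            hi = ihi - margin - cfg.pyrimidine_tract_length
            if hi <= lo:
                continue
            ts = int(rng.integers(lo, hi))
            te = ts + cfg.pyrimidine_tract_length
            tract_seq = "".join("CT"[int(b)] for b in rng.integers(0, 2, size=te - ts))
            plant(g.chrom, ts, tract_seq, priority=0)
            tracts.append(
                PyrimidineTract(g.gene_id, g.chrom, g.strand, ts, te, gene_abundance[g.gene_id])
            )

    for _, chrom, start, motif_plus in sorted(plant_queue, key=lambda t: t[0]):
        arr = np.array([code[b] for b in motif_plus], dtype=np.uint8)
        seqs[chrom][start: start + len(arr)] = arr
    genome = {c: "".join(BASES[s]) for c, s in seqs.items()}
    spans = [(g.chrom, g.strand, *g.span) for g in genes]
    truth = SimulatedTruth(
        ejc_sites, tracts, gene_abundance, gene_flags, tx_abundance, spans
    )
    return genome, ann, truth


# ---------------------------------------------------------------------------
# iCLIP library simulation
# ---------------------------------------------------------------------------

def _uniform_span_draw(rng, spans, total_len, cum):
    r = int(rng.integers(0, total_len))
    k = int(np.searchsorted(cum, r, side="right") - 1)
    chrom, strand, s, e = spans[k]
    return chrom, s + (r - int(cum[k])), strand


def simulate_iclip(
    cfg: SimulationConfig, ann: GenomeAnnotation, truth: SimulatedTruth, protein: str
) -> pd.DataFrame:
    """Raw crosslink BED6 (start = crosslink nucleotide, name = 'readid:UMI').

    ``cfg.n_events`` unique molecules are drawn, each PCR-amplified with a
    geometric copy number (rate ``cfg.duplication_rate``); duplicates share
    the molecule's UMI. Row order is shuffled.
    """
    if protein not in cfg.proteins:
        raise ValueError(f"unknown protein {protein!r}; configure it in cfg.proteins")
    model = cfg.proteins[protein]
    rng = _stream(cfg.seed, f"iclip:{protein}")

    spans = truth.transcribed_spans
    span_lens = np.array([e - s for _, _, s, e in spans], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(span_lens)))
    total_len = int(cum[-1])

    events: list[tuple[str, int, str]] = []
    n = cfg.n_events
    if model.kind == "uniform":
        for _ in range(n):
            events.append(_uniform_span_draw(rng, spans, total_len, cum))
    elif model.kind == "ptb":
        tw = np.array([t.weight for t in truth.tracts], dtype=float)
        tw /= tw.sum()
        for _ in range(n):
            if rng.random() < cfg.noise_fraction:
                events.append(_uniform_span_draw(rng, spans, total_len, cum))
                continue
            tr = truth.tracts[int(rng.choice(len(truth.tracts), p=tw))]
            pos = int(rng.integers(tr.start, tr.end))
            events.append((tr.chrom, pos, tr.strand))
    else:  # ejc
        sites = truth.ejc_sites
        sw = np.array([s.weight for s in sites], dtype=float)
        sw /= sw.sum()
        offw = np.array(cfg.deposition_weights, dtype=float)
        offw /= offw.sum()
        # optional non-EJC extra sites: one 5'-biased exonic position per gene
        extra_pos: dict[str, tuple[str, str, int]] = {}
        extra_ids: list[str] = []
        extra_w = None
        if model.non_ejc_fraction > 0:
            for g in ann.protein_coding_genes():
                t = g.transcripts[0]
                exons = t.sorted_exons()
                tx_order = exons if g.strand == "+" else exons[::-1]
                spliced = [(s, e) for s, e in tx_order]
                total = sum(e - s for s, e in spliced)
                r = int(rng.integers(0, max(1, total // 3)))  # 5'-third bias
                for s, e in spliced:
                    step = e - s
                    if r < step:
                        pos = (s + r) if g.strand == "+" else (e - 1 - r)
                        extra_pos[g.gene_id] = (g.chrom, pos, g.strand)
                        break
                    r -= step
                extra_ids.append(g.gene_id)
            extra_w = np.array(
                [truth.gene_abundance[gid] for gid in extra_ids], dtype=float
            )
            extra_w /= extra_w.sum()
        for _ in range(n):
            if rng.random() < cfg.noise_fraction:
                events.append(_uniform_span_draw(rng, spans, total_len, cum))
                continue
            if extra_w is not None and rng.random() < model.non_ejc_fraction:
                gid = extra_ids[int(rng.choice(len(extra_ids), p=extra_w))]
                events.append(extra_pos[gid])
                continue
            site = sites[int(rng.choice(len(sites), p=sw))]
            pos = site.positions[int(rng.choice(len(site.positions), p=offw))]
            events.append((site.chrom, pos, site.strand))

    # UMIs and PCR duplication
    umis = [
        "".join(BASES[rng.integers(0, 4, size=cfg.umi_length)]) for _ in range(n)
    ]
    if cfg.duplication_rate > 0:
        copies = rng.geometric(1.0 - cfg.duplication_rate, size=n)
    else:
        copies = np.ones(n, dtype=np.int64)

    rows = []
    rid = 0
    for (chrom, pos, strand), umi, k in zip(events, umis, copies):
        for _ in range(int(k)):
            rows.append((chrom, pos, pos + 1, f"r{rid:07d}:{umi}", 0, strand))
            rid += 1
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def simulate_rnaseq(cfg: SimulationConfig, ann: GenomeAnnotation, truth: SimulatedTruth):
    """Per-position strand-specific read counts, exonic and abundance-
    proportional with Poisson noise; introns stay at zero.

    Returned as a :class:`~ejckit.crosslinks.CrosslinkTrack` (library id
    "RNAseq") so RPM and per-exon read counting reuse the track machinery.
    """
    from .crosslinks import CrosslinkTrack

    rng = _stream(cfg.seed, "rnaseq")
    depth: dict[tuple[str, str], np.ndarray] = {}
    for chrom, length in ann.chrom_lengths.items():
        for strand in "+-":
            depth[(chrom, strand)] = np.zeros(length, dtype=float)
    for g in ann.genes:
        for t in g.transcripts:
            a = truth.transcript_abundance[t.transcript_id]
            for s, e in t.exons:
                depth[(g.chrom, g.strand)][s:e] += a
    total = sum(d.sum() for d in depth.values())
    if total == 0:
        return CrosslinkTrack("RNAseq", {})
    scale = cfg.n_rnaseq_reads / total
    data = {}
    for key, d in depth.items():
        counts = rng.poisson(d * scale)
        nz = np.nonzero(counts)[0]
        if len(nz):
            data[key] = (nz.astype(np.int64), counts[nz].astype(np.int64))
    return CrosslinkTrack("RNAseq", data)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(path, rebuild=True, build_index=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
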