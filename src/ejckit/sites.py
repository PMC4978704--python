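"""High-confidence EJC deposition sites, BTZ marking, and exon filters.

Peaks from different EJC proteins that overlap by at least 1 nt merge
transitively into a single site; sites supported by fewer than two distinct
proteins are dropped and sites overlapping any GFP background peak are
removed. On top of the merged sites this module quantifies BTZ marking,
searches for non-annotated candidate exons (unannotated BTZ peaks with a
confirming second protein and a nearby splice-donor motif), and applies the
per-exon RPM and read-count filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import ExonCatalog, GenomeAnnotation
from .crosslinks import CrosslinkTrack, rpm
from .peakcalling import Peak, PeakSet, PipelineParams
from .simulate import revcomp

logger = logging.getLogger(__name__)


@dataclass
class HighConfSite:
    chrom: str
    strand: str
    start: int
    end: int
    supporters: frozenset[str]
    counts: dict[str, int] = field(default_factory=dict)  # per-protein unique events
    gfp_count: int = 0
    summit: int | None = None

    @property
    def contains_btz(self) -> bool:
        return "BTZ" in self.supporters

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class CandidateExonCall:
    chrom: str
    strand: str
    start: int
    end: int
    btz_rpm: float
    second_protein: str
    motif: str
    motif_offset: int  # nt downstream of the site end (transcript sense)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_high_confidence(
    peaksets: Mapping[str, PeakSet],
    gfp_peaks: PeakSet | None = None,
    tracks: Mapping[str, CrosslinkTrack] | None = None,
    gfp_track: CrosslinkTrack | None = None,
    btz_name: str = "BTZ",
) -> list[HighConfSite]:
    """Merge per-protein peaks into >= 2-protein sites, GFP-filtered.

    All peaks are merged transitively wherever they overlap by >= 1 nt;
    merged clusters supported by a single protein are discarded. When
    ``tracks`` are provided each site records per-protein unique event
    counts and a summit (position of maximum pooled supporter count, ties
    toward the 5'-most position in transcript orientation).
    """
    if len(peaksets) < 2:
        raise ValueError(">=2 proteins required for high-confidence merging")

    tagged: list[tuple[str, str, int, int, str]] = []
    for protein, ps in peaksets.items():
        for p in ps:
            tagged.append((p.chrom, p.strand, p.start, p.end, protein))
    tagged.sort()

    sites: list[HighConfSite] = []
    i = 0
    while i < len(tagged):
        chrom, strand, start, end, protein = tagged[i]
        supporters = {protein}
        j = i + 1
        while j < len(tagged):
            c2, s2, st2, en2, pr2 = tagged[j]
            if (c2, s2) != (chrom, strand) or st2 >= end:
                break
            end = max(end, en2)
            supporters.add(pr2)
            j += 1
        if len(supporters) >= 2:
            sites.append(HighConfSite(chrom, strand, start, end, frozenset(supporters)))
        i = j

    if gfp_peaks is not None:
        gfp_trees: dict[tuple[str, str], IntervalTree] = {}
        for p in gfp_peaks:
            gfp_trees.setdefault((p.chrom, p.strand), IntervalTree()).addi(p.start, p.end)
        kept = [
            s for s in sites
            if not gfp_trees.get((s.chrom, s.strand), IntervalTree())[s.start: s.end]
        ]
        removed = len(sites) - len(kept)
        if removed:
            logger.info("GFP filter removed %d of %d candidate sites", removed, len(sites))
        sites = kept

    if tracks is not None:
        for s in sites:
            pooled = np.zeros(s.end - s.start, dtype=np.int64)
            for protein in sorted(s.supporters):
                tr = tracks.get(protein)
                if tr is None:
                    continue
                arr = tr.array(s.chrom, s.strand, s.start, s.end)
                s.counts[protein] = int(arr.sum())
                pooled += arr
            if pooled.sum() > 0:
                best = pooled.max()
                cand = np.nonzero(pooled == best)[0]
                rel = cand.min() if s.strand == "+" else cand.max()
                s.summit = s.start + int(rel)
            if gfp_track is not None:
                s.gfp_count = gfp_track.count_in(s.chrom, s.strand, s.start, s.end)
    return sites


def btz_marking_stats(sites: Iterable[HighConfSite], btz_name: str = "BTZ"):
    """(n_sites, n_with_btz, fraction) of sites supported by BTZ."""
    sites = list(sites)
    if not sites:
        raise ValueError("no high-confidence sites")
    n_btz = sum(1 for s in sites if btz_name in s.supporters)
    return len(sites), n_btz, n_btz / len(sites)


def non_btz_site_profile(
    sites: Iterable[HighConfSite],
    tracks: Mapping[str, CrosslinkTrack],
    exons: ExonCatalog,
    params: PipelineParams,
    btz_name: str = "BTZ",
):
    """Exon metaprofile of non-BTZ co-peak signal.

    Pools the supporting proteins' events inside sites that lack BTZ
    support and profiles them across the exon catalog (relative length).
    Returns (bin_centers, mean_profile_rpm, n_sites_used).
    """
    from collections import Counter

    from .profiles import exon_metaprofile

    counter: Counter = Counter()
    used = 0
    total_events = 0
    for s in sites:
        if btz_name in s.supporters:
            continue
        used += 1
        for protein in sorted(s.supporters):
            tr = tracks.get(protein)
            if tr is None:
                continue
            pos, cnt = tr.positions(s.chrom, s.strand)
            i, j = np.searchsorted(pos, [s.start, s.end])
            for p, n in zip(pos[i:j], cnt[i:j]):
                counter[(s.chrom, s.strand, int(p))] += int(n)
                total_events += int(n)
    masked = CrosslinkTrack.from_counter("non_btz", counter)
    if masked.total_unique == 0:
        nb = params.n_profile_bins
        return np.arange(nb), np.zeros(nb), used
    centers, prof = exon_metaprofile(masked, exons, params)
    return centers, prof, used


# ---------------------------------------------------------------------------
# Candidate exons
# ---------------------------------------------------------------------------

def _exon_trees(ann: GenomeAnnotation) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in ann.genes:
        for t in g.transcripts:
            for s, e in t.exons:
                trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(s, e)
    return trees


def _downstream_motif(genome: dict[str, str], chrom: str, strand: str,
                      start: int, end: int, motifs, proximity: int):
    """First donor-motif match starting within ``proximity`` nt downstream
    (transcript orientation) of the interval end; (motif, offset) or None."""
    m = max(len(x) for x in motifs)
    if strand == "+":
        seq = genome[chrom][end: end + proximity + m]
    else:
        lo = max(0, start - proximity - m)
        # contig-edge truncation shortens the far (3') end only
        seq = revcomp(genome[chrom][lo: start])
    best = None
    for motif in motifs:
        idx = seq.find(motif)  # nearest match decides
        if idx != -1 and idx <= proximity and (best is None or idx < best[1]):
            best = (motif, idx)
    return best


def find_candidate_exons(
    btz_track: CrosslinkTrack,
    btz_peaks: PeakSet,
    other_peaksets: Mapping[str, PeakSet],
    ann: GenomeAnnotation,
    genome: dict[str, str],
    params: PipelineParams,
) -> list[CandidateExonCall]:
    """Non-annotated exons: unannotated BTZ peaks with RPM above threshold,
    a confirming overlapping peak from another EJC protein, and a splice
    donor motif (AGGTAAG/AGGTGAG) starting within ``candidate_proximity``
    nt downstream of the peak end."""
    exon_trees = _exon_trees(ann)
    other_trees: dict[tuple[str, str], IntervalTree] = {}
    for protein, ps in other_peaksets.items():
        for p in ps:
            other_trees.setdefault((p.chrom, p.strand), IntervalTree()).addi(
                p.start, p.end, protein
            )

    calls: list[CandidateExonCall] = []
    for p in btz_peaks:
        key = (p.chrom, p.strand)
        if exon_trees.get(key, IntervalTree())[p.start: p.end]:
            continue  # condition 1: must not map to an annotated exon
        signal = rpm(btz_track, (p.chrom, p.strand, p.start, p.end))
        if signal <= params.candidate_btz_rpm:
            continue
        confirm = sorted(
            {iv.data for iv in other_trees.get(key, IntervalTree())[p.start: p.end]}
        )
        if not confirm:
            continue
        hit = _downstream_motif(
            genome, p.chrom, p.strand, p.start, p.end,
            params.candidate_motifs, params.candidate_proximity,
        )
        if hit is None:
            continue
        motif, offset = hit
        calls.append(
            CandidateExonCall(p.chrom, p.strand, p.start, p.end,
                              signal, confirm[0], motif, offset)
        )
    return calls


# ---------------------------------------------------------------------------
# Exon-level filters
# ---------------------------------------------------------------------------

def table1_filter(
    exons: ExonCatalog,
    btz_track: CrosslinkTrack,
    other_tracks: Mapping[str, CrosslinkTrack],
    rnaseq_track: CrosslinkTrack,
    params: PipelineParams,
) -> pd.DataFrame:
    """Per-category counts of exons with BTZ and one other EJC protein
    above ``table1_rpm`` while RNA-seq stays strictly below
    ``table1_rnaseq_rpm`` (lowly transcribed but EJC-bound exons)."""
    from .annotation import EXON_CATEGORIES

    per_cat = {c: [0, 0] for c in EXON_CATEGORIES}  # [total, passing]
    for x in exons:
        iv = (x.chrom, x.strand, x.start, x.end)
        per_cat[x.category][0] += 1
        if rpm(btz_track, iv) <= params.table1_rpm:
            continue
        if not any(rpm(tr, iv) > params.table1_rpm for tr in other_tracks.values()):
            continue
        if rpm(rnaseq_track, iv) >= params.table1_rnaseq_rpm:
            continue
        per_cat[x.category][1] += 1
    rows = [
        (cat, tot, hits, 100.0 * hits / tot if tot else 0.0)
        for cat, (tot, hits) in per_cat.items()
    ]
    return pd.DataFrame(rows, columns=["category", "n_exons", "n_pass", "pct"])


def expressed_and_marked_exons(
    exons: ExonCatalog,
    rnaseq_track: CrosslinkTrack,
    btz_track: CrosslinkTrack,
    params: PipelineParams,
    categories: tuple[str, ...] | None = None,
) -> tuple[int, int]:
    """(n_expressed, n_ejc_positive) exon counts.

    Expressed: raw RNA-seq reads >= ``expressed_exon_reads`` in the exon.
    EJC-positive: expressed and BTZ unique events >= ``ejc_positive_reads``.
    """
    n_expr = n_pos = 0
    for x in exons:
        if categories is not None and x.category not in categories:
            continue
        reads = rnaseq_track.count_in(x.chrom, x.strand, x.start, x.end)
        if reads < params.expressed_exon_reads:
            continue
        n_expr += 1
        if btz_track.count_in(x.chrom, x.strand, x.start, x.end) >= params.ejc_positive_reads:
            n_pos += 1
    return n_expr, n_pos


def sites_to_frame(sites: Iterable[HighConfSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.chrom, s.start, s.end, ",".join(sorted(s.supporters)),
             len(s.supporters), s.strand, s.summit, s.contains_btz, s.gfp_count)
            for s in sites
        ],
        columns=["chrom", "start", "end", "supporters", "n_supporters",
                 "strand", "summit", "contains_btz", "gfp_count"],
    )
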