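"""Exon- and junction-anchored coverage profiles.

Exons are rescaled to a relative length of 100% over ``n_profile_bins``
bins; events map to bin floor(offset * n_bins / length) so binned counts
are conserved exactly. Matrices are RPM-scaled per library; metaprofiles
average rows; the junction metaplot anchors at exon 3' ends in transcript
orientation, where canonical EJC deposition clusters at -24..-20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import ExonCatalog, ExonRecord, RegionMap, junction_offset
from .crosslinks import CrosslinkTrack
from .peakcalling import PeakSet, PipelineParams


@dataclass
class ExonMatrix:
    """Exons x relative-position bins, one matrix per signal.

    Rows are ordered by absolute exon length (ascending); ``raw`` holds
    conserved event counts and ``values`` the RPM-scaled version.
    """

    exons: list[ExonRecord]
    raw: np.ndarray
    values: np.ndarray
    library_id: str


def _binned_counts(track: CrosslinkTrack, exon: ExonRecord, n_bins: int) -> np.ndarray:
    out = np.zeros(n_bins, dtype=np.int64)
    pos, cnt = track.positions(exon.chrom, exon.strand)
    i, j = np.searchsorted(pos, [exon.start, exon.end])
    if i == j:
        return out
    p = pos[i:j]
    offs = p - exon.start if exon.strand == "+" else exon.end - 1 - p
    bins = (offs * n_bins) // exon.length
    np.add.at(out, bins, cnt[i:j])
    return out


def exon_matrix(
    track: CrosslinkTrack, exons: ExonCatalog | list[ExonRecord],
    params: PipelineParams, order: list[int] | None = None,
) -> ExonMatrix:
    """Relative-length binned coverage matrix for one signal.

    ``order`` overrides the default length ordering so parallel matrices
    for different signals can share identical row order.
    """
    xs = list(exons)
    if order is None:
        order = sorted(range(len(xs)), key=lambda i: (xs[i].length, xs[i].chrom, xs[i].start))
    xs = [xs[i] for i in order]
    raw = np.stack([_binned_counts(track, x, params.n_profile_bins) for x in xs]) \
        if xs else np.zeros((0, params.n_profile_bins), dtype=np.int64)
    scale = 1e6 / track.total_unique if track.total_unique else 0.0
    return ExonMatrix(xs, raw, raw * scale, track.library_id)


def exon_metaprofile(
    track: CrosslinkTrack, exons: ExonCatalog | list[ExonRecord], params: PipelineParams
):
    """Mean RPM-scaled binned profile over an exon set -> (bins, profile)."""
    mat = exon_matrix(track, exons, params)
    nb = params.n_profile_bins
    if mat.values.shape[0] == 0:
        return np.arange(nb), np.zeros(nb)
    return np.arange(nb), mat.values.mean(axis=0)


def junction_metaplot(
    track: CrosslinkTrack,
    junctions,
    offsets: tuple[int, int] = (-50, 10),
):
    """Mean RPM per signed offset from exon 3' ends (transcript sense).

    ``junctions`` is an iterable of (chrom, strand, j, ...) tuples where j
    is the first intronic base; offset -1 is the last exonic nucleotide.
    Returns (offset_array, mean_rpm).
    """
    lo, hi = offsets
    offs = np.arange(lo, hi + 1)
    total = np.zeros(len(offs), dtype=float)
    n = 0
    for jrec in junctions:
        chrom, strand, j = jrec[0], jrec[1], jrec[2]
        n += 1
        for k, o in enumerate(offs):
            p = j + o if strand == "+" else j - o
            total[k] += track.count_in(chrom, strand, p, p + 1)
    if n == 0 or track.total_unique == 0:
        return offs, np.zeros(len(offs))
    return offs, total * 1e6 / (track.total_unique * n)


def rank_exons_by_difference(
    iclip: ExonMatrix, rnaseq: ExonMatrix
) -> pd.DataFrame:
    """Order exons by (normalized RNA-seq - normalized iCLIP) mean signal.

    Each matrix is normalized by its own global mean so the two signals are
    comparable; the returned frame keeps the matrices' shared row order and
    adds ``rank`` (0 = largest difference, i.e. most RNA-seq-dominated) and
    a 4-way ``category``: 1 abundant/weak-iCLIP, 2 expressed-with-EJC,
    3 not-expressed/no-EJC, 4 weakly-expressed/EJC-enriched, from the 2x2
    of above/below the median among expressed exons.
    """
    if [x.length for x in iclip.exons] != [x.length for x in rnaseq.exons]:
        raise ValueError("matrices must share identical row order")
    r = rnaseq.values.mean(axis=1)
    i = iclip.values.mean(axis=1)
    rn = r / r.mean() if r.size and r.mean() > 0 else r
    iq = i / i.mean() if i.size and i.mean() > 0 else i
    diff = rn - iq
    expressed = r > 0
    med_r = np.median(rn[expressed]) if expressed.any() else 0.0
    med_i = np.median(iq[expressed]) if expressed.any() else 0.0
    # an exon exactly at the iCLIP median counts as weak-signal, so ties do
    # not inflate the EJC-positive categories
    hi_r, hi_i = rn >= med_r, iq > med_i
    category = np.select(
        [hi_r & ~hi_i, hi_r & hi_i, ~hi_r & ~hi_i, ~hi_r & hi_i], [1, 2, 3, 4]
    )
    order = np.argsort(-diff, kind="stable")
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(len(order))
    return pd.DataFrame(
        {
            "gene_id": [x.gene_id for x in iclip.exons],
            "chrom": [x.chrom for x in iclip.exons],
            "start": [x.start for x in iclip.exons],
            "end": [x.end for x in iclip.exons],
            "exon_category": [x.category for x in iclip.exons],
            "diff": diff,
            "rank": rank,
            "category": category,
            "expressed": expressed,
        }
    )


def log2_fold_difference(
    iclip: ExonMatrix, rnaseq: ExonMatrix, n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-exon log2((max iCLIP bin + 0.5) / (max RNA-seq bin + 0.5)) on
    RPM-scaled bins, plus per-exon-category medians with bootstrap CIs.

    Returns (per_exon, per_category) frames.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    mi = iclip.values.max(axis=1) if len(iclip.exons) else np.zeros(0)
    mr = rnaseq.values.max(axis=1) if len(rnaseq.exons) else np.zeros(0)
    lfd = np.log2((mi + 0.5) / (mr + 0.5))
    per_exon = pd.DataFrame(
        {
            "gene_id": [x.gene_id for x in iclip.exons],
            "start": [x.start for x in iclip.exons],
            "end": [x.end for x in iclip.exons],
            "category": [x.category for x in iclip.exons],
            "log2fd": lfd,
        }
    )
    rows = []
    for cat, sub in per_exon.groupby("category"):
        vals = sub["log2fd"].to_numpy()
        med = float(np.median(vals))
        if len(vals) > 1:
            boots = np.median(
                vals[rng.integers(0, len(vals), size=(n_boot, len(vals)))], axis=1
            )
            lo, hi = np.quantile(boots, [0.025, 0.975])
        else:
            lo = hi = med
        rows.append((cat, len(vals), med, float(lo), float(hi)))
    per_cat = pd.DataFrame(
        rows, columns=["category", "n", "median_log2fd", "ci_lo", "ci_hi"]
    )
    return per_exon, per_cat


def region_distribution(peaks: PeakSet, region_map: RegionMap) -> pd.DataFrame:
    """Percent of peaks per region (by summit) and peaks-per-nt enrichment.

    Percentages sum to 100; the enrichment factor divides the peak count by
    the region's cumulative length.
    """
    from .annotation import REGION_LABELS

    counts = {lab: 0 for lab in REGION_LABELS}
    for p in peaks:
        counts[region_map.label_at(p.chrom, p.strand, p.summit)] += 1
    total = sum(counts.values())
    lengths = region_map.cumulative_lengths()
    rows = []
    for lab in REGION_LABELS:
        pct = 100.0 * counts[lab] / total if total else 0.0
        enr = counts[lab] / lengths[lab] if lengths[lab] else float("nan")
        rows.append((lab, counts[lab], pct, lengths[lab], enr))
    return pd.DataFrame(
        rows, columns=["region", "n_peaks", "pct", "cumulative_length", "enrichment"]
    )
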