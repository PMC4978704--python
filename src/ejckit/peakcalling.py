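"""Permutation peak calling on crosslink tracks.

Within each gene segment, every occupied position gets a flank score (sum of
events within +/- flank nt). The null re-places the segment's events
independently and uniformly over segment positions; the FDR of a score s is
the permutation-expected number of occupied positions scoring >= s divided
by the observed number. Positions with FDR strictly below the threshold are
significant and are clustered into peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class PipelineParams:
    """Tunable analysis parameters (defaults follow the published workflow)."""

    flank: int = 15                 # nt, peak-score half-window
    n_perm: int = 100               # permutations / shuffles for nulls
    fdr_threshold: float = 0.05     # strict '<' comparison
    kmer_window: int = 40           # nt, 5mer counting half-window
    kmer_norm_window: int = 100     # nt, normalization half-window
    top_k_motifs: int = 20
    candidate_btz_rpm: float = 2.0
    candidate_motifs: tuple[str, ...] = ("AGGTAAG", "AGGTGAG")
    candidate_proximity: int = 25   # nt downstream of the site end
    table1_rpm: float = 1.0
    table1_rnaseq_rpm: float = 0.5
    expressed_exon_reads: int = 10
    ejc_positive_reads: int = 10
    strong_binding_log2fc: float = 3.0
    adj_p_threshold: float = 0.05
    top_cpm_cutoff: float = 40.0
    n_profile_bins: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for name in ("fdr_threshold", "candidate_btz_rpm", "table1_rpm",
                     "table1_rnaseq_rpm", "adj_p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Peak:
    chrom: str
    strand: str
    start: int
    end: int          # half-open
    summit: int
    score: int        # flank score at the summit
    fdr: float
    protein: str = ""
    event_count: int = 0  # unique events inside [start, end)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


class PeakSet:
    def __init__(self, peaks: Iterable[Peak], protein: str = "", params: PipelineParams | None = None):
        self.peaks = sorted(peaks, key=lambda p: (p.chrom, p.strand, p.start))
        self.protein = protein
        self.params = params

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.chrom, p.start, p.end, self.protein or p.protein,
                 p.event_count, p.strand, p.summit, p.score, p.fdr)
                for p in self.peaks
            ],
            columns=["chrom", "start", "end", "name", "score", "strand",
                     "summit", "flank_score", "fdr"],
        )


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _window_sums(counts: np.ndarray, flank: int) -> np.ndarray:
    """Sliding sum of counts over +/- flank, clipped to the segment."""
    c = np.concatenate(([0], np.cumsum(counts)))
    n = len(counts)
    idx = np.arange(n)
    lo = np.clip(idx - flank, 0, n)
    hi = np.clip(idx + flank + 1, 0, n)
    return c[hi] - c[lo]


def score_positions(
    track, segment: tuple[str, str, int, int], flank: int
) -> dict[int, int]:
    """Flank score for every occupied position of one gene segment."""
    chrom, strand, start, end = segment
    if end <= start:
        return {}
    counts = track.array(chrom, strand, start, end)
    occupied = np.nonzero(counts)[0]
    if len(occupied) == 0:
        return {}
    scores = _window_sums(counts, flank)
    return {int(start + i): int(scores[i]) for i in occupied}


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

def permutation_fdr(
    track, segment: tuple[str, str, int, int], params: PipelineParams,
    rng: np.random.Generator | None = None,
) -> dict[int, float]:
    """FDR per occupied position of one segment.

    For each permutation the segment's total unique events are re-placed
    independently and uniformly over segment positions (each permutation
    consumes one ``rng.integers(0, L, size=n)`` draw). FDR(s) = min(1,
    mean permuted #positions with score >= s / observed #positions with
    score >= s); each position inherits the FDR of its score.
    """
    chrom, strand, start, end = segment
    L = end - start
    if L <= 0:
        return {}
    counts = track.array(chrom, strand, start, end)
    n_events = int(counts.sum())
    if n_events == 0:
        return {}
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)

    scores = _window_sums(counts, params.flank)
    occupied = np.nonzero(counts)[0]
    obs_scores = scores[occupied]
    distinct = np.unique(obs_scores)
    max_s = int(distinct[-1])

    # permuted-score histogram over all permutations
    null_hist = np.zeros(max_s + 2, dtype=np.int64)  # last bin: >= max_s+1 clip
    for _ in range(params.n_perm):
        placed = rng.integers(0, L, size=n_events)
        pc = np.bincount(placed, minlength=L)
        ps = _window_sums(pc, params.flank)
        pocc = np.nonzero(pc)[0]
        vals = np.minimum(ps[pocc], max_s + 1)
        null_hist += np.bincount(vals, minlength=max_s + 2)

    # tail counts: permuted positions with score >= s, for each distinct s
    null_tail = np.cumsum(null_hist[::-1])[::-1]  # null_tail[s] = #null >= s
    fdr_of: dict[int, float] = {}
    for s in distinct:
        obs_ge = int((obs_scores >= s).sum())
        perm_ge = null_tail[int(s)] / params.n_perm
        fdr_of[int(s)] = min(1.0, perm_ge / obs_ge)
    return {int(start + i): fdr_of[int(scores[i])] for i in occupied}


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_peaks(
    positions: Sequence[int],
    track,
    segment: tuple[str, str, int, int],
    params: PipelineParams,
    fdrs: dict[int, float] | None = None,
    protein: str = "",
) -> list[Peak]:
    """Merge significant positions within <= flank nt into peaks.

    The summit is the member position with the highest event count, ties
    broken toward the 5'-most position in transcript orientation; the peak
    interval is [min, max + 1) of member positions.
    """
    chrom, strand, start, end = segment
    if not positions:
        return []
    pos = sorted(positions)
    clusters: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= params.flank:
            clusters[-1].append(p)
        else:
            clusters.append([p])

    scores = score_positions(track, segment, params.flank)
    peaks = []
    for members in clusters:
        counts = {p: track.count_in(chrom, strand, p, p + 1) for p in members}
        best = max(counts.values())
        candidates = [p for p in members if counts[p] == best]
        summit = min(candidates) if strand == "+" else max(candidates)
        lo, hi = members[0], members[-1] + 1
        peaks.append(
            Peak(
                chrom, strand, lo, hi, summit,
                score=scores.get(summit, 0),
                fdr=(fdrs or {}).get(summit, float("nan")),
                protein=protein,
                event_count=int(track.count_in(chrom, strand, lo, hi)),
            )
        )
    return peaks


def peak_midpoint(peak: Peak) -> int:
    """Motif anchor: floor((start + end - 1) / 2)."""
    return (peak.start + peak.end - 1) // 2


# ---------------------------------------------------------------------------
# Whole-annotation driver
# ---------------------------------------------------------------------------

def call_peaks(
    track, ann, params: PipelineParams, protein: str = "",
    rng: np.random.Generator | None = None,
) -> PeakSet:
    """Run score/permutation/cluster over every gene segment of ``ann``.

    Intergenic events are not peak-called (segments are gene spans). One RNG
    stream drives all segments in gene order, so results are deterministic
    for a given (track, annotation, seed).
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    peaks: list[Peak] = []
    for gene_id, chrom, strand, start, end in ann.gene_segments():
        segment = (chrom, strand, start, end)
        fdrs = permutation_fdr(track, segment, params, rng=rng)
        if not fdrs:
            continue
        significant = [p for p, f in fdrs.items() if f < params.fdr_threshold]
        peaks.extend(
            cluster_peaks(significant, track, segment, params, fdrs=fdrs, protein=protein)
        )
    return PeakSet(peaks, protein=protein, params=params)
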