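"""Positional 5mer enrichment around peak midpoints.

Every 5mer whose center lies within +/- ``kmer_window`` nt of a peak
midpoint is counted (strand-aware: minus-strand windows are
reverse-complemented, so all motifs are read on the transcribed strand).
The null re-draws each midpoint uniformly within its gene segment
``n_perm`` times; Z = (observed - null mean) / null SD. Positional
occurrence vectors span +/- ``kmer_norm_window`` nt and are normalized by
the 5mer's mean per-offset null count over that region. 5mers containing
"GT" form the junction-associated class; the rest mark the crosslink site
itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .peakcalling import PipelineParams, PeakSet, peak_midpoint
from .simulate import revcomp

K = 5
N_KMERS = 4 ** K
ALL_KMERS = ["".join(p) for p in product("ACGT", repeat=K)]
_KMER_INDEX = {k: i for i, k in enumerate(ALL_KMERS)}


def kmer_id(kmer: str) -> int:
    return _KMER_INDEX[kmer]


def is_gt(kmer: str) -> bool:
    return "GT" in kmer


class _Encoded:
    """Per-chromosome centered-5mer id arrays for both orientations."""

    def __init__(self, genome: dict[str, str]):
        self.kid = {}
        code = np.full(256, -1, dtype=np.int64)
        for i, b in enumerate("ACGT"):
            code[ord(b)] = i
        for chrom, seq in genome.items():
            c = code[np.frombuffer(seq.encode(), dtype=np.uint8)]
            n = len(c)
            if n < K:
                self.kid[(chrom, "+")] = np.full(0, -1)
                self.kid[(chrom, "-")] = np.full(0, -1)
                continue
            valid = np.ones(n - K + 1, dtype=bool)
            plus = np.zeros(n - K + 1, dtype=np.int64)
            minus = np.zeros(n - K + 1, dtype=np.int64)
            for k in range(K):
                ck = c[k: n - K + 1 + k]
                valid &= ck >= 0
                plus = plus * 4 + ck
                minus += np.where(ck >= 0, (3 - ck) * 4 ** k, 0)
            plus[~valid] = -1
            minus[~valid] = -1
            self.kid[(chrom, "+")] = plus
            self.kid[(chrom, "-")] = minus

    def centered_ids(self, chrom: str, strand: str, centers: np.ndarray,
                     offsets: np.ndarray) -> np.ndarray:
        """ids of 5mers centered at transcript-orientation offsets from
        each genomic center position; -1 where the window leaves the contig."""
        kid = self.kid[(chrom, strand)]
        if strand == "+":
            starts = centers[:, None] + offsets[None, :] - K // 2
        else:
            starts = centers[:, None] - offsets[None, :] - K // 2
        ok = (starts >= 0) & (starts < len(kid))
        ids = np.full(starts.shape, -1, dtype=np.int64)
        ids[ok] = kid[np.clip(starts, 0, max(0, len(kid) - 1))][ok]
        return ids


def _accumulate(posmat: np.ndarray, ids: np.ndarray, offsets_idx: np.ndarray):
    flat_ids = ids.ravel()
    flat_off = np.broadcast_to(offsets_idx, ids.shape).ravel()
    keep = flat_ids >= 0
    np.add.at(posmat, (flat_ids[keep], flat_off[keep]), 1)


@dataclass
class KmerCounts:
    observed: np.ndarray       # (1024,) centers within +/- kmer_window
    pos: np.ndarray            # (1024, 2*kmer_norm_window + 1) raw tallies
    offsets: np.ndarray        # center offsets, -norm..+norm
    n_peaks: int


def _midpoints_by_key(peaks: PeakSet) -> dict[tuple[str, str], np.ndarray]:
    grouped: dict[tuple[str, str], list[int]] = {}
    for p in peaks:
        grouped.setdefault((p.chrom, p.strand), []).append(peak_midpoint(p))
    return {k: np.asarray(v, dtype=np.int64) for k, v in grouped.items()}


def _count_at(enc: _Encoded, mids: dict[tuple[str, str], np.ndarray],
              params: PipelineParams) -> np.ndarray:
    W = params.kmer_norm_window
    offsets = np.arange(-W, W + 1)
    posmat = np.zeros((N_KMERS, len(offsets)), dtype=np.int64)
    oidx = np.arange(len(offsets))
    for (chrom, strand), centers in mids.items():
        ids = enc.centered_ids(chrom, strand, centers, offsets)
        _accumulate(posmat, ids, oidx)
    return posmat


def _observed_from_pos(posmat: np.ndarray, params: PipelineParams) -> np.ndarray:
    W, w = params.kmer_norm_window, params.kmer_window
    return posmat[:, W - w: W + w + 1].sum(axis=1)


def count_kmers(peaks: PeakSet, genome: dict[str, str], params: PipelineParams,
                _enc: _Encoded | None = None) -> KmerCounts:
    """Observed 5mer counts and positional vectors around peak midpoints."""
    enc = _enc or _Encoded(genome)
    mids = _midpoints_by_key(peaks)
    posmat = _count_at(enc, mids, params)
    W = params.kmer_norm_window
    return KmerCounts(
        observed=_observed_from_pos(posmat, params),
        pos=posmat,
        offsets=np.arange(-W, W + 1),
        n_peaks=len(peaks),
    )


def _segment_of_peaks(peaks: PeakSet, ann) -> dict[tuple[str, str], np.ndarray]:
    """(n_peaks, 2) segment bounds per (chrom, strand) group, matching the
    grouping order of :func:`_midpoints_by_key` (first containing gene)."""
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for _, chrom, strand, s, e in ann.gene_segments():
        spans.setdefault((chrom, strand), []).append((s, e))
    out: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for p in peaks:
        key = (p.chrom, p.strand)
        m = peak_midpoint(p)
        seg = None
        for s, e in spans.get(key, []):
            if s <= m < e:
                seg = (s, e)
                break
        if seg is None:
            seg = (max(0, m - 500), m + 500)  # orphan peak: local window
        out.setdefault(key, []).append(seg)
    return {k: np.asarray(v, dtype=np.int64) for k, v in out.items()}


def shuffle_null(peaks: PeakSet, ann, genome: dict[str, str],
                 params: PipelineParams, seed: int | None = None,
                 _enc: _Encoded | None = None):
    """Null mean/SD of windowed counts and mean per-offset region count.

    Each shuffle re-draws every peak midpoint uniformly within its gene
    segment and retallies; deterministic for a given seed.
    """
    enc = _enc or _Encoded(genome)
    segs = _segment_of_peaks(peaks, ann)
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    obs_per_shuffle = np.zeros((params.n_perm, N_KMERS), dtype=np.int64)
    pos_total = np.zeros((N_KMERS, 2 * params.kmer_norm_window + 1), dtype=np.int64)
    for s in range(params.n_perm):
        mids = {
            key: rng.integers(bounds[:, 0], bounds[:, 1])
            for key, bounds in segs.items()
        }
        posmat = _count_at(enc, mids, params)
        obs_per_shuffle[s] = _observed_from_pos(posmat, params)
        pos_total += posmat
    null_mean = obs_per_shuffle.mean(axis=0)
    if params.n_perm > 1:
        null_sd = obs_per_shuffle.std(axis=0, ddof=1)
    else:
        null_sd = np.zeros(N_KMERS)
    n_off = 2 * params.kmer_norm_window + 1
    region_mean = pos_total.sum(axis=1) / (params.n_perm * n_off)
    return null_mean, null_sd, region_mean


class KmerProfiles:
    """Per-5mer observed/null statistics and normalized positional vectors."""

    def __init__(self, counts: KmerCounts, null_mean, null_sd, region_mean,
                 params: PipelineParams):
        self.observed = counts.observed
        self.pos = counts.pos
        self.offsets = counts.offsets
        self.n_peaks = counts.n_peaks
        self.null_mean = np.asarray(null_mean, dtype=float)
        self.null_sd = np.asarray(null_sd, dtype=float)
        self.region_mean = np.asarray(region_mean, dtype=float)
        self.params = params
        self.degenerate_sd = self.null_sd <= 0
        z = np.zeros(N_KMERS)
        ok = ~self.degenerate_sd
        z[ok] = (self.observed[ok] - self.null_mean[ok]) / self.null_sd[ok]
        self.z = z
        denom = np.where(self.region_mean > 0, self.region_mean, 0.5)
        self.norm_pos = self.pos / denom[:, None]
        self.gt_mask = np.array([is_gt(k) for k in ALL_KMERS])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kmer": ALL_KMERS,
                "observed": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
                "class": np.where(self.gt_mask, "GT", "non-GT"),
            }
        )


def build_kmer_profiles(peaks: PeakSet, ann, genome: dict[str, str],
                        params: PipelineParams, seed: int | None = None) -> KmerProfiles:
    enc = _Encoded(genome)
    counts = count_kmers(peaks, genome, params, _enc=enc)
    nm, nsd, rm = shuffle_null(peaks, ann, genome, params, seed=seed, _enc=enc)
    return KmerProfiles(counts, nm, nsd, rm, params)


def top_motifs(profiles: KmerProfiles, k: int | None = None) -> list[str]:
    """5mers ranked by Z descending; ties by observed count then kmer."""
    k = profiles.params.top_k_motifs if k is None else k
    order = sorted(
        range(N_KMERS),
        key=lambda i: (-profiles.z[i], -profiles.observed[i], ALL_KMERS[i]),
    )
    return [ALL_KMERS[i] for i in order[:k]]


def class_profiles(profiles: KmerProfiles, cls: str, k: int | None = None):
    """Mean normalized positional vector over the top-k motifs of one class.

    Returns (offsets, mean_vector, members); an empty class yields a zero
    vector and an empty member list.
    """
    if cls not in ("GT", "non-GT"):
        raise ValueError("class must be 'GT' or 'non-GT'")
    top = top_motifs(profiles, k)
    members = [m for m in top if is_gt(m) == (cls == "GT")]
    if not members:
        import warnings

        warnings.warn(f"no {cls} motifs among the top {k or profiles.params.top_k_motifs}")
        return profiles.offsets, np.zeros_like(profiles.offsets, dtype=float), []
    vecs = np.stack([profiles.norm_pos[kmer_id(m)] for m in members])
    return profiles.offsets, vecs.mean(axis=0), members


def donor_motif_profile(peaks: PeakSet, genome: dict[str, str], motif: str,
                        offset_range: tuple[int, int] = (-50, 50)):
    """Exact-match frequency of ``motif`` by start offset from peak midpoints.

    Offsets are in transcript orientation; frequency = matches / n_peaks.
    """
    lo, hi = offset_range
    offsets = np.arange(lo, hi + 1)
    counts = np.zeros(len(offsets), dtype=np.int64)
    m = len(motif)
    for p in peaks:
        mid = peak_midpoint(p)
        seq = genome[p.chrom]
        if p.strand == "+":
            s0 = mid + lo
            window = seq[max(0, s0): mid + hi + m]
            pad = max(0, -s0)
        else:
            e0 = mid - lo + 1
            s0 = mid - hi - m + 1
            window = revcomp(seq[max(0, s0): e0])
            pad = max(0, e0 - len(seq))  # right truncation before revcomp
        start = window.find(motif)
        while start != -1:
            off = lo + start + pad  # pad = bases truncated off the window front
            idx = off - lo
            if 0 <= idx < len(offsets):
                counts[idx] += 1
            start = window.find(motif, start + 1)
    freq = counts / max(1, len(peaks))
    return offsets, freq


def assemble_overlapping_kmers(kmers, min_overlap: int = 4):
    """Greedy maximal-overlap merge of k-mers into a consensus string.

    Returns (consensus, merged_flag): when every input chains together with
    overlaps >= min_overlap the shortest greedy superstring is returned with
    merged=True; otherwise the inputs are returned unchanged with
    merged=False.
    """
    pieces = sorted(set(str(k) for k in kmers))
    if not pieces:
        raise ValueError("no kmers to assemble")

    def overlap(a: str, b: str) -> int:
        best = 0
        for n in range(min(len(a), len(b)), 0, -1):
            if a[-n:] == b[:n]:
                best = n
                break
        return best

    while len(pieces) > 1:
        best = (-1, None, None)
        for a in pieces:
            for b in pieces:
                if a == b:
                    continue
                ov = overlap(a, b)
                if ov > best[0] or (ov == best[0] and (a, b) < (best[1], best[2])):
                    best = (ov, a, b)
        ov, a, b = best
        if ov < min_overlap:
            return tuple(pieces), False
        pieces.remove(a)
        pieces.remove(b)
        pieces.append(a + b[ov:])
        pieces.sort()
    return pieces[0], True
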