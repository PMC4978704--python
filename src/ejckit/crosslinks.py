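"""Crosslink events: read conversion, UMI deduplication, tracks, counting.

The unit of all downstream analysis is the crosslink event — the single
nucleotide inferred as the protein-RNA contact. Aligned iCLIP reads truncate
at the crosslink, so the event sits immediately 5' of the read start.
PCR duplicates are collapsed by (position, strand, UMI).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class Event:
    chrom: str
    pos: int
    strand: str
    umi: str = ""


class CrosslinkTrack:
    """Strand-aware per-position unique crosslink-event counts for one library."""

    def __init__(
        self,
        library_id: str,
        data: Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray]],
        total_raw: int | None = None,
    ):
        # data: (chrom, strand) -> (sorted positions, counts)
        self.library_id = library_id
        self.data = {k: (np.asarray(p, dtype=np.int64), np.asarray(c, dtype=np.int64))
                     for k, (p, c) in data.items()}
        self.total_unique = int(sum(c.sum() for _, c in self.data.values()))
        self.total_raw = int(total_raw) if total_raw is not None else self.total_unique

    @classmethod
    def from_counter(
        cls, library_id: str, counter: Mapping[tuple[str, str, int], int],
        total_raw: int | None = None,
    ) -> "CrosslinkTrack":
        grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for (chrom, strand, pos), n in counter.items():
            grouped.setdefault((chrom, strand), []).append((pos, n))
        data = {}
        for key, items in grouped.items():
            items.sort()
            pos = np.array([p for p, _ in items], dtype=np.int64)
            cnt = np.array([n for _, n in items], dtype=np.int64)
            data[key] = (pos, cnt)
        return cls(library_id, data, total_raw=total_raw)

    def keys(self):
        return self.data.keys()

    def positions(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        return self.data.get(
            (chrom, strand), (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        )

    def count_in(self, chrom: str, strand: str, start: int, end: int) -> int:
        pos, cnt = self.positions(chrom, strand)
        i, j = np.searchsorted(pos, [start, end])
        return int(cnt[i:j].sum())

    def array(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense count vector over [start, end)."""
        out = np.zeros(end - start, dtype=np.int64)
        pos, cnt = self.positions(chrom, strand)
        i, j = np.searchsorted(pos, [start, end])
        out[pos[i:j] - start] = cnt[i:j]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chrom, strand), (pos, cnt) in sorted(self.data.items()):
            for p, n in zip(pos, cnt):
                rows.append((chrom, int(p), int(p) + 1, ".", int(n), strand))
        return pd.DataFrame(rows, columns=BED6_COLUMNS)

    @classmethod
    def pool(cls, tracks: Iterable["CrosslinkTrack"], library_id: str) -> "CrosslinkTrack":
        """Sum unique events across libraries (used before peak calling)."""
        counter: Counter = Counter()
        total_raw = 0
        for tr in tracks:
            total_raw += tr.total_raw
            for (chrom, strand), (pos, cnt) in tr.data.items():
                for p, n in zip(pos, cnt):
                    counter[(chrom, strand, int(p))] += int(n)
        return cls.from_counter(library_id, counter, total_raw=total_raw)


# ---------------------------------------------------------------------------
# Reads -> events
# ---------------------------------------------------------------------------

def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED6_COLUMNS)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def _umi_of(name: str) -> str:
    # name field convention "readid:UMI"
    return str(name).rsplit(":", 1)[-1] if ":" in str(name) else ""


def reads_to_crosslinks(reads: pd.DataFrame) -> tuple[list[Event], int]:
    """Convert aligned read spans (BED6) to crosslink events.

    The crosslink nucleotide is immediately 5' of the read start on the
    read's strand: plus-strand read [s, e) -> s - 1; minus-strand -> e.
    Returns (events, n_dropped) where events at negative positions are
    dropped and counted.
    """
    if "strand" not in reads.columns or reads["strand"].isna().any():
        raise ValueError("BED input must carry a strand for every read")
    events: list[Event] = []
    dropped = 0
    for chrom, start, end, name, strand in zip(
        reads["chrom"], reads["start"], reads["end"], reads["name"], reads["strand"]
    ):
        if strand == "+":
            pos = int(start) - 1
        elif strand == "-":
            pos = int(end)
        else:
            raise ValueError(f"missing/invalid strand {strand!r}")
        if pos < 0:
            dropped += 1
            continue
        events.append(Event(chrom, pos, strand, _umi_of(name)))
    if dropped:
        warnings.warn(f"dropped {dropped} crosslink events at negative positions")
    return events, dropped


def crosslink_bed_to_events(df: pd.DataFrame) -> list[Event]:
    """Interpret single-nucleotide BED records (start = crosslink site) as events."""
    return [
        Event(c, int(s), st, _umi_of(n))
        for c, s, n, st in zip(df["chrom"], df["start"], df["name"], df["strand"])
    ]


def dedup_umis(events: Iterable[Event], library_id: str = "lib") -> CrosslinkTrack:
    """Collapse identical (chrom, strand, position, UMI) tuples to one event.

    ``total_raw / total_unique`` of the returned track is the
    overamplification rate monitored by the random-barcode protocol.
    """
    raw = 0
    seen: set[tuple[str, str, int, str]] = set()
    counter: Counter = Counter()
    for ev in events:
        raw += 1
        key = (ev.chrom, ev.strand, ev.pos, ev.umi)
        if key in seen:
            continue
        seen.add(key)
        counter[(ev.chrom, ev.strand, ev.pos)] += 1
    return CrosslinkTrack.from_counter(library_id, counter, total_raw=raw)


# ---------------------------------------------------------------------------
# Normalization and counting
# ---------------------------------------------------------------------------

def rpm(track: CrosslinkTrack, interval: tuple[str, str, int, int]) -> float:
    """Unique events in (chrom, strand, start, end) per million library events."""
    if track.total_unique == 0:
        raise ValueError("RPM undefined for an empty library")
    chrom, strand, start, end = interval
    return track.count_in(chrom, strand, start, end) * 1e6 / track.total_unique


def count_per_gene(track: CrosslinkTrack, ann) -> pd.DataFrame:
    """HTSeq-union-style per-gene crosslink event counts.

    An event inside exactly one gene's exonic union (same strand) counts for
    that gene; events in the exonic union of two or more genes are
    ambiguous; non-exonic events inside exactly one gene span count as
    intronic for that gene; everything else is unassigned. The returned
    frame has one row per gene (exonic/intronic) plus ``__ambiguous__`` and
    ``__unassigned__`` rows, and conserves total_unique.
    """
    exon_trees: dict[tuple[str, str], IntervalTree] = {}
    span_trees: dict[tuple[str, str], IntervalTree] = {}
    for g in ann.genes:
        key = (g.chrom, g.strand)
        et = exon_trees.setdefault(key, IntervalTree())
        for t in g.transcripts:
            for s, e in t.exons:
                et.addi(s, e, g.gene_id)
        s, e = g.span
        span_trees.setdefault(key, IntervalTree()).addi(s, e, g.gene_id)

    exonic: Counter = Counter()
    intronic: Counter = Counter()
    ambiguous = 0
    unassigned = 0
    for (chrom, strand), (pos, cnt) in track.data.items():
        et = exon_trees.get((chrom, strand))
        st = span_trees.get((chrom, strand))
        for p, n in zip(pos, cnt):
            n = int(n)
            hits = {iv.data for iv in et[int(p)]} if et is not None else set()
            if len(hits) == 1:
                exonic[hits.pop()] += n
            elif len(hits) > 1:
                ambiguous += n
            else:
                spans = {iv.data for iv in st[int(p)]} if st is not None else set()
                if len(spans) == 1:
                    intronic[spans.pop()] += n
                elif len(spans) > 1:
                    ambiguous += n
                else:
                    unassigned += n

    rows = [
        (g.gene_id, exonic.get(g.gene_id, 0), intronic.get(g.gene_id, 0))
        for g in ann.genes
    ]
    rows.append(("__ambiguous__", ambiguous, 0))
    rows.append(("__unassigned__", unassigned, 0))
    return pd.DataFrame(rows, columns=["gene_id", "exonic", "intronic"]).set_index(
        "gene_id"
    )


def count_matrix(tracks: Iterable[CrosslinkTrack], ann) -> pd.DataFrame:
    """Genes x libraries exonic count matrix (exportable for edgeR etc.)."""
    cols = {}
    for tr in tracks:
        cols[tr.library_id] = count_per_gene(tr, ann)["exonic"]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# bedGraph I/O (plain-text, one file per strand)
# ---------------------------------------------------------------------------

def write_bedgraph(track: CrosslinkTrack, path_plus: str, path_minus: str) -> None:
    """Emit positions with count > 0 as single-nucleotide bedGraph intervals."""
    handles = {"+": open(path_plus, "w"), "-": open(path_minus, "w")}
    try:
        for (chrom, strand), (pos, cnt) in sorted(track.data.items()):
            fh = handles[strand]
            for p, n in zip(pos, cnt):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{n}\n")
    finally:
        for fh in handles.values():
            fh.close()


def read_bedgraph(path_plus: str, path_minus: str, library_id: str = "lib") -> CrosslinkTrack:
    counter: Counter = Counter()
    for path, strand in ((path_plus, "+"), (path_minus, "-")):
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
            )
        except pd.errors.EmptyDataError:
            continue
        for chrom, start, end, value in df.itertuples(index=False):
            for p in range(int(start), int(end)):
                counter[(chrom, strand, p)] += int(value)
    return CrosslinkTrack.from_counter(library_id, counter)
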