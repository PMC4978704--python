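"""High-confidence site merging, BTZ marking, candidate exons, exon filters."""

import numpy as np
import pytest

from conftest import make_annotation, make_gene
from ejckit.crosslinks import CrosslinkTrack
from ejckit.peakcalling import Peak, PeakSet, PipelineParams
from ejckit.sites import (HighConfSite, btz_marking_stats,
                          expressed_and_marked_exons, find_candidate_exons,
                          merge_high_confidence, non_btz_site_profile,
                          table1_filter)
from ejckit.annotation import classify_exons


def ps(intervals, strand="+"):
    return PeakSet([
        Peak("chr1", strand, s, e, s, 1, 0.0, event_count=1) for s, e in intervals
    ])


def test_overlapping_peaks_from_two_proteins_merge():
    sites = merge_high_confidence({"BTZ": ps([(100, 110)]), "eIF4A3": ps([(109, 120)])})
    [s] = sites
    assert (s.start, s.end) == (100, 120)
    assert s.supporters == {"BTZ", "eIF4A3"}
    assert s.contains_btz


def test_abutting_peaks_do_not_merge():
    sites = merge_high_confidence({"BTZ": ps([(100, 110)]), "eIF4A3": ps([(110, 120)])})
    assert sites == []


def test_single_protein_clusters_dropped_and_input_checked():
    sites = merge_high_confidence({"BTZ": ps([(100, 110), (105, 130)]), "eIF4A3": ps([])})
    assert sites == []
    with pytest.raises(ValueError, match=">=2"):
        merge_high_confidence({"BTZ": ps([(0, 5)])})


def test_gfp_overlap_removes_site():
    sites = merge_high_confidence(
        {"BTZ": ps([(100, 110)]), "eIF4A3": ps([(105, 120)])},
        gfp_peaks=ps([(118, 125)]),
    )
    assert sites == []
    kept = merge_high_confidence(
        {"BTZ": ps([(100, 110)]), "eIF4A3": ps([(105, 120)])},
        gfp_peaks=ps([(120, 125)]),  # abutting, no overlap
    )
    assert len(kept) == 1


def test_merged_sites_are_disjoint_and_cover_members(pipeline_run):
    sites = pipeline_run["sites"]
    by_key = {}
    for s in sites:
        by_key.setdefault((s.chrom, s.strand), []).append((s.start, s.end))
    for ivs in by_key.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2
    for protein, pset in pipeline_run["peaksets"].items():
        tree = {k: v for k, v in by_key.items()}
    assert all(len(s.supporters) >= 2 for s in sites)


def test_btz_marking_fraction():
    sites = [
        HighConfSite("chr1", "+", i * 100, i * 100 + 10,
                     frozenset({"BTZ", "eIF4A3"} if i < 9 else {"UPF3B", "eIF4A3"}))
        for i in range(10)
    ]
    n, nb, frac = btz_marking_stats(sites)
    assert (n, nb, frac) == (10, 9, 0.9)
    with pytest.raises(ValueError):
        btz_marking_stats([])


def test_btz_marks_most_sites_in_full_simulation(pipeline_run):
    assert pipeline_run["btz_fraction"] >= 0.9


def test_non_btz_profile_empty_set_is_flat_zero(pipeline_run):
    params = PipelineParams()
    cat = classify_exons(pipeline_run["ann"])
    no_sites = [s for s in pipeline_run["sites"] if False]
    bins, prof, used = non_btz_site_profile(no_sites, pipeline_run["tracks"], cat, params)
    assert used == 0 and not prof.any()


def candidate_setup():
    """Gene with one annotated exon; an unannotated intergenic BTZ peak with
    the donor motif planted downstream."""
    g = make_gene("g1", "chr1", "+", [[(100, 200)]])
    ann = make_annotation([g], {"chr1": 2000})
    seq = list("A" * 2000)
    seq[510:517] = "AGGTAAG"  # starts 10 nt downstream of peak end 500
    genome = {"chr1": "".join(seq)}
    counts = {("chr1", "+", p): 1 for p in range(490, 500)}
    btz_track = CrosslinkTrack.from_counter("BTZ", counts)
    btz_track.total_unique = 10 ** 6  # 10 events -> 10 RPM inside the peak
    btz_peaks = ps([(490, 500)])
    others = {"UPF3B": ps([(495, 505)])}
    return ann, genome, btz_track, btz_peaks, others


def test_candidate_exon_accepted():
    ann, genome, track, peaks, others = candidate_setup()
    track.total_unique = 3_000_000  # 10 events -> 3.33 RPM > 2
    [call] = find_candidate_exons(track, peaks, others, ann, genome, PipelineParams())
    assert call.motif == "AGGTAAG" and call.motif_offset == 10
    assert call.second_protein == "UPF3B"
    assert call.btz_rpm > 2


def test_candidate_rejected_when_motif_too_far():
    ann, genome, track, peaks, others = candidate_setup()
    seq = list(genome["chr1"])
    seq[510:517] = "AAAAAAA"
    seq[530:537] = "AGGTAAG"  # 30 nt downstream: beyond the 25 nt proximity
    genome = {"chr1": "".join(seq)}
    track.total_unique = 3_000_000
    assert find_candidate_exons(track, peaks, others, ann, genome, PipelineParams()) == []


def test_candidate_rejected_on_exon_overlap():
    ann, genome, track, peaks, others = candidate_setup()
    track.total_unique = 3_000_000
    peaks = ps([(195, 205)])  # 1 nt into the annotated exon suffices
    others = {"UPF3B": ps([(195, 210)])}
    assert find_candidate_exons(track, peaks, others, ann, genome, PipelineParams()) == []


def test_candidate_rejected_below_rpm():
    ann, genome, track, peaks, others = candidate_setup()
    track.total_unique = 10_000_000  # 10 events -> 1 RPM, below the threshold
    assert find_candidate_exons(track, peaks, others, ann, genome, PipelineParams()) == []


def test_candidate_calls_never_intersect_annotation(pipeline_run):
    params = PipelineParams()
    calls = find_candidate_exons(
        pipeline_run["tracks"]["BTZ"], pipeline_run["peaksets"]["BTZ"],
        {k: v for k, v in pipeline_run["peaksets"].items() if k != "BTZ"},
        pipeline_run["ann"], pipeline_run["genome"], params,
    )
    exons = [
        (g.chrom, g.strand, s, e)
        for g in pipeline_run["ann"].genes for t in g.transcripts for s, e in t.exons
    ]
    for c in calls:
        for chrom, strand, s, e in exons:
            if (chrom, strand) == (c.chrom, c.strand):
                assert c.end <= s or e <= c.start


def rpm_track(library, exon_rpm):
    """Track whose RPM inside [0,100) equals the requested value
    (10 x rpm events against a 10-million-event library)."""
    counts = {("chr1", "+", p): 1 for p in range(int(round(10 * exon_rpm)))}
    tr = CrosslinkTrack.from_counter(library, counts)
    tr.total_unique = 10 ** 7
    return tr


def test_table1_rule_combinations():
    g = make_gene("g1", "chr1", "+", [[(0, 100), (200, 300), (400, 500)]])
    ann = make_annotation([g], {"chr1": 1000})
    cat = classify_exons(ann)
    params = PipelineParams()
    # events land in [0,100): only the 5' terminal exon can pass
    passing = table1_filter(cat, rpm_track("BTZ", 1.5), {"eIF4A3": rpm_track("e", 1.2)},
                            rpm_track("RNA", 0.3), params)
    assert passing.set_index("category").loc["five_prime_terminal", "n_pass"] == 1
    assert passing["n_pass"].sum() == 1
    # RNA-seq exactly at the threshold: strict '<' excludes
    at_cut = table1_filter(cat, rpm_track("BTZ", 1.5), {"eIF4A3": rpm_track("e", 1.2)},
                           rpm_track("RNA", 0.5), params)
    assert at_cut["n_pass"].sum() == 0
    # BTZ alone is not enough
    alone = table1_filter(cat, rpm_track("BTZ", 1.5), {"eIF4A3": rpm_track("e", 0.0)},
                          rpm_track("RNA", 0.3), params)
    assert alone["n_pass"].sum() == 0


def test_expression_thresholds_are_inclusive():
    g = make_gene("g1", "chr1", "+", [[(0, 100), (200, 300)]])
    ann = make_annotation([g], {"chr1": 1000})
    cat = classify_exons(ann)
    params = PipelineParams()
    rna = CrosslinkTrack.from_counter("RNA", {("chr1", "+", p): 1 for p in range(10)})
    btz9 = CrosslinkTrack.from_counter("BTZ", {("chr1", "+", p): 1 for p in range(9)})
    n_expr, n_pos = expressed_and_marked_exons(cat, rna, btz9, params)
    assert n_expr == 1  # exactly 10 reads counts as expressed
    assert n_pos == 0   # 9 BTZ events misses the >= 10 cut
    btz10 = CrosslinkTrack.from_counter("BTZ", {("chr1", "+", p): 1 for p in range(10)})
    assert expressed_and_marked_exons(cat, rna, btz10, params) == (1, 1)


def test_expressed_and_marked_recovers_simulated_truth(small_sim):
    """Highly transcribed exons with junction-bearing ends carry >= 10 BTZ
    events; the recovered counts stay within sampling noise of the truth."""
    from ejckit.simulate import simulate_rnaseq

    params = PipelineParams()
    cat = classify_exons(small_sim["ann"])
    rna = simulate_rnaseq(small_sim["cfg"], small_sim["ann"], small_sim["truth"])
    n_expr, n_pos = expressed_and_marked_exons(cat, rna, small_sim["tracks"]["BTZ"], params)
    assert 0 < n_pos <= n_expr <= len(cat)
    # most exons of this deeply sequenced simulation are expressed
    assert n_expr / len(cat) > 0.8
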