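"""Simulator determinism, planted structure, and sampling distributions."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_annotation, make_gene
from ejckit.annotation import classify_exons, junction_offset
from ejckit.crosslinks import crosslink_bed_to_events, dedup_umis
from ejckit.simulate import (ProteinModel, SimulatedTruth, SimulationConfig,
                             generate_genome_and_annotation, revcomp,
                             simulate_iclip, simulate_rnaseq)


def test_generation_is_deterministic_given_seed():
    cfg = SimulationConfig(seed=42, n_genes=8)
    g1, a1, t1 = generate_genome_and_annotation(cfg)
    g2, a2, t2 = generate_genome_and_annotation(cfg)
    assert g1 == g2
    assert [(x.gene_id, x.span) for x in a1.genes] == [(x.gene_id, x.span) for x in a2.genes]
    assert [s.positions for s in t1.ejc_sites] == [s.positions for s in t2.ejc_sites]


def test_category_plan_realizes_requested_exons():
    cfg = SimulationConfig(seed=1, n_genes=12, category_plan={"skip": 5})
    _, ann, _ = generate_genome_and_annotation(cfg)
    counts = classify_exons(ann).category_counts()
    assert counts["variant"] >= 5


def test_all_seven_categories_realized(small_sim):
    counts = classify_exons(small_sim["ann"]).category_counts()
    assert all(counts[c] > 0 for c in counts)


def test_donor_consensus_planted_at_every_junction(small_sim):
    genome, ann = small_sim["genome"], small_sim["ann"]
    consensus = small_sim["cfg"].donor_consensus
    for chrom, strand, j, _ in ann.junctions():
        if strand == "+":
            window = genome[chrom][j - 2: j + 5]
        else:
            window = revcomp(genome[chrom][j - 4: j + 3])
        assert window == consensus


def test_truth_sites_sit_in_canonical_window(small_sim):
    for site in small_sim["truth"].ejc_sites:
        for p in site.positions:
            assert -24 <= junction_offset(p, site.junction, site.strand) <= -20


def test_noise_free_ejc_events_all_in_truth_windows():
    cfg = SimulationConfig(seed=5, n_genes=10, noise_fraction=0.0,
                           duplication_rate=0.0, n_events=2000,
                           proteins={"BTZ": ProteinModel("ejc")})
    _, ann, truth = generate_genome_and_annotation(cfg)
    raw = simulate_iclip(cfg, ann, truth, "BTZ")
    windows = truth.window_set()
    assert len(raw) == cfg.n_events  # duplication rate 0: one row per molecule
    assert all((r.chrom, r.strand, r.start) in windows for r in raw.itertuples())


def test_pcr_duplicates_share_umi_and_inflate_raw():
    cfg = SimulationConfig(seed=5, n_genes=6, duplication_rate=0.5, n_events=2000,
                           proteins={"BTZ": ProteinModel("ejc")})
    _, ann, truth = generate_genome_and_annotation(cfg)
    raw = simulate_iclip(cfg, ann, truth, "BTZ")
    assert len(raw) > cfg.n_events
    track = dedup_umis(crosslink_bed_to_events(raw), "BTZ")
    assert track.total_raw == len(raw)
    assert track.total_unique <= cfg.n_events
    assert track.total_raw / track.total_unique > 1.5


def test_unknown_protein_rejected(small_sim):
    with pytest.raises(ValueError, match="unknown protein"):
        simulate_iclip(small_sim["cfg"], small_sim["ann"], small_sim["truth"], "XYZ")


def test_gfp_positions_uniform_over_transcribed_span():
    """KS test against uniform on the concatenated gene spans, not rejected
    at alpha=0.01 (n=10,000, fixed seed)."""
    cfg = SimulationConfig(seed=9, n_genes=20, n_events=10_000, duplication_rate=0.0,
                           proteins={"GFP": ProteinModel("uniform")})
    _, ann, truth = generate_genome_and_annotation(cfg)
    raw = simulate_iclip(cfg, ann, truth, "GFP")
    spans = truth.transcribed_spans
    offsets = {}
    cum = 0
    for chrom, strand, s, e in spans:
        offsets[(chrom, strand, s, e)] = cum
        cum += e - s
    u = []
    for r in raw.itertuples():
        for chrom, strand, s, e in spans:
            if chrom == r.chrom and strand == r.strand and s <= r.start < e:
                u.append((offsets[(chrom, strand, s, e)] + r.start - s) / cum)
                break
    assert len(u) == len(raw)
    assert sps.kstest(u, "uniform").pvalue > 0.01


def test_depleted_genes_have_downweighted_truth(small_sim):
    truth = small_sim["truth"]
    mult = small_sim["cfg"].depleted_multiplier
    flagged = {g for g, f in truth.gene_flags.items() if f}
    assert flagged  # the default fraction creates some
    for site in truth.ejc_sites:
        expected = sum(
            truth.transcript_abundance[t.transcript_id]
            for g in small_sim["ann"].genes if g.gene_id == site.gene_id
            for t in g.transcripts
            if _uses_junction(t, g.strand, site.junction)
        )
        if site.gene_id in flagged:
            expected *= mult
        assert site.weight == pytest.approx(expected)


def _uses_junction(t, strand, j):
    exons = t.sorted_exons()
    donors = [e for _, e in exons[:-1]] if strand == "+" else [s - 1 for s, _ in exons[1:]]
    return j in donors


def test_rnaseq_skipped_exon_tracks_isoform_abundance():
    """The minor isoform (1 of 10:1) carries the cassette exon, so that
    exon's coverage is ~1/11 of the shared-exon coverage (within Poisson
    tolerance)."""
    shared1, cassette, shared2 = (0, 200), (400, 600), (800, 1000)
    g = make_gene("g1", "chr1", "+", [[shared1, cassette, shared2], [shared1, shared2]])
    ann = make_annotation([g], {"chr1": 2000})
    truth = SimulatedTruth(
        ejc_sites=[], tracts=[], gene_abundance={"g1": 11.0},
        gene_flags={"g1": ""},
        transcript_abundance={"g1.t1": 1.0, "g1.t2": 10.0},
        transcribed_spans=[("chr1", "+", 0, 1000)],
    )
    cfg = SimulationConfig(seed=4, n_rnaseq_reads=300_000)
    track = simulate_rnaseq(cfg, ann, truth)
    c_shared = track.count_in("chr1", "+", *shared1) / 200
    c_skip = track.count_in("chr1", "+", *cassette) / 200
    ratio = c_skip / c_shared
    sd = 3 * np.sqrt(max(c_skip * 200, 1.0)) / 200 / c_shared
    assert abs(ratio - 1 / 11) < 0.02 + sd
    assert track.count_in("chr1", "+", 200, 400) == 0  # intron


def test_rnaseq_zero_abundance_means_zero_coverage():
    g = make_gene("g1", "chr1", "+", [[(0, 100)]])
    ann = make_annotation([g], {"chr1": 500})
    truth = SimulatedTruth([], [], {"g1": 0.0}, {"g1": ""}, {"g1.t1": 0.0},
                           [("chr1", "+", 0, 100)])
    track = simulate_rnaseq(SimulationConfig(seed=4), ann, truth)
    assert track.total_unique == 0


def test_rnaseq_reproducible(small_sim):
    a = simulate_rnaseq(small_sim["cfg"], small_sim["ann"], small_sim["truth"])
    b = simulate_rnaseq(small_sim["cfg"], small_sim["ann"], small_sim["truth"])
    assert a.total_unique == b.total_unique
    for key in a.keys():
        pa, ca = a.positions(*key)
        pb, cb = b.positions(*key)
        assert np.array_equal(pa, pb) and np.array_equal(ca, cb)


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(exon_length=(10, 30))
    with pytest.raises(ValueError):
        SimulationConfig(noise_fraction=1.5)
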