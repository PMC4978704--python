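"""Gene-model parsing, region maps, and exon classification."""

import random

import pytest

from conftest import make_annotation, make_gene
from ejckit.annotation import (EXON_CATEGORIES, ExonRecord, GenomeAnnotation,
                               build_region_map, classify_exons,
                               cumulative_region_lengths, junction_offset,
                               read_gtf, write_gtf)


def test_gtf_roundtrip_converts_coordinates(tmp_path):
    """A GTF exon 101..200 becomes the internal interval [100, 200) and
    write/read reproduces every interval exactly."""
    gtf = tmp_path / "toy.gtf"
    attrs = 'gene_id "g1"; transcript_id "g1.t1"; gene_biotype "protein_coding";'
    gtf.write_text(
        "\n".join(
            [
                f"chr1\tx\tgene\t101\t400\t.\t+\t.\t{attrs}",
                f"chr1\tx\ttranscript\t101\t400\t.\t+\t.\t{attrs}",
                f"chr1\tx\texon\t101\t200\t.\t+\t.\t{attrs}",
                f"chr1\tx\texon\t301\t400\t.\t+\t.\t{attrs}",
                f"chr1\tx\tCDS\t151\t200\t.\t+\t.\t{attrs}",
                f"chr1\tx\tCDS\t301\t350\t.\t+\t.\t{attrs}",
            ]
        )
        + "\n"
    )
    ann = read_gtf(str(gtf), {"chr1": 1000})
    t = ann.genes[0].transcripts[0]
    assert t.exons == [(100, 200), (300, 400)]
    assert t.cds == (150, 350)

    out = tmp_path / "rt.gtf"
    write_gtf(ann, str(out))
    ann2 = read_gtf(str(out), {"chr1": 1000})
    t2 = ann2.genes[0].transcripts[0]
    assert t2.exons == t.exons and t2.cds == t.cds


def test_gtf_groups_transcripts_under_gene(tmp_path):
    gtf = tmp_path / "two.gtf"
    lines = []
    for tid in ("t1", "t2"):
        attrs = f'gene_id "g1"; transcript_id "{tid}";'
        lines.append(f"chr1\tx\ttranscript\t101\t200\t.\t+\t.\t{attrs}")
        lines.append(f"chr1\tx\texon\t101\t200\t.\t+\t.\t{attrs}")
    gtf.write_text("\n".join([f'chr1\tx\tgene\t101\t200\t.\t+\t.\tgene_id "g1";'] + lines) + "\n")
    ann = read_gtf(str(gtf), {"chr1": 500})
    assert len(ann.genes) == 1 and len(ann.genes[0].transcripts) == 2


def test_exon_outside_chromosome_rejected():
    g = make_gene("g1", "chr1", "+", [[(0, 100)]])
    with pytest.raises(ValueError, match="outside"):
        make_annotation([g], {"chr1": 50})


def test_region_map_hand_enumerated_example():
    """One transcript, exons [0,100)+[200,300), CDS [50,250): 5'UTR 0-49,
    ORF 50-99 and 200-249, intron 100-199, 3'UTR 250-299."""
    g = make_gene("g1", "chr1", "+", [[(0, 100), (200, 300)]], cds=(50, 250))
    ann = make_annotation([g], {"chr1": 1000})
    rm = build_region_map(ann)
    expected = {}
    expected.update({p: "five_prime_utr" for p in range(0, 50)})
    expected.update({p: "orf" for p in range(50, 100)})
    expected.update({p: "intron" for p in range(100, 200)})
    expected.update({p: "orf" for p in range(200, 250)})
    expected.update({p: "three_prime_utr" for p in range(250, 300)})
    for pos, lab in expected.items():
        assert rm.label_at("chr1", "+", pos) == lab, pos
    assert rm.label_at("chr1", "-", 60) == "intergenic"  # strand-specific
    lengths = cumulative_region_lengths(rm)
    assert lengths["orf"] == 100
    assert lengths["five_prime_utr"] == 50
    assert lengths["three_prime_utr"] == 50
    assert lengths["intron"] == 100


def test_empty_annotation_is_all_intergenic():
    ann = GenomeAnnotation([], {"chr1": 1000})
    lengths = cumulative_region_lengths(build_region_map(ann))
    assert lengths["intergenic"] == 2000
    assert sum(lengths.values()) == 2000


def test_orf_precedence_over_intron_across_isoforms():
    """A position exonic-ORF in one gene and intronic in another is ORF."""
    a = make_gene("a", "chr1", "+", [[(100, 200)]], cds=(100, 200))
    b = make_gene("b", "chr1", "+", [[(0, 50), (400, 450)]], cds=(0, 450))
    ann = make_annotation([a, b], {"chr1": 1000})
    rm = build_region_map(ann)
    assert rm.label_at("chr1", "+", 150) == "orf"


def test_region_partition_identity_on_simulation(small_sim):
    rm = build_region_map(small_sim["ann"])
    lengths = cumulative_region_lengths(rm)
    assert sum(lengths.values()) == 2 * sum(small_sim["ann"].chrom_lengths.values())
    assert all(lengths[lab] > 0 for lab in ("orf", "five_prime_utr",
                                            "three_prime_utr", "intron",
                                            "intergenic", "ncRNA"))


def test_classify_skipped_exon_rule_table():
    """T1 = A,B,C and T2 = A,C: A is 5' terminal, C 3' terminal, B variant."""
    A, B, C = (0, 100), (200, 300), (400, 500)
    g = make_gene("g1", "chr1", "+", [[A, B, C], [A, C]])
    cat = {((x.start, x.end)): x.category for x in classify_exons(make_annotation([g], {"chr1": 1000}))}
    assert cat[A] == "five_prime_terminal"
    assert cat[C] == "three_prime_terminal"
    assert cat[B] == "variant"


def test_classify_alternative_donor_and_acceptor():
    flank5, flank3 = (0, 100), (600, 700)
    g = make_gene(
        "g1", "chr1", "+",
        [[flank5, (200, 300), flank3], [flank5, (200, 320), flank3]],
    )
    cat = {(x.start, x.end): x.category for x in classify_exons(make_annotation([g], {"chr1": 1000}))}
    assert cat[(200, 300)] == "alt_donor" and cat[(200, 320)] == "alt_donor"

    # same variation on the minus strand flips donor/acceptor
    gm = make_gene(
        "g2", "chr1", "-",
        [[flank5, (200, 300), flank3], [flank5, (200, 320), flank3]],
    )
    catm = {(x.start, x.end): x.category for x in classify_exons(make_annotation([gm], {"chr1": 1000}))}
    assert catm[(200, 300)] == "alt_acceptor"


def test_classify_single_isoform_and_single_exon():
    g = make_gene("g1", "chr1", "+", [[(0, 100), (200, 300), (400, 500)]])
    cat = {(x.start, x.end): x.category for x in classify_exons(make_annotation([g], {"chr1": 1000}))}
    assert cat[(200, 300)] == "constitutive"

    mono = make_gene("g2", "chr1", "+", [[(0, 100)]])
    [x] = list(classify_exons(make_annotation([mono], {"chr1": 1000})))
    assert x.category == "three_prime_terminal"  # 3' wins for single-exon


def test_classification_invariant_to_transcript_order(small_sim):
    ann = small_sim["ann"]
    base = {(x.chrom, x.start, x.end): x.category for x in classify_exons(ann)}
    rng = random.Random(0)
    for g in ann.genes:
        rng.shuffle(g.transcripts)
    shuffled = {(x.chrom, x.start, x.end): x.category for x in classify_exons(ann)}
    assert base == shuffled


def test_constitutive_exons_present_in_every_isoform(small_sim):
    ann = small_sim["ann"]
    by_gene = {g.gene_id: g for g in ann.genes}
    for x in classify_exons(ann):
        if x.category == "constitutive":
            g = by_gene[x.gene_id]
            assert all((x.start, x.end) in t.exons for t in g.transcripts)


def test_every_exon_has_exactly_one_known_category(small_sim):
    cat = classify_exons(small_sim["ann"])
    assert all(x.category in EXON_CATEGORIES for x in cat)
    seen = set()
    for x in cat:
        key = (x.chrom, x.strand, x.start, x.end, x.gene_id)
        assert key not in seen
        seen.add(key)


def test_junction_offset_convention():
    # plus strand: junction j, last exonic base j-1 has offset -1
    assert junction_offset(99, 100, "+") == -1
    assert junction_offset(76, 100, "+") == -24
    # minus strand: junction j, last exonic base j+1 has offset -1
    assert junction_offset(101, 100, "-") == -1
    assert junction_offset(124, 100, "-") == -24
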