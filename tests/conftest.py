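"""Shared fixtures: small simulated datasets reused across the suite."""

import pytest

from ejckit.annotation import Gene, GenomeAnnotation, Transcript
from ejckit.simulate import (ProteinModel, SimulationConfig,
                             generate_genome_and_annotation)
from ejckit.workflows import ejc_pipeline_experiment, simulate_tracks

SEED = 11


@pytest.fixture(scope="session")
def small_sim():
    """Compact genome with all exon categories and one EJC-like library."""
    cfg = SimulationConfig(
        seed=SEED, n_genes=20,
        category_plan={"skip": 4, "alt_donor": 3, "alt_acceptor": 3, "alt_both": 2},
        proteins={"BTZ": ProteinModel("ejc"), "GFP": ProteinModel("uniform"),
                  "PTB": ProteinModel("ptb")},
        n_events=15_000,
    )
    genome, ann, truth, tracks = simulate_tracks(cfg)
    return {"cfg": cfg, "genome": genome, "ann": ann, "truth": truth, "tracks": tracks}


@pytest.fixture(scope="session")
def pipeline_run():
    """Full four-protein + GFP integration run (shared by several tests)."""
    return ejc_pipeline_experiment(SEED)


def make_gene(gene_id, chrom, strand, isoform_exons, cds=None, biotype="protein_coding"):
    g = Gene(gene_id, chrom, strand, biotype)
    for i, exons in enumerate(isoform_exons):
        g.transcripts.append(
            Transcript(f"{gene_id}.t{i + 1}", gene_id, sorted(exons), cds)
        )
    return g


def make_annotation(genes, chrom_lengths):
    ann = GenomeAnnotation(genes, chrom_lengths)
    ann.validate()
    return ann
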