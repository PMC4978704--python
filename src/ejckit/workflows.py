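"""End-to-end pipeline drivers on simulated data.

These functions wire the stages together the way the analysis runs on real
libraries — simulate (or load) crosslink events, deduplicate, call peaks
per protein, merge high-confidence sites, profile motifs — and return the
summary quantities the method is judged by: permutation-FDR calibration of
the peak caller and recovery of canonical deposition positions by the
multi-protein integration.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import motifs as mt
from .crosslinks import CrosslinkTrack, crosslink_bed_to_events, dedup_umis
from .peakcalling import PipelineParams, PeakSet, call_peaks
from .simulate import (ProteinModel, SimulationConfig, SimulatedTruth,
                       generate_genome_and_annotation, simulate_iclip,
                       simulate_rnaseq)
from .sites import HighConfSite, btz_marking_stats, merge_high_confidence


def simulate_tracks(cfg: SimulationConfig, proteins: list[str] | None = None):
    """Simulate genome + one deduplicated track per protein library."""
    genome, ann, truth = generate_genome_and_annotation(cfg)
    tracks: dict[str, CrosslinkTrack] = {}
    for protein in proteins or list(cfg.proteins):
        raw = simulate_iclip(cfg, ann, truth, protein)
        tracks[protein] = dedup_umis(crosslink_bed_to_events(raw), library_id=protein)
    return genome, ann, truth, tracks


def call_peaksets(tracks, ann, params: PipelineParams, seed: int) -> dict[str, PeakSet]:
    """Permutation peak calling per library, one derived seed per protein."""
    out = {}
    for i, (protein, track) in enumerate(sorted(tracks.items())):
        p = replace(params, rng_seed=(seed + 1000 * (i + 1)) % (2**31))
        out[protein] = call_peaks(track, ann, p, protein=protein)
    return out


def canonical_site_fraction(sites: list[HighConfSite], ann) -> float:
    """Fraction of sites whose summit sits 20-24 nt upstream of a junction."""
    junctions = {(c, s, j) for c, s, j, _ in ann.junctions()}
    if not sites:
        return float("nan")
    hit = 0
    for s in sites:
        p = s.summit if s.summit is not None else (s.start + s.end - 1) // 2
        if s.strand == "+":
            ok = any((s.chrom, "+", p + d) in junctions for d in range(20, 25))
        else:
            ok = any((s.chrom, "-", p - d) in junctions for d in range(20, 25))
        hit += ok
    return hit / len(sites)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def fdr_calibration_experiment(
    seed: int,
    n_genes: int = 200,
    n_events: int = 40_000,
    n_perm: int = 100,
) -> dict:
    """Realized false-discovery proportion of the permutation peak caller.

    One EJC-like library over ``n_genes`` genes with deposition planted at
    half of the junction-bearing exon ends and uniform background at 1:1
    signal:noise. A called peak is false when its interval overlaps no
    planted deposition window.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        deposit_fraction=0.5,
        noise_fraction=0.5,
        n_events=n_events,
        proteins={"BTZ": ProteinModel("ejc")},
    )
    genome, ann, truth, tracks = simulate_tracks(cfg, ["BTZ"])
    params = PipelineParams(n_perm=n_perm, rng_seed=seed % (2**31))
    peaks = call_peaks(tracks["BTZ"], ann, params, protein="BTZ")

    windows = truth.window_set()
    n_false = 0
    for p in peaks:
        if not any((p.chrom, p.strand, q) in windows for q in range(p.start, p.end)):
            n_false += 1
    n_called = len(peaks)
    fdp = n_false / n_called if n_called else 0.0
    mc_sd = float(np.sqrt(max(fdp * (1 - fdp), 1e-12) / n_called)) if n_called else 0.0
    return {
        "fdp_pct": 100.0 * fdp,
        "n_called": n_called,
        "n_false": n_false,
        "mc_sd_pct": 100.0 * mc_sd,
        "nominal_pct": 100.0 * params.fdr_threshold,
    }


def ejc_pipeline_experiment(
    seed: int,
    n_genes: int = 60,
    n_events: int = 30_000,
    n_perm: int = 100,
) -> dict:
    """Full integration run: four EJC-like libraries plus GFP background.

    Simulates shared deposition at -24..-20 with moderate uniform noise and
    PCR duplicates, calls peaks per protein, merges >= 2-protein sites with
    the GFP filter, and profiles 5mers around the BTZ peaks. Returns the
    site statistics, the canonical-position fraction, and the motif
    summaries (top GT motifs in the downstream donor window and their
    assembled consensus).
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        n_events=n_events,
        proteins={
            "BTZ": ProteinModel("ejc", 0.0),
            "eIF4A3": ProteinModel("ejc", 0.10),
            "UPF3B": ProteinModel("ejc", 0.10),
            "RNPS1": ProteinModel("ejc", 0.15),
            "GFP": ProteinModel("uniform"),
        },
    )
    genome, ann, truth, tracks = simulate_tracks(cfg)
    params = PipelineParams(n_perm=n_perm, rng_seed=seed % (2**31))
    peaksets = call_peaksets(tracks, ann, params, seed)
    gfp_peaks = peaksets.pop("GFP")
    gfp_track = tracks["GFP"]

    sites = merge_high_confidence(
        peaksets, gfp_peaks=gfp_peaks,
        tracks={k: tracks[k] for k in peaksets}, gfp_track=gfp_track,
    )
    n_sites, n_btz, btz_fraction = btz_marking_stats(sites)
    canon = canonical_site_fraction(sites, ann)

    profiles = mt.build_kmer_profiles(
        peaksets["BTZ"], ann, genome, params, seed=(seed + 77) % (2**31)
    )
    # GT-containing 5mers ranked by occurrences in the downstream donor
    # window (junction sits ~20-24 nt 3' of the deposition site)
    W = params.kmer_norm_window
    win = slice(W + 15, W + 31)
    down_counts = profiles.pos[:, win].sum(axis=1)
    gt_idx = np.nonzero(profiles.gt_mask)[0]
    top_gt = [
        mt.ALL_KMERS[i]
        for i in sorted(gt_idx, key=lambda i: -down_counts[i])[:3]
    ]
    consensus, merged = mt.assemble_overlapping_kmers(top_gt)

    return {
        "genome": genome,
        "ann": ann,
        "truth": truth,
        "tracks": tracks,
        "peaksets": peaksets,
        "gfp_peaks": gfp_peaks,
        "sites": sites,
        "n_sites": n_sites,
        "n_btz": n_btz,
        "btz_fraction": btz_fraction,
        "canonical_fraction": canon,
        "canonical_pct": 100.0 * canon,
        "kmer_profiles": profiles,
        "top_gt_downstream": top_gt,
        "donor_consensus": consensus,
        "donor_assembled": merged,
    }
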