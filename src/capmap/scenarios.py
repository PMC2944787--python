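"""Canned simulation scenarios and the on-disk fixture bundle writer.

Each scenario builds a genome, gene models, ground-truth CGI records and a
set of assay tracks in memory; ``write_fixture_bundle`` serialises a
scenario to FASTA/GTF/WIG/TSV with a manifest of checksums. Scenario
defaults are the study conditions every other module is tested against
(2 Mb genome, ~100 planted ~1 kb islands, mean depth 5 reads/bp).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (
    CAP_STRINGENCY_MID_HIGH,
    CAP_STRINGENCY_MID_LOW,
    AssayParams,
    TruthRecord,
    assign_methylation,
    gen_background_genome,
    gen_gene_models,
    plant_islands,
    simulate_cap_stringency_pair,
    simulate_track,
)
from .track_io import DepthTrack, GeneModel, write_fasta, write_gtf, write_wig

SOMATIC_TISSUES = ("blood", "cerebellum")
GERMLINE = "sperm"


@dataclass
class SimBundle:
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: list[TruthRecord]
    tracks: dict[str, DepthTrack] = field(default_factory=dict)  # keyed "assay/tissue[/rep]"
    config: dict = field(default_factory=dict)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _mixed_oe_dist(rng_frac_poor: float = 0.15):
    """Island o/e population: mostly CpG-rich (~1 CpG/10 bp), with a
    CpG-poor tail (o/e 0.24-0.32) emulating the relatively CpG-deficient
    islands that only the relaxed wash recovers."""

    def draw(r: np.random.Generator) -> float:
        if r.random() < rng_frac_poor:
            return float(r.uniform(0.24, 0.32))
        return float(np.clip(r.normal(0.80, 0.10), 0.62, 1.10))

    return draw


def default_scenario(
    seed: int = 0,
    genome_length: int = 2_000_000,
    n_islands: int = 100,
    n_genes: int = 60,
    mean_depth: float = 5.0,
) -> SimBundle:
    """The reference desk-scale study: three tissues (sperm germline, blood,
    cerebellum), CAP at both wash stringencies plus a technical replicate,
    and MAP for differential-methylation calling."""
    rng_genome, rng_genes, rng_islands, rng_meth, rng_tracks = _rngs(seed, 5)
    genome = gen_background_genome(genome_length, rng=rng_genome)
    genes = gen_gene_models({c: len(s) for c, s in genome.items()}, n_genes, rng_genes,
                            min_len=8_000, max_len=20_000)
    genome, truth = plant_islands(
        genome, n_islands, rng_islands, genes, oe_dist=_mixed_oe_dist()
    )
    tissues = (GERMLINE,) + SOMATIC_TISSUES
    assign_methylation(truth, tissues, rng_meth)

    cap_low = AssayParams("CAP", mean_depth=mean_depth,
                          cap_stringency_mid=CAP_STRINGENCY_MID_LOW)
    cap_high = AssayParams("CAP", mean_depth=mean_depth,
                           cap_stringency_mid=CAP_STRINGENCY_MID_HIGH)
    map_p = AssayParams("MAP", mean_depth=mean_depth)

    tracks: dict[str, DepthTrack] = {}
    for tissue in tissues:
        low, high = simulate_cap_stringency_pair(genome, truth, cap_low, cap_high,
                                                 tissue, rng_tracks)
        tracks[f"CAP/{tissue}"] = low
        tracks[f"CAP_high/{tissue}"] = high
        tracks[f"MAP/{tissue}"] = simulate_track(genome, truth, map_p, tissue, rng_tracks)
    # technical replicate of the germline CAP (same rates, independent draw)
    rep, _ = simulate_cap_stringency_pair(genome, truth, cap_low, cap_high,
                                          GERMLINE, rng_tracks)
    tracks[f"CAP/{GERMLINE}/rep2"] = rep
    return SimBundle(genome, genes, truth, tracks,
                     {"scenario": "default", "seed": seed, "genome_length": genome_length,
                      "n_islands": n_islands, "mean_depth": mean_depth})


def density_scenario(
    seed: int = 0,
    genome_length: int = 1_200_000,
    islands_per_bin: int = 15,
) -> SimBundle:
    """Islands spanning the six CpG-density bins, with an H3K4me3 track whose
    signal is linear in CpG density (all islands unmethylated)."""
    rng_genome, rng_islands, rng_tracks = _rngs(seed, 3)
    genome = gen_background_genome(genome_length, rng=rng_genome)
    # o/e targets whose expected densities sit mid-bin (per100 ~ 10.56 * oe at 65% G+C)
    targets = [0.33, 0.52, 0.62, 0.71, 0.80, 1.00]
    draws = [t for t in targets for _ in range(islands_per_bin)]
    it = iter(draws)
    genome, truth = plant_islands(
        genome, len(draws), rng_islands, (),
        class_mix=(0.0, 0.0, 1.0),
        oe_dist=lambda r: next(it),
        length_dist=lambda r: 1000,
    )
    for rec in truth:
        rec.meth["es"] = False
        rec.active["es"] = True
    k4 = AssayParams("H3K4me3", k4_gain=0.5)
    tracks = {"H3K4me3/es": simulate_track(genome, truth, k4, "es", rng_tracks)}
    return SimBundle(genome, [], truth, tracks,
                     {"scenario": "density", "seed": seed})


def x_inactivation_scenario(
    seed: int = 0,
    genome_length: int = 400_000,
    n_islands: int = 30,
    n_female_methylated: int = 10,
) -> SimBundle:
    """A block of CGIs methylated in the female sample only — the
    calibration fixture for the differential-methylation caller."""
    rng_genome, rng_islands, rng_pick, rng_tracks = _rngs(seed, 4)
    genome = gen_background_genome(genome_length, rng=rng_genome, chrom="chrX")
    genome, truth = plant_islands(genome, n_islands, rng_islands, (),
                                  class_mix=(0.0, 0.0, 1.0))
    flagged = rng_pick.choice(n_islands, size=n_female_methylated, replace=False)
    for i, rec in enumerate(truth):
        xi = i in flagged
        rec.flags["x_inactivated"] = xi
        for tissue, meth in ((GERMLINE, False), ("female", xi), ("male", False)):
            rec.meth[tissue] = meth
            rec.active[tissue] = not meth
    map_p = AssayParams("MAP")
    tracks = {
        f"MAP/{t}": simulate_track(genome, truth, map_p, t, rng_tracks)
        for t in (GERMLINE, "female", "male")
    }
    return SimBundle(genome, [], truth, tracks, {"scenario": "x_inactivation", "seed": seed})


def tumour_scenario(
    seed: int = 0,
    genome_length: int = 1_000_000,
    n_islands: int = 60,
    n_tumour_specific: int = 12,
    n_shared: int = 10,
    n_pairs: int = 5,
    polycomb_rate_background: float = 0.15,
    polycomb_rate_tumour_specific: float = 0.60,
) -> SimBundle:
    """Five matched normal-mucosa / tumour MAP pairs plus the germline
    reference. Tumour-specifically methylated CGIs are planted methylated
    in >= 3 of 5 tumours and no normals, preferentially at
    polycomb-flagged (embryonic H3K27me3) CGIs."""
    rng_genome, rng_islands, rng_assign, rng_tracks = _rngs(seed, 4)
    genome = gen_background_genome(genome_length, rng=rng_genome)
    genome, truth = plant_islands(genome, n_islands, rng_islands, (),
                                  class_mix=(0.0, 0.0, 1.0))
    normals = [f"C{i}" for i in range(1, n_pairs + 1)]
    tumours = [f"T{i}" for i in range(1, n_pairs + 1)]
    order = rng_assign.permutation(n_islands)
    ts_ids = set(order[:n_tumour_specific])
    shared_ids = set(order[n_tumour_specific : n_tumour_specific + n_shared])
    for i, rec in enumerate(truth):
        rec.meth[GERMLINE] = False
        rec.active[GERMLINE] = True
        if i in ts_ids:
            n_meth = int(rng_assign.integers(3, n_pairs + 1))
            meth_t = set(rng_assign.choice(n_pairs, size=n_meth, replace=False))
            for j, t in enumerate(tumours):
                rec.meth[t] = j in meth_t
            for c in normals:
                rec.meth[c] = False
            p_flag = polycomb_rate_tumour_specific
        elif i in shared_ids:
            n_meth = int(rng_assign.integers(1, n_pairs + 1))
            meth_n = set(rng_assign.choice(n_pairs, size=n_meth, replace=False))
            for j, c in enumerate(normals):
                rec.meth[c] = j in meth_n
            for t in tumours:  # methylation of normal tissue is retained in the tumour
                rec.meth[t] = True
            p_flag = polycomb_rate_background
        else:
            for s in normals + tumours:
                rec.meth[s] = False
            p_flag = polycomb_rate_background
        rec.flags["tumour_specific"] = i in ts_ids
        rec.flags["H3K27me3"] = bool(rng_assign.random() < p_flag)
        for s in normals + tumours:
            rec.active[s] = not rec.meth[s]
    map_p = AssayParams("MAP")
    tracks = {
        f"MAP/{s}": simulate_track(genome, truth, map_p, s, rng_tracks)
        for s in [GERMLINE] + normals + tumours
    }
    return SimBundle(genome, [], truth, tracks,
                     {"scenario": "tumour_cohort", "seed": seed,
                      "normals": normals, "tumours": tumours})


def two_species_scenario(seed: int = 0, genome_length: int = 600_000) -> SimBundle:
    """Two CGI populations with shifted o/e distributions (human-like vs the
    lower-density mouse-like set); used for the composition contrast."""
    rng_a, rng_b = _rngs(seed, 2)
    out = {}
    for label, mean_oe, rng in (("human", 0.82, rng_a), ("mouse", 0.68, rng_b)):
        genome = gen_background_genome(genome_length, rng=rng, chrom=f"{label}_chr1")
        genome, truth = plant_islands(
            genome, 40, rng, (), class_mix=(0.0, 0.0, 1.0),
            oe_dist=lambda r, m=mean_oe: float(np.clip(r.normal(m, 0.10), 0.35, 1.10)),
        )
        out[label] = (genome, truth)
    genome = {**out["human"][0], **out["mouse"][0]}
    truth = out["human"][1] + out["mouse"][1]
    for rec, label in zip(truth, ["human"] * 40 + ["mouse"] * 40):
        rec.flags["species"] = label == "human"
    return SimBundle(genome, [], truth, {}, {"scenario": "two_species", "seed": seed})


SCENARIOS = {
    "default": default_scenario,
    "density": density_scenario,
    "x_inactivation": x_inactivation_scenario,
    "tumour_cohort": tumour_scenario,
    "two_species": two_species_scenario,
}


def truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for rec in truth:
        row = {
            "cgi": rec.interval.name,
            "chrom": rec.interval.chrom,
            "start": rec.interval.start,
            "end": rec.interval.end,
            "class": rec.cgi_class,
            "target_oe": rec.target_oe,
            "per100": rec.per100,
        }
        row.update({f"meth_{t}": v for t, v in rec.meth.items()})
        row.update({f"active_{t}": v for t, v in rec.active.items()})
        row.update({f"flag_{k}": v for k, v in rec.flags.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_fixture_bundle(
    outdir, scenario: str = "default", seed: int = 0, force: bool = False, **kwargs
) -> dict:
    """Serialise a scenario to FASTA + GTF + truth TSV + per-track WIGs,
    with a manifest recording the configuration and file checksums.
    Refuses a non-empty output directory unless ``force``."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (pass force=True to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = SCENARIOS[scenario](seed=seed, **kwargs)

    files = {}
    write_fasta(bundle.genome, outdir / "genome.fa")
    files["genome.fa"] = None
    if bundle.genes:
        write_gtf(bundle.genes, outdir / "genes.gtf")
        files["genes.gtf"] = None
    truth_frame(bundle.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    files["truth.tsv"] = None
    for key, track in bundle.tracks.items():
        fname = key.replace("/", "_") + ".wig"
        write_wig(track, outdir / fname, name=key)
        files[fname] = None
    for fname in files:
        files[fname] = hashlib.sha256((outdir / fname).read_bytes()).hexdigest()
    manifest = {"scenario": scenario, "seed": seed, "config": bundle.config, "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
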