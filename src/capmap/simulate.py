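"""Synthetic genomes and enrichment tracks with the statistical structure
the analysis assumes.

The background genome is a first-order Markov base chain whose C->G
transition is damped so the whole-sequence CpG o/e hits a target
(bulk-genome default 0.21 at 40% G+C). CpG islands are planted as ~1 kb
Markov segments at elevated G+C (0.65) and island-level o/e, placed to
realise a requested positional class against planted gene models.
Methylation states are drawn per (CGI, somatic tissue) with class-specific
rates; the germline is always unmethylated.

Assay tracks are simulated by tiling the genome into fragments and drawing
per-base Poisson depth at a fragment-level rate:

* CAP retains fragments by a logistic function of unmethylated-CpG density
  (CpGs/100 bp); the logistic midpoint abstracts the salt-wash stringency
  (high-stringency wash keeps only denser islands than the relaxed wash).
* MAP retains fragments whose methyl-CpG density reaches ~1 meCpG/100 bp;
  the bulk genome is methylated at 75% of its CpGs, a heavily methylated
  CGI at 90%.
* H3K4me3 signal grows linearly with CpG density at unmethylated CGIs.
* RNAPII marks CGIs with promoter activity in the simulated tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .cgi_annotation import GeneIndex, classify_cgi
from .cpg_metrics import cpg_stats
from .intervals import GenomeInterval
from .track_io import DepthTrack, GeneModel

BASES = "ACGT"
_A, _C, _G, _T = range(4)

#: fraction of bulk-genome CpGs carrying methylation (midpoint of the
#: 70-80% typical of mammalian somatic DNA)
BULK_METH_FRACTION = 0.75
#: fraction of CpGs methylated within a CGI scored as methylated
CGI_METH_FRACTION = 0.90

DEFAULT_CLASS_METH_RATES = {"ATSS": 0.03, "Intragenic": 0.24, "Intergenic": 0.14}
DEFAULT_CLASS_MIX = (0.48, 0.26, 0.26)  # ATSS, Intragenic, Intergenic


@dataclass
class TruthRecord:
    """Ground truth for one planted CGI."""

    interval: GenomeInterval
    target_oe: float
    per100: float  # realised CpGs per 100 bp of the planted sequence
    cgi_class: str
    meth: dict[str, bool] = field(default_factory=dict)  # per-tissue methylation
    active: dict[str, bool] = field(default_factory=dict)  # per-tissue promoter activity
    flags: dict[str, bool] = field(default_factory=dict)  # e.g. H3K27me3, X-inactivation


@dataclass(frozen=True)
class AssayParams:
    """Per-assay simulation parameters.

    fragment_len: tiling fragment size (bp); mean_depth: reads/bp over a
    fully retained fragment; cap_stringency_mid: unmethylated-CpG density
    (CpGs/100 bp) at 50% CAP retention — high-stringency default 5.0, the
    relaxed wash 3.5; cap_slope: logistic steepness (CpGs/100 bp);
    map_min_density: methyl-CpG density needed for MAP retention;
    k4_gain: H3K4me3 reads/bp per unit CpG density; background_depth:
    off-target reads/bp.
    """

    assay: str  # CAP | MAP | H3K4me3 | RNAPII
    fragment_len: int = 500
    mean_depth: float = 5.0
    cap_stringency_mid: float = 5.0
    cap_slope: float = 1.0
    map_min_density: float = 1.0
    k4_gain: float = 0.5
    background_depth: float = 0.1

    def __post_init__(self) -> None:
        if self.assay not in ("CAP", "MAP", "H3K4me3", "RNAPII"):
            raise ValueError(f"unknown assay {self.assay!r}")
        for name in ("fragment_len", "mean_depth", "cap_slope", "map_min_density",
                     "k4_gain", "background_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


CAP_STRINGENCY_MID_HIGH = 5.0  # 600 mM-like wash
CAP_STRINGENCY_MID_LOW = 3.5   # relaxed 560 mM-like wash


# ---------------------------------------------------------------------------
# sequence generation


def _markov_matrix(gc: float, cpg_oe: float, iters: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix whose stationary chain hits (gc, cpg_oe).

    All rows equal a base distribution q except the C row, where the C->G
    probability is damped so the realised o/e (= T[C,G] / piG) equals the
    target; q is corrected by fixed-point iteration so the stationary
    composition still matches the requested G+C.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if cpg_oe <= 0:
        raise ValueError("cpg_oe must be > 0")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    q = p.copy()
    g_cg = cpg_oe * p[_G]
    for _ in range(iters):
        T = np.tile(q, (4, 1))
        row_c = q.copy()
        if g_cg >= 1.0:
            raise ValueError(f"infeasible (gc={gc}, cpg_oe={cpg_oe}): damped C->G >= 1; "
                             "reduce cpg_oe or gc")
        row_c[_G] = g_cg
        others = [_A, _C, _T]
        row_c[others] = q[others] * (1 - g_cg) / (1 - q[_G])
        T[_C] = row_c
        # stationary distribution
        evals, evecs = np.linalg.eig(T.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = np.abs(pi) / np.abs(pi).sum()
        g_cg = cpg_oe * pi[_G]
        q = np.clip(q + (p - pi), 1e-6, None)
        q /= q.sum()
    return T, pi


def markov_sequence(length: int, gc: float, cpg_oe: float, rng: np.random.Generator) -> str:
    """Generate a Markov base sequence with target composition. Deterministic per rng state."""
    T, pi = _markov_matrix(gc, cpg_oe)
    cum = np.cumsum(T, axis=1)
    rows = [(float(c[0]), float(c[1]), float(c[2])) for c in cum]
    u = rng.random(length)
    state = int(rng.choice(4, p=pi))
    out = bytearray(length)
    bases = b"ACGT"
    for i in range(length):
        ui = u[i]
        c0, c1, c2 = rows[state]
        state = 0 if ui < c0 else 1 if ui < c1 else 2 if ui < c2 else 3
        out[i] = bases[state]
    return out.decode("ascii")


def gen_background_genome(
    length: int,
    gc: float = 0.40,
    cpg_oe: float = 0.21,
    rng: np.random.Generator | int | None = None,
    chrom: str = "chr1",
) -> dict[str, str]:
    """A single-chromosome background genome at bulk-genome composition."""
    if length < 10_000:
        raise ValueError("length must be >= 10,000")
    rng = np.random.default_rng(rng)
    return {chrom: markov_sequence(length, gc, cpg_oe, rng)}


# ---------------------------------------------------------------------------
# island planting


def plant_islands(
    genome: Mapping[str, str],
    n: int,
    rng: np.random.Generator,
    gene_models: Sequence[GeneModel] = (),
    class_mix: Sequence[float] = DEFAULT_CLASS_MIX,
    oe_dist: Callable[[np.random.Generator], float] | None = None,
    length_dist: Callable[[np.random.Generator], int] | None = None,
    island_gc: float = 0.65,
    min_gap: int = 2000,
    flank: int = 100,
    max_tries: int = 400,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Replace ``n`` non-overlapping genome segments with CGI-like sequence.

    Island lengths default to ~1 kb (Normal(1000, 150) clipped to
    [400, 1600]); island o/e defaults to a CpG-rich population
    (Normal(0.8, 0.1) clipped to [0.62, 1.1], about 1 CpG per 10 bp at 65%
    G+C). Placement honours the requested positional class against the
    supplied gene models and is verified with the classifier itself, so
    planted classes are reproduced exactly. Raises when a class cannot be
    placed within ``max_tries`` attempts, reporting achieved counts.
    """
    mix = np.asarray(class_mix, dtype=float)
    if not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must sum to 1")
    if oe_dist is None:
        oe_dist = lambda r: float(np.clip(r.normal(0.80, 0.10), 0.62, 1.10))
    if length_dist is None:
        length_dist = lambda r: int(np.clip(r.normal(1000, 150), 400, 1600))

    counts = np.floor(mix * n).astype(int)
    for i in np.argsort(-(mix * n - counts))[: n - counts.sum()]:
        counts[i] += 1
    wanted = [c for cls, k in zip(("ATSS", "Intragenic", "Intergenic"), counts) for c in [cls] * k]
    rng.shuffle(wanted)

    index = GeneIndex(gene_models)
    genome_out = {c: bytearray(s, "ascii") for c, s in genome.items()}
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    chroms = sorted(genome)
    placed: list[GenomeInterval] = []
    truth: list[TruthRecord] = []

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)

    def clashes(iv: GenomeInterval) -> bool:
        return any(
            p.chrom == iv.chrom and iv.distance(p) is not None and iv.distance(p) < min_gap
            for p in placed
        )

    for i, cls in enumerate(wanted):
        length = length_dist(rng)
        target_oe = oe_dist(rng)
        ok = False
        for _ in range(max_tries):
            if cls == "ATSS" and gene_models:
                gene = gene_models[int(rng.integers(len(gene_models)))]
                tss = gene.tss
                off = int(rng.integers(flank, max(flank + 1, length - flank)))
                start = tss - off
                chrom = gene.interval.chrom
            elif cls == "Intragenic" and gene_models:
                gene = gene_models[int(rng.integers(len(gene_models)))]
                giv = gene.interval
                pad = flank + 200
                lo = giv.start + pad if giv.strand == "-" else gene.tss + pad
                hi = giv.end - pad - length if giv.strand == "+" else gene.tss - pad - length
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                chrom = giv.chrom
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, max(1, chrom_lengths[chrom] - length)))
            end = start + length
            if start < flank or end > chrom_lengths[chrom] - flank:
                continue
            iv = GenomeInterval(chrom, start, end, name=f"cgi_{i:04d}")
            if clashes(iv):
                continue
            if classify_cgi(iv, index, flank) != cls:
                continue
            ok = True
            break
        if not ok:
            achieved = {c: sum(t.cgi_class == c for t in truth) for c in ("ATSS", "Intragenic", "Intergenic")}
            raise RuntimeError(
                f"could not place a {cls} island after {max_tries} tries; achieved {achieved}"
            )
        # resample until the realised o/e is close to target, so truth
        # labels are faithful at 1 kb scale
        for _ in range(50):
            seq = markov_sequence(length, island_gc, target_oe, rng)
            realised = cpg_stats(seq).oe
            if realised is not None and abs(realised - target_oe) <= 0.10:
                break
        genome_out[chrom][start:end] = seq.encode("ascii")
        placed.append(iv)
        truth.append(
            TruthRecord(iv, target_oe, cpg_stats(seq).per100, cls)
        )
    return {c: bytes(s).decode("ascii") for c, s in genome_out.items()}, truth


def assign_methylation(
    truth: Sequence[TruthRecord],
    tissues: Sequence[str],
    rng: np.random.Generator,
    class_rates: Mapping[str, float] = DEFAULT_CLASS_METH_RATES,
    germline: Sequence[str] = ("sperm",),
    activity_rate: float = 0.8,
) -> list[TruthRecord]:
    """Draw per-(CGI, tissue) methylation states in place.

    Somatic tissues methylate independently with class-specific rates
    (defaults: ATSS 3%, intragenic 24%, intergenic 14%); germline tissues
    are forced unmethylated. A tissue is "active" at a CGI (RNAPII
    recruitment) only when unmethylated, with probability
    ``activity_rate``.
    """
    if len(set(tissues)) != len(tissues):
        raise ValueError("tissue names must be unique")
    for cls, rate in class_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"rate for {cls} outside [0, 1]")
    for rec in truth:
        for tissue in tissues:
            if tissue in germline:
                rec.meth[tissue] = False
            else:
                rec.meth[tissue] = bool(rng.random() < class_rates.get(rec.cgi_class, 0.0))
            rec.active[tissue] = (not rec.meth[tissue]) and bool(rng.random() < activity_rate)
    return list(truth)


# ---------------------------------------------------------------------------
# track simulation


def _fragment_rates(
    genome: Mapping[str, str],
    truth: Sequence[TruthRecord],
    params: AssayParams,
    tissue: str,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (tile boundaries, Poisson rate per tile)."""
    flen = params.fragment_len
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = len(arr)
        cpg_pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        n_tiles = int(np.ceil(n / flen))
        counts = np.bincount(cpg_pos // flen, minlength=n_tiles).astype(float)
        tile_len = np.full(n_tiles, flen, dtype=float)
        if n % flen:
            tile_len[-1] = n % flen
        density = 100.0 * counts / tile_len

        # which island (if any) covers each tile, and its states
        island_meth = np.zeros(n_tiles, dtype=bool)
        island_active = np.zeros(n_tiles, dtype=bool)
        in_island = np.zeros(n_tiles, dtype=bool)
        for rec in truth:
            if rec.interval.chrom != chrom:
                continue
            t0 = rec.interval.start // flen
            t1 = (rec.interval.end - 1) // flen + 1
            in_island[t0:t1] = True
            island_meth[t0:t1] = rec.meth.get(tissue, False)
            island_active[t0:t1] = rec.active.get(tissue, False)

        if params.assay == "CAP":
            unmeth_frac = np.where(
                in_island,
                np.where(island_meth, 1 - CGI_METH_FRACTION, 1.0),
                1 - BULK_METH_FRACTION,
            )
            u_density = density * unmeth_frac
            retention = 1.0 / (
                1.0 + np.exp(-(u_density - params.cap_stringency_mid) / params.cap_slope)
            )
            rate = params.mean_depth * retention
        elif params.assay == "MAP":
            meth_frac = np.where(
                in_island,
                np.where(island_meth, CGI_METH_FRACTION, 0.0),
                BULK_METH_FRACTION,
            )
            m_density = density * meth_frac
            rate = params.mean_depth * (m_density >= params.map_min_density)
        elif params.assay == "H3K4me3":
            rate = np.where(in_island & ~island_meth, params.k4_gain * density, 0.0)
        else:  # RNAPII
            rate = np.where(island_active, params.mean_depth, 0.0)
        out[chrom] = (tile_len.astype(int), rate + params.background_depth)
    return out


def simulate_track(
    genome: Mapping[str, str],
    truth: Sequence[TruthRecord],
    params: AssayParams,
    tissue: str,
    rng: np.random.Generator,
) -> DepthTrack:
    """Poisson depth track for one assay in one tissue. Deterministic per rng."""
    data = {}
    for chrom, (tile_len, rate) in _fragment_rates(genome, truth, params, tissue).items():
        per_base_rate = np.repeat(rate, tile_len)
        data[chrom] = rng.poisson(per_base_rate).astype(float)
    return DepthTrack(data)


def simulate_cap_stringency_pair(
    genome: Mapping[str, str],
    truth: Sequence[TruthRecord],
    params_low: AssayParams,
    params_high: AssayParams,
    tissue: str,
    rng: np.random.Generator,
) -> tuple[DepthTrack, DepthTrack]:
    """Coupled low/high-stringency CAP tracks from the same fragment pool.

    The high-stringency track is a binomial thinning of the low-stringency
    draw, mirroring the physical process (the stringent wash keeps a subset
    of the fragments the relaxed wash keeps). Marginally both tracks are
    Poisson at their own rates, and per-base depth is pointwise nested
    (high <= low), so called peak coverage is nested deterministically.
    """
    if params_low.cap_stringency_mid >= params_high.cap_stringency_mid:
        raise ValueError("low-stringency midpoint must be below high-stringency midpoint")
    rates_low = _fragment_rates(genome, truth, params_low, tissue)
    rates_high = _fragment_rates(genome, truth, params_high, tissue)
    low_data, high_data = {}, {}
    for chrom in rates_low:
        tile_len, r_low = rates_low[chrom]
        _, r_high = rates_high[chrom]
        lam_low = np.repeat(r_low, tile_len)
        lam_high = np.repeat(r_high, tile_len)
        n_low = rng.poisson(lam_low)
        keep = np.divide(lam_high, lam_low, out=np.zeros_like(lam_low), where=lam_low > 0)
        n_high = rng.binomial(n_low, np.clip(keep, 0, 1))
        low_data[chrom] = n_low.astype(float)
        high_data[chrom] = n_high.astype(float)
    return DepthTrack(low_data), DepthTrack(high_data)


# ---------------------------------------------------------------------------
# gene models


def gen_gene_models(
    chrom_lengths: Mapping[str, int],
    n_genes: int,
    rng: np.random.Generator,
    min_len: int = 10_000,
    max_len: int = 40_000,
    min_gap: int = 5_000,
) -> list[GeneModel]:
    """Random non-overlapping stranded gene bodies for island placement."""
    genes: list[GeneModel] = []
    chroms = sorted(chrom_lengths)
    tries = 0
    while len(genes) < n_genes and tries < 100 * n_genes:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(min_len, max_len))
        if chrom_lengths[chrom] <= length + 2 * min_gap:
            continue
        start = int(rng.integers(min_gap, chrom_lengths[chrom] - length - min_gap))
        iv = GenomeInterval(chrom, start, start + length, "+" if rng.random() < 0.5 else "-")
        if any(
            g.interval.chrom == chrom and g.interval.distance(iv) < min_gap for g in genes
        ):
            continue
        gid = f"gene_{len(genes):03d}"
        genes.append(GeneModel(GenomeInterval(iv.chrom, iv.start, iv.end, iv.strand, gid), gid))
    if len(genes) < n_genes:
        raise RuntimeError(f"could only place {len(genes)} of {n_genes} genes")
    return genes
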