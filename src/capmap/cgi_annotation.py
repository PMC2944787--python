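"""Positional classification of CGIs and intersection with feature peak sets.

A CGI is promoter-associated (ATSS) when, extended by a flank (default
100 bp) on each side, it contains the transcription start site of an
annotated gene; otherwise it is Intragenic if the extended interval
overlaps any gene body, else Intergenic. ATSS takes precedence over
Intragenic and "orphan" denotes any non-ATSS CGI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cpg_metrics import CpgStats
from .intervals import GenomeInterval
from .track_io import GeneModel

CLASSES = ("ATSS", "Intragenic", "Intergenic")
DEFAULT_FLANK = 100


@dataclass
class CgiRecord:
    """A CGI with its positional class, CpG metrics, feature flags and
    per-sample differential-methylation scores."""

    interval: GenomeInterval
    cgi_class: str
    cpg: CpgStats | None = None
    feature_flags: dict[str, bool] = field(default_factory=dict)
    dm_scores: dict[str, int] = field(default_factory=dict)

    @property
    def orphan(self) -> bool:
        return self.cgi_class != "ATSS"


class GeneIndex:
    """Overlap index over gene bodies and TSS positions, per chromosome."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.bodies: dict[str, IntervalTree] = {}
        self.tss: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[int]] = {}
        for g in genes:
            iv = g.interval
            self.bodies.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, g)
            by_chrom.setdefault(iv.chrom, []).append(g.tss)
        self.tss = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}

    def tss_in(self, chrom: str, start: int, end: int) -> bool:
        pos = self.tss.get(chrom)
        if pos is None:
            return False
        i = np.searchsorted(pos, start, side="left")
        return i < len(pos) and pos[i] < end

    def overlaps_body(self, chrom: str, start: int, end: int) -> bool:
        tree = self.bodies.get(chrom)
        return bool(tree and tree.overlap(start, end))


def classify_cgi(
    cgi: GenomeInterval,
    genes: Sequence[GeneModel] | GeneIndex,
    flank: int = DEFAULT_FLANK,
) -> str:
    """Classify one CGI as ATSS, Intragenic or Intergenic.

    The CGI extended by ``flank`` bp is tested first for containing any
    gene TSS (-> ATSS), then for overlap with any gene body
    (-> Intragenic); otherwise Intergenic.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    ext = cgi.expand(flank)
    if index.tss_in(ext.chrom, ext.start, ext.end):
        return "ATSS"
    if index.overlaps_body(ext.chrom, ext.start, ext.end):
        return "Intragenic"
    return "Intergenic"


def classify_all(
    cgis: Sequence[GenomeInterval],
    genes: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> list[CgiRecord]:
    index = GeneIndex(genes)
    return [CgiRecord(iv, classify_cgi(iv, index, flank)) for iv in cgis]


def collapse_isoforms(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Keep one model per gene_id: the union span on the majority strand.

    Preprocessing helper for transcript-level annotations; classification
    itself always uses one TSS per supplied model.
    """
    by_id: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_id.setdefault(g.gene_id, []).append(g)
    out = []
    for gid, models in by_id.items():
        chroms = {m.interval.chrom for m in models}
        if len(chroms) > 1:
            raise ValueError(f"gene {gid}: isoforms on multiple chromosomes")
        strand = max(("+", "-"), key=lambda s: sum(m.interval.strand == s for m in models))
        start = min(m.interval.start for m in models)
        end = max(m.interval.end for m in models)
        out.append(GeneModel(GenomeInterval(chroms.pop(), start, end, strand, gid), gid))
    return out


def intersect_features(
    cgis: Sequence[CgiRecord],
    feature_peaks: Sequence[GenomeInterval],
    label: str,
    flank: int = DEFAULT_FLANK,
) -> None:
    """Flag each CGI that, extended by ``flank`` bp, overlaps >= 1 feature
    interval by >= 1 bp. Flags are stored in ``record.feature_flags[label]``."""
    trees: dict[str, IntervalTree] = {}
    for iv in feature_peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    for rec in cgis:
        ext = rec.interval.expand(flank)
        tree = trees.get(ext.chrom)
        rec.feature_flags[label] = bool(tree and tree.overlap(ext.start, ext.end))


def overlap_table(
    cgis: Sequence[CgiRecord],
    flag_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percentage of CGIs carrying each feature flag, per positional class.

    Includes an ``"All"`` column (union across flags) and explicit
    numerators/denominators. Empty classes report NaN percentages.
    """
    if flag_columns is None:
        flag_columns = sorted({k for rec in cgis for k in rec.feature_flags})
    rows = []
    for cls in CLASSES:
        members = [rec for rec in cgis if rec.cgi_class == cls]
        denom = len(members)
        for col in list(flag_columns) + ["All"]:
            if col == "All":
                n = sum(any(rec.feature_flags.get(f, False) for f in flag_columns) for rec in members)
            else:
                n = sum(rec.feature_flags.get(col, False) for rec in members)
            pct = 100.0 * n / denom if denom else float("nan")
            rows.append({"class": cls, "flag": col, "n_flagged": n, "n_total": denom, "pct": pct})
    return pd.DataFrame(rows)


def proximity_fraction(
    query_intervals: Sequence[GenomeInterval],
    cgis: Sequence[GenomeInterval],
    max_dist: int = 100,
) -> float:
    """Fraction of query intervals within ``max_dist`` bp of the nearest CGI.

    Distance is 0 when overlapping; a gap of exactly ``max_dist`` counts
    (inclusive). Queries on chromosomes without any CGI count as distant.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if not cgis:
        raise ValueError("empty CGI set")
    if not query_intervals:
        return 0.0
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {c.chrom for c in cgis}:
        ivs = sorted((c for c in cgis if c.chrom == chrom), key=lambda c: c.start)
        starts[chrom] = np.array([c.start for c in ivs])
        ends[chrom] = np.array([c.end for c in ivs])
    n_close = 0
    for q in query_intervals:
        if q.chrom not in starts:
            continue
        s, e = starts[q.chrom], ends[q.chrom]
        # gap to each CGI; 0 when overlapping
        gap = np.maximum(0, np.maximum(s - q.end, q.start - e))
        if gap.min() <= max_dist:
            n_close += 1
    return n_close / len(query_intervals)
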