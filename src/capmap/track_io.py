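"""Read/write genomic formats and the per-base depth-track data model.

Internally everything is 0-based half-open. WIG files (1-based) and GTF
(1-based closed) are converted on read and on write. Depth is stored as a
real value per base because library-size normalization produces
non-integer depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .intervals import GenomeInterval

log = logging.getLogger(__name__)

SEQUENCE_ALPHABET = frozenset("ACGTN")


class DepthTrack:
    """Per-base non-negative read depth along named chromosomes."""

    def __init__(self, data: Mapping[str, np.ndarray]):
        self.data: dict[str, np.ndarray] = {}
        for chrom, values in data.items():
            arr = np.asarray(values, dtype=np.float64)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: depth values must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{chrom}: depth contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative depth values")
            self.data[chrom] = arr

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def chroms(self) -> list[str]:
        return list(self.data)

    def total(self) -> float:
        """Sum of per-base depth over all chromosomes."""
        return float(sum(v.sum() for v in self.data.values()))

    def scaled(self, factor: float) -> "DepthTrack":
        return DepthTrack({c: v * factor for c, v in self.data.items()})

    def copy(self) -> "DepthTrack":
        return DepthTrack({c: v.copy() for c, v in self.data.items()})

    def slice(self, interval: GenomeInterval) -> np.ndarray:
        return self.data[interval.chrom][interval.start : interval.end]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTrack):
            return NotImplemented
        if set(self.data) != set(other.data):
            return False
        return all(np.array_equal(self.data[c], other.data[c]) for c in self.data)


class WigParseError(ValueError):
    """Raised for malformed WIG content; message names the offending line."""


def read_wig(path, chrom_lengths: Mapping[str, int] | None = None) -> DepthTrack:
    """Parse a fixedStep/variableStep WIG file into a :class:`DepthTrack`.

    WIG positions are 1-based; they are converted to the internal 0-based
    half-open convention. Bases not covered by any record have depth 0.
    Chromosome lengths default to the last covered base unless declared via
    ``chrom_lengths`` or ``#chrom_length <chrom> <len>`` comment lines
    (written by :func:`write_wig`).
    """
    declared: dict[str, int] = dict(chrom_lengths or {})
    # chrom -> list of (start0, end0, value) spans
    spans: dict[str, list[tuple[int, int, float]]] = {}
    mode: str | None = None
    chrom: str | None = None
    step = span = 1
    pos0 = 0  # next 0-based start for fixedStep

    def parse_decl(line: str, lineno: int) -> dict[str, str]:
        fields = {}
        for tok in line.split()[1:]:
            if "=" not in tok:
                raise WigParseError(f"line {lineno}: malformed declaration token {tok!r}")
            k, v = tok.split("=", 1)
            fields[k] = v
        return fields

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#chrom_length"):
                try:
                    _, c, n = line.split()
                    declared[c] = max(declared.get(c, 0), int(n))
                except ValueError as exc:
                    raise WigParseError(f"line {lineno}: bad #chrom_length comment") from exc
                continue
            if line.startswith("#") or line.startswith("track") or line.startswith("browser"):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                fields = parse_decl(line, lineno)
                if "chrom" not in fields:
                    raise WigParseError(f"line {lineno}: declaration missing chrom=")
                mode = line.split()[0]
                chrom = fields["chrom"]
                spans.setdefault(chrom, [])
                try:
                    span = int(fields.get("span", 1))
                    if mode == "fixedStep":
                        start1 = int(fields["start"])
                        step = int(fields.get("step", 1))
                        pos0 = start1 - 1
                except (KeyError, ValueError) as exc:
                    raise WigParseError(f"line {lineno}: malformed {mode} header") from exc
                if span < 1 or (mode == "fixedStep" and (step < 1 or pos0 < 0)):
                    raise WigParseError(f"line {lineno}: non-positive span/step/start")
                continue
            if mode is None:
                raise WigParseError(f"line {lineno}: data before any step declaration")
            toks = line.split()
            try:
                if mode == "fixedStep":
                    if len(toks) != 1:
                        raise ValueError
                    value = float(toks[0])
                    start0 = pos0
                    pos0 += step
                else:
                    if len(toks) != 2:
                        raise ValueError
                    start0 = int(toks[0]) - 1
                    value = float(toks[1])
                    if start0 < 0:
                        raise ValueError
            except ValueError as exc:
                raise WigParseError(f"line {lineno}: malformed {mode} data line") from exc
            if not np.isfinite(value) or value < 0:
                raise WigParseError(f"line {lineno}: negative or non-finite depth {value}")
            assert chrom is not None
            spans[chrom].append((start0, start0 + span, value))

    data: dict[str, np.ndarray] = {}
    for c, recs in spans.items():
        covered = max((e for _, e, _ in recs), default=0)
        length = max(covered, declared.get(c, 0))
        arr = np.zeros(length)
        for s, e, v in recs:
            arr[s:e] = v
        data[c] = arr
    for c, n in declared.items():
        data.setdefault(c, np.zeros(n))
    return DepthTrack(data)


def write_wig(track: DepthTrack, path, name: str = "track") -> None:
    """Write a track as run-length fixedStep WIG blocks.

    Zero runs are omitted (WIG's implicit default on read) and chromosome
    lengths are preserved through ``#chrom_length`` comments, so
    ``read_wig(write_wig(t)) == t`` exactly for exactly-representable
    depths; fractional depths round-trip through ``repr`` and are therefore
    also exact for float64.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom, arr in track.data.items():
            fh.write(f"#chrom_length {chrom} {len(arr)}\n")
            if len(arr) == 0:
                continue
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(f"fixedStep chrom={chrom} start={s + 1} step={e - s} span={e - s}\n")
                fh.write(repr(float(v)) + "\n")


def read_bed(path) -> list[GenomeInterval]:
    """Read BED3/BED6 (0-based half-open). Extra columns are ignored with a warning."""
    out: list[GenomeInterval] = []
    warned = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            if len(cols) > 6 and not warned:
                log.warning("%s: >6 BED columns; columns 7+ ignored", path)
                warned = True
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 else "."
            out.append(GenomeInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: Iterable[GenomeInterval], path) -> None:
    """Write intervals in file order as BED6 (BED3 when no name/strand anywhere)."""
    ivs = list(intervals)
    bed6 = any(iv.name is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if bed6:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into ``{name: sequence}``, uppercased, alphabet {A,C,G,T,N}.

    The key is the first whitespace-delimited header token. Duplicate
    headers and non-IUPAC characters are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            pos = next(i for i, ch in enumerate(seq) if ch in bad)
            raise ValueError(
                f"{path}: record {rec.id}: non-IUPAC character {seq[pos]!r} at position {pos}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval; the TSS is the 5' base of the model."""

    interval: GenomeInterval
    gene_id: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand required for TSS definition")

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1


def read_gtf(path, feature: str = "gene") -> list[GeneModel]:
    """Read gene models from GTF (1-based closed -> 0-based half-open).

    Only rows whose feature column matches ``feature`` are kept; the
    ``gene_id`` attribute is required.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns")
            if cols[2] != feature:
                continue
            chrom, start1, end1, strand, attrs = cols[0], cols[3], cols[4], cols[6], cols[8]
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene_id = item.split(None, 1)[1].strip('"')
            if gene_id is None:
                raise ValueError(f"{path}: line {lineno}: missing gene_id attribute")
            iv = GenomeInterval(chrom, int(start1) - 1, int(end1), strand, gene_id)
            genes.append(GeneModel(iv, gene_id))
    return genes


def write_gtf(genes: Iterable[GeneModel], path, source: str = "capmap") -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


def bin_track(track: DepthTrack, width: int) -> dict[str, np.ndarray]:
    """Mean depth in non-overlapping ``width``-bp windows per chromosome.

    The trailing partial window (shorter than ``width``) is dropped, so the
    output length is ``floor(chrom_length / width)``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    out = {}
    for chrom, arr in track.data.items():
        n = len(arr) // width
        out[chrom] = arr[: n * width].reshape(n, width).mean(axis=1) if n else np.empty(0)
    return out
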