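"""Composite profiles, density-bin summaries, genome-wide correlation and
distribution tests — the figure-level computations, emitted as tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cgi_annotation import CgiRecord
from .cpg_metrics import DENSITY_BIN_LABELS, density_bin
from .intervals import GenomeInterval
from .track_io import DepthTrack, bin_track


@dataclass(frozen=True)
class ProfileParams:
    """span: total width of the profile around each CGI midpoint (bp);
    window/slide: moving-average geometry; central: width of the central
    summary window used for per-bin means."""

    span: int = 5000
    window: int = 500
    slide: int = 100
    central: int = 2000

    def __post_init__(self) -> None:
        if self.window > self.span or self.central > self.span:
            raise ValueError("window and central must not exceed span")


def composite_profile(
    track: DepthTrack,
    intervals: Sequence[GenomeInterval],
    params: ProfileParams = ProfileParams(),
) -> pd.DataFrame:
    """Quantile profile of depth around interval midpoints.

    For each interval, window means are taken at offsets
    -span/2 ... +span/2 (step ``slide``) from the midpoint; the table
    reports median and quartiles across intervals per offset. Windows
    truncated by a chromosome end are omitted for that interval only.
    """
    if not intervals:
        raise ValueError("need at least one interval")
    offsets = np.arange(-params.span // 2, params.span // 2 + 1, params.slide)
    half_w = params.window // 2
    per_offset: list[list[float]] = [[] for _ in offsets]
    for iv in intervals:
        arr = track.data[iv.chrom]
        mid = (iv.start + iv.end) // 2
        for i, off in enumerate(offsets):
            s = mid + off - half_w
            e = s + params.window
            if s < 0 or e > len(arr):
                continue
            per_offset[i].append(float(arr[s:e].mean()))
    rows = []
    for off, vals in zip(offsets, per_offset):
        if vals:
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
        else:
            q25 = med = q75 = np.nan
        rows.append({"offset": int(off), "median": med, "q25": q25, "q75": q75, "n": len(vals)})
    return pd.DataFrame(rows)


def central_mean(track: DepthTrack, interval: GenomeInterval, central: int = 2000) -> float:
    """Mean depth over the central ``central`` bp around the interval midpoint."""
    arr = track.data[interval.chrom]
    mid = (interval.start + interval.end) // 2
    s = max(0, mid - central // 2)
    e = min(len(arr), mid + central // 2)
    return float(arr[s:e].mean())


def density_bin_summary(
    cgis: Sequence[CgiRecord],
    track: DepthTrack,
    params: ProfileParams = ProfileParams(),
) -> pd.DataFrame:
    """Mean central-window depth per CpG-density bin.

    CGIs are grouped by their CpGs-per-100-bp density bin; per bin, the
    mean depth over each CGI's central window is averaged. Bins without
    members report NaN, never 0.
    """
    values: dict[str, list[float]] = {label: [] for label in DENSITY_BIN_LABELS}
    for rec in cgis:
        if rec.cpg is None:
            raise ValueError(f"CGI {rec.interval} lacks CpG stats")
        values[density_bin(rec.cpg.per100)].append(
            central_mean(track, rec.interval, params.central)
        )
    rows = [
        {
            "bin": label,
            "n": len(vals),
            "mean_central_depth": float(np.mean(vals)) if vals else np.nan,
        }
        for label, vals in values.items()
    ]
    return pd.DataFrame(rows)


def pairwise_correlation(
    track_a: DepthTrack,
    track_b: DepthTrack,
    width: int = 1000,
) -> float | None:
    """Pearson r between two tracks over contiguous ``width``-bp window means.

    Windows where both tracks are zero are retained. Returns None when
    either binned vector has zero variance (r undefined).
    """
    if set(track_a.data) != set(track_b.data):
        raise ValueError("tracks cover different chromosome universes")
    a = np.concatenate([bin_track(track_a, width)[c] for c in sorted(track_a.data)])
    b = np.concatenate([bin_track(track_b, width)[c] for c in sorted(track_b.data)])
    if len(a) != len(b):
        raise ValueError("binned vectors differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    if np.array_equal(a, b):
        return 1.0
    return float(stats.pearsonr(a, b).statistic)


def welch_t(sample_x: Sequence[float], sample_y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, Welch-Satterthwaite df, two-sided p).

    Raises on samples smaller than 2 or when both samples have zero
    variance (the statistic is undefined under exact separation).
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples must have n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("zero variance in both samples: t undefined under exact separation")
    res = stats.ttest_ind(x, y, equal_var=False)
    sx, sy = vx / len(x), vy / len(y)
    df = (sx + sy) ** 2 / (sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def category_percentage_table(
    records: Sequence[CgiRecord],
    condition: str | None = None,
    score_of: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Counts and percentages of condition-positive CGIs per positional class.

    ``condition`` names a feature flag; alternatively ``score_of`` maps CGI
    ids to -1/0/+1 scores, where +1 counts as positive (e.g. "methylated").
    Denominators are explicit in the output. Empty input yields an empty
    table.
    """
    if not records:
        return pd.DataFrame(columns=["class", "n_positive", "n_total", "pct"])

    def positive(rec: CgiRecord) -> bool:
        if score_of is not None:
            key = rec.interval.name or str(rec.interval)
            return score_of.get(key, 0) == 1
        if condition is not None:
            return bool(rec.feature_flags.get(condition, False))
        raise ValueError("provide condition or score_of")

    rows = []
    classes = sorted({rec.cgi_class for rec in records})
    for cls in ["all"] + classes:
        members = [r for r in records if cls == "all" or r.cgi_class == cls]
        n_pos = sum(positive(r) for r in members)
        rows.append(
            {
                "class": cls,
                "n_positive": n_pos,
                "n_total": len(members),
                "pct": 100.0 * n_pos / len(members),
            }
        )
    return pd.DataFrame(rows)
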