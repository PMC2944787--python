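"""Sliding-window differential-methylation calling on CGIs.

Per CGI, mean MAP-seq depth is computed in 100 bp windows sliding by
20 bp, each somatic/tumour sample is compared against the hypomethylated
germline (sperm) reference, and the CGI is scored +1 (more methylated than
sperm), -1 (less) or 0 (same). A CGI scores +1 when some frame of m=10
consecutive windows contains >= k=9 windows with log2(test/ref) > 2; -1 is
the mirrored rule. Window ratios are forced to 1 when both window totals
fall below a read floor (4 reads), removing bias from fluctuation at low
depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeInterval
from .track_io import DepthTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DmParams:
    """window/slide: sliding-window geometry (bp); read_floor: window total
    below which (on both sides) the ratio is forced to 1; log2_threshold:
    exceedance cut; k of m contiguous windows required; pseudocount: added
    to both window totals when at least one side is above the floor (a zero
    reference window would otherwise give an infinite ratio);
    proportional_rule: score short CGIs with >= ceil(0.9 n) of their n
    windows instead of requiring m windows."""

    window: int = 100
    slide: int = 20
    read_floor: float = 4.0
    log2_threshold: float = 2.0
    k: int = 9
    m: int = 10
    pseudocount: float = 1.0
    proportional_rule: bool = False

    def __post_init__(self) -> None:
        if not self.window > self.slide > 0:
            raise ValueError("require window > slide > 0")
        if self.k > self.m:
            raise ValueError("require k <= m")
        if self.log2_threshold <= 0:
            raise ValueError("log2_threshold must be > 0")
        if self.read_floor < 0:
            raise ValueError("read_floor must be >= 0")


@dataclass(frozen=True)
class DmCall:
    cgi_id: str | None
    score: int  # -1, 0, +1
    n_windows: int
    evaluable: bool  # enough windows for the k-of-m rule


def window_means(track: DepthTrack, interval: GenomeInterval, params: DmParams) -> np.ndarray:
    """Mean depth in windows at offsets 0, slide, 2*slide, ... within the CGI.

    Returns an empty array when the interval is shorter than one window;
    otherwise ``floor((len - window) / slide) + 1`` values.
    """
    depth = track.slice(interval)
    n = len(depth)
    if n < params.window:
        return np.empty(0)
    csum = np.concatenate(([0.0], np.cumsum(depth)))
    starts = np.arange(0, n - params.window + 1, params.slide)
    return (csum[starts + params.window] - csum[starts]) / params.window


def _window_ratios(ref: np.ndarray, test: np.ndarray, params: DmParams) -> np.ndarray:
    t_ref = ref * params.window
    t_test = test * params.window
    both_low = (t_ref < params.read_floor) & (t_test < params.read_floor)
    eps = params.pseudocount
    ratio = (t_test + eps) / (t_ref + eps)
    ratio[both_low] = 1.0
    return ratio


def _frame_fires(exceed: np.ndarray, params: DmParams) -> bool:
    n = len(exceed)
    if params.proportional_rule and n < params.m:
        return n > 0 and exceed.sum() >= int(np.ceil(0.9 * n))
    if n < params.m:
        return False
    counts = np.convolve(exceed.astype(int), np.ones(params.m, dtype=int), mode="valid")
    return bool((counts >= params.k).any())


def dm_score(
    ref_series: np.ndarray,
    test_series: np.ndarray,
    params: DmParams = DmParams(),
    cgi_id: str | None = None,
) -> DmCall:
    """Score one CGI against the germline reference.

    +1 when some frame of m consecutive windows has >= k windows with
    log2(test/ref) above the threshold; -1 under the mirrored rule; else 0.
    CGIs with fewer than m windows are non-evaluable and score 0 (unless
    the proportional rule is enabled). If both directions fire the signal
    is mixed and the score is 0, preserving antisymmetry.
    """
    ref = np.asarray(ref_series, dtype=float)
    test = np.asarray(test_series, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"series length mismatch: {ref.shape} vs {test.shape}")
    n = len(ref)
    evaluable = n >= params.m or (params.proportional_rule and n > 0)
    if n == 0:
        return DmCall(cgi_id, 0, 0, False)
    log2r = np.log2(_window_ratios(ref, test, params))
    up = _frame_fires(log2r > params.log2_threshold, params)
    down = _frame_fires(log2r < -params.log2_threshold, params)
    score = 0
    if evaluable and up != down:
        score = 1 if up else -1
    return DmCall(cgi_id, score, n, evaluable)


def dm_matrix(
    cgis: Sequence[GenomeInterval],
    ref_track: DepthTrack,
    test_tracks: Mapping[str, DepthTrack],
    params: DmParams = DmParams(),
) -> pd.DataFrame:
    """CGI x sample matrix of -1/0/+1 scores against the reference track.

    Rows are indexed by CGI name (or ``chrom:start-end`` when unnamed).
    Per-CGI failures are reported as missing (pandas NA) with a logged
    reason, never silently dropped.
    """
    ids = [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in cgis]
    table = pd.DataFrame(index=ids, columns=list(test_tracks), dtype="Int64")
    for iv, cgi_id in zip(cgis, ids):
        try:
            ref_means = window_means(ref_track, iv, params)
        except KeyError:
            log.warning("CGI %s: chromosome absent from reference track", cgi_id)
            continue
        for sample, track in test_tracks.items():
            try:
                test_means = window_means(track, iv, params)
                table.loc[cgi_id, sample] = dm_score(ref_means, test_means, params, cgi_id).score
            except (KeyError, ValueError) as exc:
                log.warning("CGI %s sample %s: %s", cgi_id, sample, exc)
    return table


def consensus_tumour_calls(
    score_table: pd.DataFrame,
    tumour_samples: Sequence[str],
    normal_samples: Sequence[str],
    min_tumour: int = 3,
    max_normal: int = 0,
    min_normal: int | None = None,
    max_tumour: int = 0,
    min_shared: int = 1,
) -> dict[str, list[str]]:
    """Partition methylated CGIs into normal-only, shared and tumour-specific.

    tumour_specific: methylated (+1) in >= min_tumour tumours and <=
    max_normal normals; normal_only: the mirrored rule (min_normal defaults
    to min_tumour); shared: methylated in >= min_shared samples of each
    group. The three subsets are disjoint by construction.
    """
    for s in list(tumour_samples) + list(normal_samples):
        if s not in score_table.columns:
            raise KeyError(f"sample {s!r} absent from score table")
    if min_normal is None:
        min_normal = min_tumour
    tum = (score_table[list(tumour_samples)] == 1).sum(axis=1)
    nor = (score_table[list(normal_samples)] == 1).sum(axis=1)
    tumour_specific = score_table.index[(tum >= min_tumour) & (nor <= max_normal)]
    normal_only = score_table.index[(nor >= min_normal) & (tum <= max_tumour)]
    shared = score_table.index[(tum >= min_shared) & (nor >= min_shared)]
    return {
        "normal_only": list(normal_only),
        "shared": list(shared),
        "tumour_specific": list(tumour_specific),
    }


def conservation_table(
    ortholog_pairs: Sequence[tuple[str, str]],
    calls_species_a: Mapping[str, int],
    calls_species_b: Mapping[str, int],
    classes: Mapping[str, str],
    exclude_classes: Sequence[str] = ("Intergenic",),
) -> pd.DataFrame:
    """Conservation of methylation across species, per positional class.

    Among class-c CGIs methylated (+1) in species A that have an ortholog,
    the percentage also methylated in species B. Intergenic CGIs are
    excluded by default (syntenic mapping is unreliable away from genes).
    """
    unknown = [a for a, b in ortholog_pairs if a not in calls_species_a] + [
        b for a, b in ortholog_pairs if b not in calls_species_b
    ]
    if unknown:
        raise KeyError(f"ortholog pairs reference unknown CGIs: {sorted(set(unknown))}")
    if not ortholog_pairs:
        log.warning("empty ortholog pair table; conservation output is empty")
    rows = []
    for cls in sorted({c for c in classes.values() if c not in exclude_classes}):
        meth_with_orth = [
            (a, b)
            for a, b in ortholog_pairs
            if classes.get(a) == cls and calls_species_a[a] == 1
        ]
        n_conserved = sum(calls_species_b[b] == 1 for _, b in meth_with_orth)
        denom = len(meth_with_orth)
        rows.append(
            {
                "class": cls,
                "n_methylated_with_ortholog": denom,
                "n_conserved": n_conserved,
                "pct_conserved": 100.0 * n_conserved / denom if denom else float("nan"),
            }
        )
    return pd.DataFrame(rows)
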