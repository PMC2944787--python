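"""Library-size normalization of enrichment tracks.

Like-assay samples (e.g. all CAP purifications) are scaled to a common
total approximating the average read mass, so read depths are directly
comparable across samples. For MAP tracks, low-level off-target background
is removed *before* totals are computed, because background reads would
otherwise skew the scaling constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .track_io import DepthTrack

DEFAULT_MAP_BACKGROUND_FLOOR = 2.0


@dataclass(frozen=True)
class NormalizationParams:
    """target_total: explicit scaling constant or "auto" (mean of like-sample
    totals); background_floor: depth at or below which MAP bases are zeroed
    before totals are computed."""

    target_total: float | str = "auto"
    background_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.target_total != "auto" and not self.target_total > 0:
            raise ValueError("explicit target_total must be > 0")
        if self.background_floor < 0:
            raise ValueError("background_floor must be >= 0")


def total_depth(track: DepthTrack) -> float:
    """Sum of per-base depth over all chromosomes."""
    return track.total()


def remove_background(track: DepthTrack, floor: float) -> DepthTrack:
    """Zero every base whose depth is <= ``floor``; higher bases unchanged.

    Idempotent and monotone non-increasing per base.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    return DepthTrack({c: np.where(v > floor, v, 0.0) for c, v in track.data.items()})


def scale_like_samples(
    tracks: Sequence[DepthTrack],
    params: NormalizationParams = NormalizationParams(),
    names: Sequence[str] | None = None,
) -> tuple[list[DepthTrack], list[float]]:
    """Scale like-assay tracks to a common total read mass.

    Each track is multiplied by ``target_total / its_total``. With
    ``target_total="auto"`` the target is the arithmetic mean of the
    (post-background) totals. Returns ``(scaled_tracks, scale_factors)``.
    """
    if not tracks:
        raise ValueError("need at least one track")
    names = list(names) if names is not None else [f"sample{i}" for i in range(len(tracks))]
    if params.background_floor > 0:
        tracks = [remove_background(t, params.background_floor) for t in tracks]
    totals = [t.total() for t in tracks]
    for name, tot in zip(names, totals):
        if tot <= 0:
            raise ValueError(f"sample {name!r} has zero total depth; cannot scale")
    target = float(np.mean(totals)) if params.target_total == "auto" else float(params.target_total)
    factors = [target / tot for tot in totals]
    return [t.scaled(f) for t, f in zip(tracks, factors)], factors
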