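"""CpG composition statistics.

The observed/expected (o/e) ratio follows the Gardiner-Garden convention:
``oe = n_cpg * length / (n_c * n_g)``, the convention behind the classical
0.6 island-prediction threshold. ``per100`` is CpGs per 100 bp. N bases
reduce the effective length and can form neither CpGs nor C/G counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Human bulk-genome average o/e and the classical island-prediction
#: threshold; used for reporting and plots only, never as calling thresholds.
GENOME_AVERAGE_OE = 0.21
PREDICTION_THRESHOLD_OE = 0.6

DENSITY_BIN_LABELS = ("<5", "5-6", "6-7", "7-8", "8-9", ">9")
_DENSITY_BIN_EDGES = (5.0, 6.0, 7.0, 8.0, 9.0)


@dataclass(frozen=True)
class CpgStats:
    n_cpg: int
    n_c: int
    n_g: int
    length: int  # effective (non-N) length
    oe: float | None  # None when n_c or n_g is 0 (undefined)
    per100: float


def cpg_stats(sequence: str) -> CpgStats:
    """Composition statistics of a sequence over {A,C,G,T,N}.

    CpGs are counted with an overlapping dinucleotide scan; any position
    involving an N is skipped. Requires effective length >= 2.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    length = int((~is_n).sum())
    if length < 2:
        raise ValueError("sequence must have >= 2 non-N bases")
    n_c = int((arr == ord("C")).sum())
    n_g = int((arr == ord("G")).sum())
    n_cpg = int(((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).sum())
    oe = n_cpg * length / (n_c * n_g) if n_c and n_g else None
    per100 = 100.0 * n_cpg / length
    return CpgStats(n_cpg, n_c, n_g, length, oe, per100)


def sliding_cpg_oe(
    sequence: str,
    window: int = 400,
    slide: int = 10,
    max_n_frac: float = 0.2,
) -> pd.DataFrame:
    """Sliding-window o/e and density profile along a sequence.

    One row per window start 0, slide, 2*slide, ... while
    ``start + window <= len(sequence)``; the window midpoint is the profile
    coordinate. Windows with more than ``max_n_frac`` N bases (or an
    undefined o/e) report NaN.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if slide < 1:
        raise ValueError("slide must be >= 1")
    rows = []
    for start in range(0, len(sequence) - window + 1, slide):
        sub = sequence[start : start + window]
        n_frac = sub.upper().count("N") / window
        if n_frac > max_n_frac:
            rows.append((start + window // 2, np.nan, np.nan))
            continue
        try:
            st = cpg_stats(sub)
        except ValueError:
            rows.append((start + window // 2, np.nan, np.nan))
            continue
        rows.append((start + window // 2, st.oe if st.oe is not None else np.nan, st.per100))
    return pd.DataFrame(rows, columns=["midpoint", "oe", "per100"])


def density_bin(per100: float) -> str:
    """Map a CpGs-per-100-bp value onto the six density bins <5 ... >9.

    Interior bins are left-closed right-open; 9.0 falls in ">9" so that the
    six labels are exhaustive.
    """
    if per100 < 0:
        raise ValueError("per100 must be >= 0")
    for edge, label in zip(_DENSITY_BIN_EDGES, DENSITY_BIN_LABELS):
        if per100 < edge:
            return label
    return DENSITY_BIN_LABELS[-1]
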