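"""Independent brute-force oracles used to validate the optimised paths.

These deliberately use the most literal possible formulation (explicit
base sets, substring scans) and share no code with the implementation.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(depth: np.ndarray, H: float, L: int, G: int) -> list[tuple[int, int]]:
    """Peak calling by explicit base marking and run merging.

    Marks every base >= H, chains marked runs whose separating gap is
    <= G bp, and reports chained spans (first to last marked base) of
    length >= L.
    """
    marked = [i for i, v in enumerate(depth) if v >= H]
    if not marked:
        return []
    chains: list[list[int]] = [[marked[0]]]
    for pos in marked[1:]:
        if pos - chains[-1][-1] - 1 <= G:
            chains[-1].append(pos)
        else:
            chains.append([pos])
    return [(c[0], c[-1] + 1) for c in chains if c[-1] + 1 - c[0] >= L]


def brute_force_cpg(sequence: str) -> tuple[int, int, int, int]:
    """(n_cpg, n_c, n_g, effective_length) by literal substring scanning."""
    seq = sequence.upper()
    n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
    n_c = seq.count("C")
    n_g = seq.count("G")
    length = len(seq) - seq.count("N")
    return n_cpg, n_c, n_g, length


def brute_force_union(sets: list[list[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Interval union via an explicit covered-base set."""
    covered: set[int] = set()
    for s in sets:
        for start, end in s:
            covered.update(range(start, end))
    if not covered:
        return []
    out = []
    run = [min(covered)]
    for b in sorted(covered)[1:]:
        if b == run[-1] + 1:
            run.append(b)
        else:
            out.append((run[0], run[-1] + 1))
            run = [b]
    out.append((run[0], run[-1] + 1))
    return out


def random_track(rng: np.random.Generator, max_len: int = 2000) -> np.ndarray:
    """A spiky random track: Poisson background plus rectangular enrichments."""
    n = int(rng.integers(50, max_len + 1))
    depth = rng.poisson(rng.uniform(0.05, 1.0), size=n).astype(float)
    for _ in range(int(rng.integers(0, 6))):
        w = int(rng.integers(10, max(11, n // 3)))
        s = int(rng.integers(0, max(1, n - w)))
        depth[s : s + w] += rng.uniform(1, 8)
    return depth


def random_hlg(rng: np.random.Generator) -> tuple[float, int, int]:
    L = int(rng.integers(2, 400))
    G = int(rng.integers(0, L))
    H = float(rng.uniform(0.5, 6.0))
    return H, L, G
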