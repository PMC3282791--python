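"""Independent brute-force oracles used to validate the implementation.

Each oracle solves a small instance by exhaustive enumeration or direct
simulation and deliberately shares no code with the library path it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def mixture_scan_d(bafs, noise_sd: float, step: float = 0.001) -> float:
    """Half-separation of a symmetric two-band BAF mixture by exhaustive scan.

    Maximises the likelihood of the equal-weight mixture
    0.5*N(0.5-d, sd) + 0.5*N(0.5+d, sd) over d in [0, 0.5] on a fine grid.
    """
    bafs = np.asarray(bafs, dtype=float)
    ds = np.arange(0.0, 0.5 + step / 2, step)
    best_d, best_ll = 0.0, -np.inf
    for d in ds:
        ll = np.sum(np.log(
            0.5 * stats.norm.pdf(bafs, 0.5 - d, noise_sd)
            + 0.5 * stats.norm.pdf(bafs, 0.5 + d, noise_sd)
        ))
        if ll > best_ll:
            best_d, best_ll = float(d), ll
    return best_d


def single_split_scan(x, min_markers: int) -> tuple[int, float]:
    """Best single breakpoint by direct Welch t-test at every admissible split."""
    x = np.asarray(x, dtype=float)
    best_k, best_t = -1, -np.inf
    for k in range(min_markers, len(x) - min_markers + 1):
        t = stats.ttest_ind(x[:k], x[k:], equal_var=False).statistic
        if np.isfinite(t) and abs(t) > best_t:
            best_k, best_t = k, abs(t)
    return best_k, best_t


def per_base_regions(intervals_by_sample: dict, threshold: int, lo: int, hi: int,
                     grid: int = 1000) -> list[tuple[int, int]]:
    """Recurrent intervals by direct per-base counting on a coarse grid.

    Counts, for every grid cell in [lo, hi), how many samples cover it fully
    or partially at single-base resolution by evaluating coverage at each cell
    boundary; works for instances up to ~10 Mb at 1 kb cells. Interval
    endpoints must be multiples of ``grid`` for exact agreement.
    """
    edges = np.arange(lo, hi + grid, grid)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for ivs in intervals_by_sample.values():
        covered = np.zeros(len(edges) - 1, dtype=bool)
        for s, e in ivs:
            covered |= (edges[:-1] < e) & (edges[1:] > s)
        counts += covered
    out = []
    in_run = False
    for i, c in enumerate(counts):
        if c >= threshold and not in_run:
            start, in_run = int(edges[i]), True
        elif c < threshold and in_run:
            out.append((start, int(edges[i])))
            in_run = False
    if in_run:
        out.append((start, int(edges[-1])))
    return out


def permutation_anova_p(values, groups, n_perm: int, rng) -> float:
    """Permutation p-value of the one-way F statistic."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)

    def fstat(v):
        return stats.f_oneway(*[v[groups == g] for g in levels]).statistic

    f_obs = fstat(values)
    hits = 0
    for _ in range(n_perm):
        hits += fstat(rng.permutation(values)) >= f_obs
    return (hits + 1) / (n_perm + 1)
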