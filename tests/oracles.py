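"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the library's vectorized code paths: clusters are
found by set-based flood fill, permutation nulls by explicit per-pattern
loops, and labels by naive region growth, so that agreement is evidence and
not tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_clusters(t_map: np.ndarray, threshold: float,
                         diagonal: bool = False) -> list[tuple[int, frozenset, float]]:
    """(sign, member index set, mass) triples via flood fill."""
    t_map = np.asarray(t_map, float)
    if t_map.ndim == 1:
        t_map = t_map[None, :]
        one_d = True
    else:
        one_d = False
    nr, nc = t_map.shape
    if one_d:
        steps = [(0, 1), (0, -1)]
    elif diagonal:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    out = []
    for sign in (1, -1):
        supra = {(r, c) for r in range(nr) for c in range(nc)
                 if (t_map[r, c] > threshold if sign == 1 else t_map[r, c] < -threshold)}
        while supra:
            seed = next(iter(supra))
            comp, frontier = {seed}, [seed]
            while frontier:
                r, c = frontier.pop()
                for dr, dc in steps:
                    nb = (r + dr, c + dc)
                    if nb in supra and nb not in comp:
                        comp.add(nb)
                        frontier.append(nb)
            supra -= comp
            members = frozenset(c for _, c in comp) if one_d else frozenset(comp)
            out.append((sign, members, float(sum(t_map[p] for p in comp))))
    return out


def one_sample_t(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def exhaustive_max_masses(diffs: np.ndarray, threshold: float,
                          diagonal: bool = False) -> np.ndarray:
    """Max |cluster mass| for every one of the 2^n sign patterns, by loops."""
    import itertools

    n = diffs.shape[0]
    out = []
    for pattern in itertools.product((1.0, -1.0), repeat=n):
        flipped = diffs * np.array(pattern).reshape((n,) + (1,) * (diffs.ndim - 1))
        t = one_sample_t(flipped)
        clusters = brute_force_clusters(t, threshold, diagonal=diagonal)
        out.append(max((abs(mass) for _, _, mass in clusters), default=0.0))
    return np.array(out)


def brute_force_label(adjacency, activation, mask, fraction: float) -> set[int]:
    """Naive region growth: peak in mask, flood fill over >=fraction vertices."""
    mask = set(int(v) for v in mask)
    peak = sorted(mask, key=lambda v: (-activation[v], v))[0]
    thr = fraction * activation[peak]
    region, frontier = {peak}, [peak]
    while frontier:
        v = frontier.pop()
        for u in adjacency[v]:
            if u in mask and u not in region and activation[u] >= thr:
                region.add(u)
                frontier.append(u)
    return region
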