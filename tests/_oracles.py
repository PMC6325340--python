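"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity by direct enumeration or summation,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_bpi(depths: np.ndarray, cell: float, inner: float, outer: float) -> np.ndarray:
    """Double-loop annulus-mean BPI on elevation = -depth."""
    elev = -np.asarray(depths, dtype=float)
    nr, nc = elev.shape
    out = np.empty_like(elev)
    for i in range(nr):
        for j in range(nc):
            acc = cnt = 0
            for di in range(-int(outer // cell) - 1, int(outer // cell) + 2):
                for dj in range(-int(outer // cell) - 1, int(outer // cell) + 2):
                    r = cell * np.hypot(di, dj)
                    if not (inner < r <= outer):
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nr and 0 <= jj < nc and np.isfinite(elev[ii, jj]):
                        acc += elev[ii, jj]
                        cnt += 1
            out[i, j] = elev[i, j] - acc / cnt if cnt else np.nan
    return out


def brute_tri(depths: np.ndarray, cell: float, radius: float) -> np.ndarray:
    """Double-loop mean-absolute-difference TRI."""
    elev = -np.asarray(depths, dtype=float)
    nr, nc = elev.shape
    out = np.empty_like(elev)
    for i in range(nr):
        for j in range(nc):
            acc = cnt = 0
            for di in range(-int(radius // cell) - 1, int(radius // cell) + 2):
                for dj in range(-int(radius // cell) - 1, int(radius // cell) + 2):
                    if di == 0 and dj == 0:
                        continue
                    if cell * np.hypot(di, dj) > radius:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nr and 0 <= jj < nc:
                        acc += abs(elev[i, j] - elev[ii, jj])
                        cnt += 1
            out[i, j] = acc / cnt if cnt else np.nan
    return out


def rarefaction_by_enumeration(incidence: np.ndarray, t: int) -> float:
    """Mean richness over all C(T, t) unit subsets of an incidence matrix."""
    T = incidence.shape[0]
    vals = [
        float((np.asarray(incidence)[list(combo)].sum(axis=0) > 0).sum())
        for combo in itertools.combinations(range(T), t)
    ]
    return float(np.mean(vals))


def individual_rarefaction_by_enumeration(counts: np.ndarray, n: int,
                                          n_rep: int = 0) -> float:
    """E[S(n)] without replacement via the exact hypergeometric identity,
    computed with factorials on small integers (independent of gammaln)."""
    from math import comb

    counts = np.asarray(counts, dtype=int)
    N = counts.sum()
    miss = [comb(N - x, n) / comb(N, n) if N - x >= n else 0.0 for x in counts if x > 0]
    return float(sum(1 - m for m in miss))


def bray_curtis_pair(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).sum() / (a + b).sum())


def permanova_f(d: np.ndarray, groups: np.ndarray) -> float:
    """Pseudo-F computed from scratch on a distance matrix."""
    n = d.shape[0]
    d2 = d**2
    ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    labels = sorted(set(groups))
    for g in labels:
        idx = [i for i in range(n) if groups[i] == g]
        ss_w += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    a = len(labels)
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


def permanova_p_by_enumeration(d: np.ndarray, groups) -> float:
    """Exact permutation p over all distinct label arrangements."""
    groups = list(groups)
    n = len(groups)
    f_obs = permanova_f(d, groups)
    seen = set()
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        key = tuple(groups[i] for i in perm)
        if key in seen:
            continue
        seen.add(key)
        f = permanova_f(d, list(key))
        total += 1
        if f >= f_obs - 1e-12:
            hits += 1
    return hits / total


def expected_diversity_by_multinomial(counts: np.ndarray, n: int) -> dict:
    """Exact E[exp H'] and E[1/D] of an n-individual multinomial draw."""
    from math import comb, factorial

    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    k = p.size
    eh = iv = 0.0
    for combo in itertools.product(range(n + 1), repeat=k):
        if sum(combo) != n:
            continue
        prob = factorial(n)
        for c, pi in zip(combo, p):
            prob *= pi**c / factorial(c)
        q = np.array([c / n for c in combo if c > 0])
        eh += prob * np.exp(-(q * np.log(q)).sum())
        iv += prob / (q**2).sum()
    return {"exp_shannon": eh, "inv_simpson": iv}
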