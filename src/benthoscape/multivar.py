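"""Community-composition analysis from first principles.

Bray-Curtis dissimilarities on square-root transformed densities, non-metric
multidimensional scaling (Kruskal stress-1 with isotonic regression),
one-way PERMANOVA with pairwise follow-ups, SIMPER decomposition, and
Spearman rank correlation with permutation p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .diversity import AbundanceTable

__all__ = [
    "DissimilarityMatrix",
    "bray_curtis",
    "NMDSResult",
    "nmds",
    "PermanovaResult",
    "permanova",
    "simper",
    "spearman",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric Bray-Curtis matrix with unit ids and a transformation tag."""

    ids: list
    values: np.ndarray
    transform: str = "sqrt-density"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _transform_matrix(table: AbundanceTable, transform: str) -> np.ndarray:
    if transform == "sqrt-density":
        return np.sqrt(table.densities().to_numpy())
    if transform == "density":
        return table.densities().to_numpy()
    if transform == "sqrt-count":
        return np.sqrt(table.counts.to_numpy(dtype=float))
    raise ValueError(f"unknown transform {transform!r}")


def bray_curtis(table: AbundanceTable | None = None, y: np.ndarray | None = None,
                ids=None, transform: str = "sqrt-density") -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities d_ij = sum|y_i - y_j| / sum(y_i + y_j).

    By default y is the square-root transformed density matrix of the table.
    Pairs of all-empty units are undefined (nan) and flagged with a warning.
    """
    if y is None:
        if table is None:
            raise ValueError("provide a table or a transformed matrix")
        y = _transform_matrix(table, transform)
        ids = list(table.counts.index)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    ids = list(ids) if ids is not None else list(range(n))
    num = np.abs(y[:, None, :] - y[None, :, :]).sum(axis=2)
    den = (y[:, None, :] + y[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        warnings.warn("pairs of empty units have undefined Bray-Curtis dissimilarity")
    return DissimilarityMatrix(ids=ids, values=d, transform=transform)


# -- nMDS -----------------------------------------------------------------------


@dataclass
class NMDSResult:
    """Ordination configuration with Kruskal stress-1 diagnostics."""

    coords: pd.DataFrame
    stress: float
    stress_trace: np.ndarray      # raw-stress trace of the best start
    restart_stresses: np.ndarray
    converged: bool


def _pcoa_init(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    return v[:, idx] * np.sqrt(np.maximum(w[idx], 1e-12))


def _nmds_single(delta: np.ndarray, n: int, k: int, X0: np.ndarray,
                 max_iter: int, tol: float):
    iso = IsotonicRegression(increasing=True)
    X = X0 - X0.mean(axis=0)
    trace = []
    dhat = None
    for _ in range(max_iter):
        d = pdist(X)
        order = np.lexsort((d, delta))   # primary (weak) tie treatment
        fitted = iso.fit_transform(np.arange(d.size), d[order])
        dhat = np.empty_like(d)
        dhat[order] = fitted
        sigma = float(np.sum((d - dhat) ** 2))
        if trace and trace[-1] - sigma < tol * max(trace[-1], 1e-12):
            trace.append(min(sigma, trace[-1]))
            break
        trace.append(sigma)
        # Guttman transform
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / n
        X -= X.mean(axis=0)
    d = pdist(X)
    denom = float(np.sum(d**2))
    stress1 = float(np.sqrt(np.sum((d - dhat) ** 2) / denom)) if denom > 0 else np.inf
    return X, stress1, np.asarray(trace)


def nmds(D: DissimilarityMatrix | np.ndarray, k: int = 2, restarts: int = 50,
         max_iter: int = 300, tol: float = 1e-9, seed=None) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Monotone (isotonic) regression of configuration distances on the ranked
    dissimilarities alternates with Guttman-transform configuration updates;
    the best of ``restarts`` starts (a principal-coordinates start plus
    random starts) is kept.  Deterministic under a fixed seed.
    """
    if isinstance(D, DissimilarityMatrix):
        ids, mat = D.ids, D.values
    else:
        mat = np.asarray(D, dtype=float)
        ids = list(range(mat.shape[0]))
    n = mat.shape[0]
    if n < 4:
        raise ValueError("nMDS needs at least 4 points")
    delta = squareform(mat, checks=False)
    if np.allclose(delta, delta[0]):
        warnings.warn("all dissimilarities equal; nMDS configuration is degenerate")
    rng = np.random.default_rng(seed)

    best = None
    stresses = []
    scale = max(delta.mean(), 1e-6)
    for r in range(max(restarts, 1)):
        X0 = _pcoa_init(mat, k) if r == 0 else rng.normal(scale=scale, size=(n, k))
        X, stress, trace = _nmds_single(delta, n, k, X0, max_iter, tol)
        stresses.append(stress)
        if best is None or stress < best[1]:
            best = (X, stress, trace)
    X, stress, trace = best
    coords = pd.DataFrame(X, index=ids, columns=[f"nmds{i + 1}" for i in range(k)])
    return NMDSResult(coords=coords, stress=stress, stress_trace=trace,
                      restart_stresses=np.asarray(stresses),
                      converged=len(trace) < max_iter)


# -- PERMANOVA ------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """One-way PERMANOVA summary with optional pairwise follow-ups."""

    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    method: str
    pairwise: pd.DataFrame | None = None

    def summary(self) -> str:
        s = (f"PERMANOVA: pseudo-F = {self.pseudo_f:.3f}, R2 = {self.r2:.3f}, "
             f"p = {self.p_value:.4g} ({self.method}, {self.n_permutations} permutations)")
        if self.pairwise is not None:
            s += "\n" + self.pairwise.to_string(index=False)
        return s


def _permanova_stats(d2: np.ndarray, idx_by_group: list[np.ndarray], n: int):
    ss_t = d2.sum() / (2.0 * n)
    ss_w = 0.0
    for idx in idx_by_group:
        ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_a = ss_t - ss_w
    a = len(idx_by_group)
    f = (ss_a / (a - 1)) / (ss_w / (n - a))
    return f, ss_a / ss_t


def permanova(D: DissimilarityMatrix | np.ndarray, groups, n_perm: int = 9999,
              seed=None, method: str = "sampled", pairwise: bool = False,
              adjust: str = "holm") -> PermanovaResult:
    """One-way permutational MANOVA on a dissimilarity matrix.

    ``method='sampled'`` draws ``n_perm`` random label permutations and uses
    p = (1 + #[F_perm >= F_obs]) / (1 + n_perm); ``method='exact'``
    enumerates every distinct label arrangement.  Pairwise tests rerun the
    same procedure on group pairs, with Holm-adjusted p-values reported
    alongside the raw ones.
    """
    mat = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    groups = np.asarray(groups)
    n = mat.shape[0]
    if groups.size != n:
        raise ValueError("groups length must match matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two units")
    d2 = mat**2
    idx_by_group = [np.flatnonzero(groups == g) for g in labels]
    f_obs, r2 = _permanova_stats(d2, idx_by_group, n)

    if method == "sampled":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _permanova_stats(d2, [perm[i] for i in idx_by_group], n)[0] >= f_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        n_used = n_perm
    elif method == "exact":
        hits = total = 0
        base = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
        seen = set()
        for perm in itertools.permutations(range(n)):
            key = tuple(base[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            idxs = [np.flatnonzero(np.array(key) == i) for i in range(labels.size)]
            f = _permanova_stats(d2, idxs, n)[0]
            total += 1
            if f >= f_obs - 1e-12:
                hits += 1
        p = hits / total
        n_used = total
    else:
        raise ValueError("method must be 'sampled' or 'exact'")

    pw = None
    if pairwise:
        rng = np.random.default_rng(seed)
        rows = []
        for ga, gb in itertools.combinations(labels, 2):
            sel = np.flatnonzero((groups == ga) | (groups == gb))
            sub = permanova(mat[np.ix_(sel, sel)], groups[sel], n_perm=n_perm,
                            seed=rng.integers(2**31), method="sampled")
            rows.append({"group_a": ga, "group_b": gb, "pseudo_f": sub.pseudo_f,
                         "r2": sub.r2, "p": sub.p_value})
        pw = pd.DataFrame(rows)
        pw["p_adj"] = multipletests(pw["p"], method=adjust)[1]
    return PermanovaResult(pseudo_f=f_obs, r2=r2, p_value=p, n_permutations=n_used,
                           method=method, pairwise=pw)


# -- SIMPER ---------------------------------------------------------------------


def simper(table: AbundanceTable, group_a, group_b,
           transform: str = "sqrt-density") -> pd.DataFrame:
    """Per-species contributions to mean between-group Bray-Curtis dissimilarity.

    For every cross-group unit pair, species k contributes
    |y_ik - y_jk| / sum_s (y_is + y_js); contributions are averaged over
    pairs and sum exactly to the mean between-group dissimilarity.
    """
    y = _transform_matrix(table, transform)
    ia = np.flatnonzero((table.groups == group_a).to_numpy())
    ib = np.flatnonzero((table.groups == group_b).to_numpy())
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must contain units")
    contribs = np.zeros(y.shape[1])
    n_pairs = 0
    for i in ia:
        for j in ib:
            den = (y[i] + y[j]).sum()
            if den <= 0:
                continue
            contribs += np.abs(y[i] - y[j]) / den
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no valid cross-group pairs")
    contribs /= n_pairs
    total = contribs.sum()
    out = pd.DataFrame({
        "species": table.counts.columns,
        "contribution": contribs,
        "mean_a": y[ia].mean(axis=0),
        "mean_b": y[ib].mean(axis=0),
    }).sort_values("contribution", ascending=False, kind="stable")
    out["pct"] = 100.0 * out["contribution"] / total if total > 0 else 0.0
    out["cum_pct"] = out["pct"].cumsum()
    out.attrs["mean_dissimilarity"] = float(total)
    return out.reset_index(drop=True)


# -- Spearman -------------------------------------------------------------------


def spearman(x, y, n_perm: int = 9999, seed=None) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks with a permutation p-value.

    Two-sided p from random permutations of one variable (appropriate at the
    small n of replicate-unit comparisons).  Constant inputs are undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return np.nan, np.nan
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return rho, (1 + hits) / (1 + n_perm)
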