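"""k-means and fuzzy c-means partitioning of temporal profiles.

Both algorithms minimize a within-cluster squared Euclidean objective.
k-means (Lloyd's algorithm) gives hard one-hot memberships; fuzzy c-means
(Bezdek's alternating updates) gives soft memberships in [0, 1] summing to
one per site, controlled by the fuzzifier exponent m > 1.  As m -> 1+ the
soft memberships approach the hard k-means assignments.

Centroids are initialized as k distinct data rows drawn uniformly at
random under the given seed, and clustering is typically repeated with
several seeds (:func:`fit_repeated`) because both objectives are
non-convex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .preprocessing import TemporalMatrix

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200


@dataclass
class ClusterModel:
    """One clustering outcome.

    ``membership`` rows sum to 1 (one-hot for k-means); ``hard_assignment``
    is the argmax cluster per site; ``objective`` is the final
    within-cluster objective; ``objective_trace`` records it per iteration.
    """

    k: int
    site_ids: list[str]
    centroids: np.ndarray
    membership: np.ndarray = field(repr=False)
    hard_assignment: np.ndarray = field(repr=False)
    objective: float = np.nan
    seed: int | None = None
    method: str = ""
    n_iter: int = 0
    objective_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroids rows != k")
        if self.membership.shape != (len(self.site_ids), self.k):
            raise ValueError("membership shape mismatch")
        if not np.allclose(self.membership.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def assignment_of(self) -> dict[str, int]:
        return {s: int(c) for s, c in zip(self.site_ids, self.hard_assignment)}

    def relabel(self, perm: np.ndarray) -> "ClusterModel":
        """Apply a cluster-label permutation: new cluster p[i] is old i."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(self.k)
        return ClusterModel(
            k=self.k,
            site_ids=list(self.site_ids),
            centroids=self.centroids[inv],
            membership=self.membership[:, inv],
            hard_assignment=perm[self.hard_assignment],
            objective=self.objective,
            seed=self.seed,
            method=self.method,
            n_iter=self.n_iter,
            objective_trace=list(self.objective_trace),
        )


def _sq_dist(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, n x k, clipped at 0 for roundoff."""
    d2 = (
        np.einsum("ij,ij->i", x, x)[:, None]
        - 2.0 * x @ v.T
        + np.einsum("ij,ij->i", v, v)[None, :]
    )
    return np.maximum(d2, 0.0)


def _init_centroids(x: np.ndarray, k: int, rng: np.random.Generator,
                    init: str) -> np.ndarray:
    n = x.shape[0]
    if init == "random":
        return x[rng.choice(n, size=k, replace=False)].copy()
    if init == "k-means++":
        centroids = np.empty((k, x.shape[1]))
        centroids[0] = x[rng.integers(n)]
        d2 = _sq_dist(x, centroids[:1]).ravel()
        for i in range(1, k):
            total = d2.sum()
            if total == 0:
                centroids[i] = x[rng.integers(n)]
            else:
                centroids[i] = x[rng.choice(n, p=d2 / total)]
            d2 = np.minimum(d2, _sq_dist(x, centroids[i : i + 1]).ravel())
        return centroids
    raise ValueError(f"unknown init {init!r}")


def kmeans_fit(
    m: TemporalMatrix,
    k: int,
    seed: int,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    init: Literal["random", "k-means++"] = "random",
) -> ClusterModel:
    """Lloyd's k-means with Euclidean distance.

    Runs to convergence (max centroid shift < ``tol``) or ``max_iter``.
    An emptied cluster is re-seeded at the data point farthest from its
    current centroid.
    """
    x = m.values
    n = x.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} must be in [2, n_sites={n}]")
    rng = np.random.default_rng(seed)
    centroids = _init_centroids(x, k, rng, init)
    labels = np.zeros(n, dtype=int)
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = _sq_dist(x, centroids)
        labels = d2.argmin(axis=1)
        for i in range(k):
            if not np.any(labels == i):
                far = _sq_dist(x, centroids[i : i + 1]).ravel().argmax()
                centroids[i] = x[far]
                labels[far] = i
        trace.append(float(_sq_dist(x, centroids)[np.arange(n), labels].sum()))
        new_centroids = np.vstack([x[labels == i].mean(axis=0) for i in range(k)])
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            break
    d2 = _sq_dist(x, centroids)
    labels = d2.argmin(axis=1)
    objective = float(d2[np.arange(n), labels].sum())
    trace.append(objective)
    membership = np.zeros((n, k))
    membership[np.arange(n), labels] = 1.0
    return ClusterModel(
        k=k, site_ids=list(m.site_ids), centroids=centroids,
        membership=membership, hard_assignment=labels,
        objective=objective, seed=seed, method="kmeans",
        n_iter=it, objective_trace=trace,
    )


def cmeans_fit(
    m: TemporalMatrix,
    c: int,
    seed: int,
    *,
    fuzzifier: float = 1.5,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    init: Literal["random", "k-means++"] = "random",
) -> ClusterModel:
    """Bezdek fuzzy c-means.

    Alternates membership updates
    ``u_si \\propto (1/d(x_s, v_i)^2)^{1/(m-1)}`` (normalized over
    clusters) with weighted centroid updates
    ``v_i = sum_s u_si^m x_s / sum_s u_si^m``, until the maximum
    membership change drops below ``tol`` or ``max_iter`` is reached.
    A site coinciding exactly with a centroid gets membership 1 there
    (the m -> d->0 limit).
    """
    x = m.values
    n = x.shape[0]
    if not 2 <= c <= n:
        raise ValueError(f"c={c} must be in [2, n_sites={n}]")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    rng = np.random.default_rng(seed)
    centroids = _init_centroids(x, c, rng, init)
    exponent = 1.0 / (fuzzifier - 1.0)
    if _cmeans_loop_jit is not None:
        u, centroids, it = _cmeans_loop_jit(
            np.ascontiguousarray(x), np.ascontiguousarray(centroids),
            fuzzifier, exponent, tol, max_iter,
        )
    else:
        xn = np.einsum("ij,ij->i", x, x)[:, None]  # row norms, constant
        u = _cmeans_membership(x, centroids, exponent, xn)
        for it in range(1, max_iter + 1):
            um = _upow(u, fuzzifier)
            weights = um.sum(axis=0)
            centroids = (um.T @ x) / weights[:, None]
            u_new = _cmeans_membership(x, centroids, exponent, xn)
            change = np.abs(u_new - u).max()
            u = u_new
            if change < tol:
                break
    d2 = _sq_dist(x, centroids)
    objective = float((_upow(u, fuzzifier) * d2).sum())
    labels = u.argmax(axis=1)
    return ClusterModel(
        k=c, site_ids=list(m.site_ids), centroids=centroids,
        membership=u, hard_assignment=labels,
        objective=objective, seed=seed, method="cmeans",
        n_iter=it, objective_trace=[],
    )


def _upow(u: np.ndarray, fuzzifier: float) -> np.ndarray:
    """u ** fuzzifier, with cheap paths for the common exponents."""
    if fuzzifier == 1.5:
        return u * np.sqrt(u)
    if fuzzifier == 2.0:
        return u * u
    return u ** fuzzifier


def _cmeans_membership(
    x: np.ndarray, v: np.ndarray, exponent: float, xn: np.ndarray | None = None
) -> np.ndarray:
    if xn is None:
        xn = np.einsum("ij,ij->i", x, x)[:, None]
    d2 = np.maximum(
        xn - 2.0 * (x @ v.T) + np.einsum("ij,ij->i", v, v)[None, :], 0.0
    )
    if exponent == 2.0:
        # default fuzzifier 1.5: w = d2^-2 without logs; flooring d2 keeps
        # the weights finite and already realizes the coincident-point
        # limit (membership ~1 at the coincident centroid)
        iw = np.square(np.maximum(d2, 1e-30))
        np.reciprocal(iw, out=iw)
        return iw / iw.sum(axis=1, keepdims=True)
    zero = d2 <= 0.0
    u = np.zeros_like(d2)
    coincident = zero.any(axis=1)
    ok = ~coincident
    if ok.any():
        # log-space keeps the update stable for large exponents
        # (fuzzifier -> 1+) and near-coincident points
        logw = -exponent * np.log(d2[ok])
        wv = np.exp(logw - logw.max(axis=1, keepdims=True))
        u[ok] = wv / wv.sum(axis=1, keepdims=True)
    if coincident.any():
        rows, cols = np.where(zero & coincident[:, None])
        # split mass evenly if a point coincides with several centroids
        counts = zero.sum(axis=1)
        u[rows, cols] = 1.0 / counts[rows]
    return u


def _build_cmeans_loop():
    """Compiled fuzzy c-means iteration (same update equations as the
    numpy path; used when numba is available for a several-fold speedup
    on benchmark-sized problems)."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional accelerator
        return None

    @njit(cache=False)
    def loop(x, centroids, fuzzifier, exponent, tol, max_iter):
        n, t = x.shape
        c = centroids.shape[0]
        u = np.empty((n, c))
        d2 = np.empty(c)
        _memberships(x, centroids, exponent, u, d2)
        sums = np.empty(c)
        it = 0
        for it in range(1, max_iter + 1):
            # centroid update v_i = sum u^m x / sum u^m
            centroids[:, :] = 0.0
            sums[:] = 0.0
            for s in range(n):
                for i in range(c):
                    if fuzzifier == 1.5:
                        um = u[s, i] * np.sqrt(u[s, i])
                    elif fuzzifier == 2.0:
                        um = u[s, i] * u[s, i]
                    else:
                        um = u[s, i] ** fuzzifier
                    sums[i] += um
                    for j in range(t):
                        centroids[i, j] += um * x[s, j]
            for i in range(c):
                for j in range(t):
                    centroids[i, j] /= sums[i]
            change = _memberships(x, centroids, exponent, u, d2)
            if change < tol:
                break
        return u, centroids, it

    @njit(cache=False)
    def _memberships(x, centroids, exponent, u, d2):
        n, t = x.shape
        c = centroids.shape[0]
        change = 0.0
        for s in range(n):
            dmin = np.inf
            n_zero = 0
            for i in range(c):
                acc = 0.0
                for j in range(t):
                    diff = x[s, j] - centroids[i, j]
                    acc += diff * diff
                d2[i] = acc
                if acc <= 0.0:
                    n_zero += 1
                elif acc < dmin:
                    dmin = acc
            total = 0.0
            if n_zero > 0:
                # coincident-point limit: all mass on the zero distances
                for i in range(c):
                    w = (1.0 / n_zero) if d2[i] <= 0.0 else 0.0
                    delta = abs(w - u[s, i])
                    if delta > change:
                        change = delta
                    u[s, i] = w
                continue
            for i in range(c):
                # (dmin/d2)^exponent <= 1: no overflow for any exponent
                if exponent == 2.0:
                    r = dmin / d2[i]
                    w = r * r
                else:
                    w = (dmin / d2[i]) ** exponent
                d2[i] = w
                total += w
            for i in range(c):
                w = d2[i] / total
                delta = abs(w - u[s, i])
                if delta > change:
                    change = delta
                u[s, i] = w
        return change

    return loop


_cmeans_loop_jit = _build_cmeans_loop()


def fit_repeated(
    m: TemporalMatrix,
    k: int,
    repeats: int,
    method: Literal["kmeans", "cmeans"] = "cmeans",
    base_seed: int = 0,
    **fit_kwargs,
) -> list[ClusterModel]:
    """Fit ``repeats`` models with seeds base_seed, base_seed+1, ...

    Both objectives are non-convex; restarts with different random
    centroid initializations sample the local optima.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    fit = {"kmeans": kmeans_fit, "cmeans": cmeans_fit}[method]
    return [fit(m, k, base_seed + r, **fit_kwargs) for r in range(repeats)]


def write_clustering_tsv(model: ClusterModel, path) -> None:
    """Cluster output TSV: site, hard cluster, membership of that cluster,
    then the full membership vector."""
    import pandas as pd

    mcols = {f"membership_{i + 1}": model.membership[:, i] for i in range(model.k)}
    df = pd.DataFrame(
        {
            "site": model.site_ids,
            "cluster": model.hard_assignment + 1,
            "membership": model.membership[np.arange(model.n_sites), model.hard_assignment],
            **mcols,
        }
    )
    df.to_csv(path, sep="\t", index=False)
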