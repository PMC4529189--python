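"""The CLUE scoring engine.

For a partitioning of phosphosites into k clusters, each (cluster i,
kinase j) pair defines a 2x2 contingency table over the dataset universe:

    a_ij  sites of kinase j inside cluster i
    b_ij  sites of kinase j outside cluster i
    c_ij  sites in cluster i not annotated to j
    d_ij  sites neither in cluster i nor annotated to j

Over-representation of j's substrates in cluster i (odds ratio
theta = (a/b)/(c/d) > 1) is tested with the one-sided Fisher exact test,
i.e. the hypergeometric upper tail P(X >= a).  The information content of
cluster i is summarized by its best kinase, p(cluster_i) = min_j p_ij,
and the k per-cluster p-values are combined with Fisher's combined
probability test,

    P_k = P(chi2_{2k} > -2 sum_i ln p(cluster_i)),

yielding the enrichment score E_k = -log10 P_k.  Sweeping k and taking
the k with the highest mean score over random restarts selects the most
biologically informative partitioning: over-clustering splits a kinase's
substrates across clusters (penalized by the per-cluster exact tests),
while under-clustering merges unrelated sites (penalized by the combined
test over fewer, weaker clusters).

The per-cluster minima are treated as if uniform under the null, exactly
as the score is defined; they are extreme order statistics, so E_k is a
selection criterion, not a calibrated p-value (see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats

from .annotations import AnnotationDB
from .clustering import ClusterModel, fit_repeated
from .preprocessing import TemporalMatrix

logger = logging.getLogger(__name__)

LOG10_E = math.log10(math.e)


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 overlap counts between one cluster and one kinase's substrates."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d <= 0:
            raise ValueError("universe must be non-empty")

    @property
    def universe(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_substrates(self) -> int:
        return self.a + self.b

    @property
    def cluster_size(self) -> int:
        return self.a + self.c


def fisher_one_sided_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Vectorized one-sided Fisher exact p-values for over-representation.

    With fixed margins, "odds ratio at least as large as observed" is
    equivalent to "a at least as large", so the p-value is the
    hypergeometric upper tail P(X >= a) with population a+b+c+d, success
    count a+b, and draws a+c.  Degenerate margins (no substrates or an
    empty cluster) give 1.
    """
    a, b, c, d = np.broadcast_arrays(a, b, c, d)
    a = np.asarray(a, dtype=np.int64)
    universe = a + b + c + d
    substrates = a + b
    cluster = a + c
    p = stats.hypergeom.sf(a - 1, universe, substrates, cluster)
    return np.where((substrates == 0) | (cluster == 0), 1.0, p)


def fisher_one_sided(counts: ContingencyCounts) -> float:
    """One-sided Fisher exact p-value for a single 2x2 table.

    See :func:`fisher_one_sided_many` for the tail convention.
    """
    return float(
        fisher_one_sided_many(counts.a, counts.b, counts.c, counts.d)[()]
    )


def log_fisher_one_sided(counts: ContingencyCounts) -> float:
    """Natural log of :func:`fisher_one_sided`.

    Needed for large datasets where the strongest enrichments underflow
    float64 probabilities; computed by log-sum-exp over the
    hypergeometric log-pmf of the upper tail.
    """
    if counts.n_substrates == 0 or counts.cluster_size == 0:
        return 0.0
    hi = min(counts.n_substrates, counts.cluster_size)
    if counts.a <= max(0, counts.n_substrates + counts.cluster_size - counts.universe):
        return 0.0
    support = np.arange(counts.a, hi + 1)
    logpmf = stats.hypergeom.logpmf(
        support, counts.universe, counts.n_substrates, counts.cluster_size
    )
    return float(min(special.logsumexp(logpmf), 0.0))


def cluster_min_p(p_row: Sequence[float]) -> float:
    """p(cluster_i) = min over kinases; an empty row (no eligible kinase)
    is uninformative and returns 1."""
    p = np.asarray(list(p_row), dtype=float)
    if p.size == 0:
        return 1.0
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(p.min())


def _chi2_even_logsf(x: float, k: int) -> float:
    """log upper tail of chi-squared with 2k (even) degrees of freedom.

    For even df the tail has the closed form
    ``exp(-x/2) * sum_{i<k} (x/2)^i / i!``; evaluating it with
    log-sum-exp keeps E_k finite and discriminating for arbitrarily
    large test statistics, where the distribution's survival function
    underflows.
    """
    if x <= 0:
        return 0.0
    i = np.arange(k)
    terms = i * np.log(x / 2.0) - special.gammaln(i + 1)
    return float(min(-x / 2.0 + special.logsumexp(terms), 0.0))


def combine_fisher_from_logs(log_ps: Sequence[float]) -> tuple[float, float, float]:
    """Fisher's combination from natural-log p-values.

    Returns ``(log P_k, P_k, E_k)``; the whole computation stays in log
    space so many very small per-cluster p-values (large k, strong
    enrichment) never saturate the score.
    """
    logp = np.asarray(list(log_ps), dtype=float)
    if logp.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(logp > 0) or not np.all(np.isfinite(logp)):
        raise ValueError("log p-values must be finite and <= 0")
    x = -2.0 * logp.sum()
    log_pk = _chi2_even_logsf(x, logp.size)
    return log_pk, float(np.exp(log_pk)), float(-log_pk * LOG10_E)


def combine_fisher(cluster_ps: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability test over the k per-cluster p-values.

    Returns ``(P_k, E_k)`` where ``P_k`` is the upper tail of a
    chi-squared distribution with 2k degrees of freedom at
    ``-2 sum ln p`` and ``E_k = -log10 P_k``.  An exact p-value of 0 is
    floored to the smallest positive float with a warning (use
    :func:`combine_fisher_from_logs` to avoid the floor entirely).
    """
    p = np.asarray(list(cluster_ps), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        logger.warning("p-value of 0 floored to smallest positive float")
        p = np.maximum(p, np.nextafter(0.0, 1.0))
    _, pk, ek = combine_fisher_from_logs(np.log(p))
    return pk, ek


@dataclass
class EnrichmentTable:
    """Per-(cluster, kinase) Fisher p-values and the combined CLUE score.

    ``log_p`` carries the natural-log p-values without underflow;
    ``p = exp(log_p)`` is floored at the smallest positive float so it
    stays in (0, 1].
    """

    kinases: list[str]
    p: np.ndarray = field(repr=False)  # k x m
    cluster_p: np.ndarray = field(repr=False)  # length k
    combined_p: float = np.nan
    score: float = np.nan  # E_k
    df: int = 0  # 2k
    log_p: np.ndarray | None = field(default=None, repr=False)  # k x m
    cluster_log_p: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.p.shape[0]

    def p_of(self, cluster: int, kinase: str) -> float:
        return float(self.p[cluster, self.kinases.index(kinase)])


def score_clustering(model: ClusterModel, db: AnnotationDB) -> EnrichmentTable:
    """Build the full enrichment table for one clustering.

    ``db`` must already be restricted to the clustered sites
    (:func:`clue.annotations.restrict_to_dataset`); the enrichment
    universe is all clustered sites, annotated or not.
    """
    site_index = {s: idx for idx, s in enumerate(model.site_ids)}
    unknown = sorted(db.all_sites() - site_index.keys())
    if unknown:
        raise ValueError(
            f"{len(unknown)} annotated site(s) absent from the clustered "
            f"matrix (restrict the DB to the dataset first): {unknown[:5]}"
        )
    n = model.n_sites
    k = model.k
    kinases = db.kinases
    m_kin = len(kinases)
    if m_kin == 0:
        log_p = np.zeros((k, 0))
        cluster_log_p = np.zeros(k)
    else:
        member = np.zeros((n, m_kin), dtype=np.int64)
        for j, kin in enumerate(kinases):
            rows = [site_index[s] for s in db.substrates_of[kin]]
            member[rows, j] = 1
        onehot = np.zeros((n, k), dtype=np.int64)
        onehot[np.arange(n), model.hard_assignment] = 1
        a = onehot.T @ member  # k x m
        substrate_counts = member.sum(axis=0)  # a+b per kinase
        cluster_sizes = onehot.sum(axis=0)  # a+c per cluster
        p = fisher_one_sided_many(
            a,
            substrate_counts[None, :] - a,
            cluster_sizes[:, None] - a,
            n - substrate_counts[None, :] - cluster_sizes[:, None] + a,
        )
        with np.errstate(divide="ignore"):
            log_p = np.log(p)
        # strongest enrichments can underflow float64; redo those in log space
        for i, j in zip(*np.where(p == 0.0)):
            log_p[i, j] = log_fisher_one_sided(
                ContingencyCounts(
                    a=int(a[i, j]),
                    b=int(substrate_counts[j] - a[i, j]),
                    c=int(cluster_sizes[i] - a[i, j]),
                    d=int(n - substrate_counts[j] - cluster_sizes[i] + a[i, j]),
                )
            )
        # empty clusters (possible under pathological fits) are uninformative
        log_p[cluster_sizes == 0, :] = 0.0
        cluster_log_p = log_p.min(axis=1)
    log_pk, combined_p, score = combine_fisher_from_logs(cluster_log_p)
    tiny = np.nextafter(0.0, 1.0)
    return EnrichmentTable(
        kinases=list(kinases),
        p=np.maximum(np.exp(log_p), tiny),
        cluster_p=np.maximum(np.exp(cluster_log_p), tiny),
        combined_p=max(combined_p, tiny) if log_pk < 0 else combined_p,
        score=score,
        df=2 * k,
        log_p=log_p,
        cluster_log_p=cluster_log_p,
    )


@dataclass
class SweepResult:
    """Outcome of evaluating a range of cluster numbers."""

    k_values: list[int]
    mean_score: np.ndarray
    per_run_scores: np.ndarray = field(repr=False)  # len(k_values) x repeats
    optimal_k: int = 0
    best_model: ClusterModel | None = field(default=None, repr=False)
    best_table: EnrichmentTable | None = field(default=None, repr=False)
    uninformative: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": self.k_values,
                "mean_enrichment_score": self.mean_score,
                **{
                    f"run_{r + 1}": self.per_run_scores[:, r]
                    for r in range(self.per_run_scores.shape[1])
                },
            }
        )


def sweep_k(
    m: TemporalMatrix,
    db: AnnotationDB,
    k_range: Sequence[int] | range = range(2, 21),
    repeats: int = 10,
    method: Literal["kmeans", "cmeans"] = "cmeans",
    base_seed: int = 0,
    **fit_kwargs,
) -> SweepResult:
    """Evaluate each k with ``repeats`` random restarts and select the k
    maximizing the mean enrichment score.

    The mean is taken over the per-run scores E_k (not over P_k, which
    would be dominated by single extreme runs).  Ties in the mean go to
    the smallest k (parsimony).  ``best_model`` is the single run with the
    highest score at the optimal k.  If no k attains a positive mean
    score the result is flagged ``uninformative`` (no annotation signal).
    """
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values:
        raise ValueError("empty k_range")
    if k_values[0] < 2 or k_values[-1] > m.n_sites:
        raise ValueError(f"k_range must lie within [2, {m.n_sites}]")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")

    scores = np.zeros((len(k_values), repeats))
    best_per_k: list[tuple[ClusterModel, EnrichmentTable]] = []
    for ki, k in enumerate(k_values):
        models = fit_repeated(m, k, repeats, method=method, base_seed=base_seed, **fit_kwargs)
        tables = [score_clustering(model, db) for model in models]
        scores[ki] = [t.score for t in tables]
        best_run = int(np.argmax(scores[ki]))
        best_per_k.append((models[best_run], tables[best_run]))

    mean_score = scores.mean(axis=1)
    opt_idx = int(np.argmax(mean_score))  # argmax takes the first (smallest k) on ties
    best_model, best_table = best_per_k[opt_idx]
    return SweepResult(
        k_values=k_values,
        mean_score=mean_score,
        per_run_scores=scores,
        optimal_k=k_values[opt_idx],
        best_model=best_model,
        best_table=best_table,
        uninformative=bool(mean_score[opt_idx] <= 0.0),
    )


def enriched_kinases(
    table: EnrichmentTable,
    alpha: float = 0.05,
    *,
    bh_correct: bool = False,
) -> list[list[tuple[str, float]]]:
    """Per cluster, the kinases with p < alpha sorted ascending by p.

    With ``bh_correct`` the Benjamini-Hochberg adjusted p-values (across
    kinases within each cluster) are thresholded and reported instead of
    the raw ones.  ``alpha=1`` lists every kinase.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    out: list[list[tuple[str, float]]] = []
    for i in range(table.k):
        row = table.p[i]
        if bh_correct and row.size:
            row = _bh_adjust(row)
        mask = (row < alpha) if alpha < 1 else (row <= 1)
        hits = [(table.kinases[j], float(row[j])) for j in np.where(mask)[0]]
        hits.sort(key=lambda kp: (kp[1], kp[0]))
        out.append(hits)
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def minmax_normalize(
    scores: Sequence[float],
    direction: Literal["maximize", "minimize"] = "maximize",
) -> np.ndarray:
    """Min-Max transform of a per-k score curve into [0, 1].

    Scores from criteria that *minimize* their objective are flipped to
    1 - normalized so that higher is always better, making curves from
    different cluster-number criteria co-plottable.
    """
    s = np.asarray(list(scores), dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores")
    lo, hi = s.min(), s.max()
    if lo == hi:
        raise ValueError("all scores equal: Min-Max normalization undefined")
    norm = (s - lo) / (hi - lo)
    if direction == "minimize":
        norm = 1.0 - norm
    elif direction != "maximize":
        raise ValueError("direction must be 'maximize' or 'minimize'")
    return norm
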