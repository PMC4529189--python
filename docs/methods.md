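# Methods

## The selection score

Given a hard partitioning of *n* phosphosites into *k* clusters and a
kinase-substrate annotation database restricted to those sites, every
(cluster *i*, kinase *j*) pair yields a 2×2 contingency table with cells
*a* (substrates of *j* in cluster *i*), *b* (substrates of *j*
elsewhere), *c* (cluster members not annotated to *j*) and *d* (the
remainder). The enrichment universe is **all clustered sites**,
annotated or not — the literal reading of those cell definitions.
Over-representation (odds ratio (a/b)/(c/d) > 1) is tested with the
one-sided Fisher exact test; with margins fixed, "odds ratio at least as
extreme" is equivalent to "a at least as large", so the p-value is the
hypergeometric upper tail P(X ≥ a).

Each cluster contributes its most enriched kinase,
p(cluster i) = min_j p_ij, and the k per-cluster p-values are combined
by Fisher's method: X = −2 Σ ln p(cluster i) referred to a chi-squared
distribution with 2k degrees of freedom. The enrichment score is
E_k = −log₁₀ P_k, and the sweep selects the k with the highest mean E_k
over random restarts (ties go to the smallest k).

Two properties of this construction matter in practice:

* **It is a selection criterion, not a calibrated p-value.** The
  per-cluster minima are extreme order statistics over m kinases, not
  uniform nulls, so every cluster contributes more than its 2 degrees of
  freedom "deserve" on average and E_k is inflated in absolute terms.
  Only differences across k are meaningful. A corollary, visible in very
  clean low-noise simulations: when clusters are so tight that splitting
  one costs almost nothing in per-cluster enrichment, the order-statistic
  inflation can push the optimum one or two clusters above the truth.
  At realistic noise levels (site noise comparable to the profile
  amplitude, as in the shipped benchmark) splitting dilutes the split
  cluster's enrichment and the score peaks at the true k.
* **Averaging happens on E_k**, not on P_k: averaging the probabilities
  across restarts would be dominated by the single largest value.

### Numerical policy

All tail probabilities are carried in natural-log space end to end.
Per-table p-values are computed with `scipy.stats.hypergeom.sf`; any
cell that underflows float64 (strong enrichments in datasets of a few
thousand sites routinely reach p < 10⁻³⁰⁰) is recomputed as a
log-sum-exp over the hypergeometric log-pmf. The chi-squared upper tail
uses the closed form for even degrees of freedom,
P = e^(−X/2) Σ_{i<k} (X/2)^i / i!, evaluated by log-sum-exp, which stays
finite and discriminating for arbitrarily large X — the generic survival
function saturates at 0 there, which would make all large k tie at
E_k = ∞. The `EnrichmentTable` keeps both `log_p` (exact) and
`p = exp(log_p)` floored at the smallest positive float (reporting).

Degenerate tables (kinase with no in-dataset substrates, empty cluster)
score p = 1, neutral under Fisher's combination since ln 1 = 0. An
all-zero mean-score curve (no annotation signal at any k, e.g. a purely
random database) is reported with an `uninformative` flag rather than a
silently arbitrary optimum.

## Clustering

Profiles are z-scored per site (population SD) before clustering by
default, so Euclidean distance compares temporal shapes rather than
magnitudes; constant profiles have no shape and are dropped with a
warning. Both k-means (Lloyd) and fuzzy c-means (Bezdek) are provided;
enrichment always uses the hard argmax assignment, with the fuzzy
memberships kept as per-site confidence metadata.

Defaults and their reasons:

* **Initialization**: k distinct data rows drawn uniformly under the
  seed (k-means++ available but not the default); selection robustness
  comes from restarts, 10 by default, seeded base, base+1, ….
* **Convergence**: tolerance 1e−6 on the maximum parameter change
  (centroid shift for k-means, membership change for c-means), capped at
  200 iterations.
* **Empty k-means cluster**: re-seeded at the point farthest from the
  emptied centroid.
* **Fuzzifier m = 1.5.** The textbook default of 2.0 fails on
  row-standardized profiles: all points lie on a sphere of radius √T in
  T-dimensional time space, relative distance contrasts are modest, and
  at m = 2 the memberships flatten until several centroids collapse onto
  the data centroid — hard clusters empty out, templates merge, and the
  k-sweep drifts past the true cluster number. At m = 1.5 (or 1.2, or
  with plain k-means) the benchmark recovers the true k exactly. This is
  the known membership-degeneracy regime of fuzzy c-means for
  standardized expression-like data; m is exposed as a parameter and
  m → 1⁺ reproduces k-means.

## The simulation benchmark

The generator emulates a designed phosphoproteomics time-course
experiment:

* **14 temporal templates × 7 time points** (`data/templates.tsv`, a
  versioned fixture): monotone rises/falls, early/mid/late transients,
  saturating plateaus, delayed responses, two oscillations, and a square
  pulse, on a common 0–4 amplitude scale. After per-profile
  standardization the minimum pairwise Euclidean distance between
  templates is 1.56 — distinct but deliberately not orthogonal.
* **Site noise**: each simulated site is its template plus i.i.d.
  Gaussian noise, σ = 1 by default — of the same order as the
  within-template amplitude SD (≈1.3–2.0), so clusters overlap
  realistically; 500 sites per template by default.
* **Annotations**: 100 kinase groups × 50 substrates. g *informative*
  groups sample their substrates from a single template's sites (one
  distinct template each); the rest sample uniformly from all sites.
  Annotation noise s replaces ⌈s·50⌉ members of each informative group
  with sites of a different template, drawn uniformly (not
  adversarially). g = 0 models the no-prior-knowledge situation.
* **Design stressors**: `time_subset` keeps a subset of time points
  (e.g. (0, 3, 6) for a 3-point design); `noisy_tail` replaces trailing
  time points with pure Gaussian noise around zero, modeling
  non-functional phosphorylation accumulating late after stimulus.

Replicate r of a scenario re-runs the whole pipeline under seed
(base + r); matrix noise and annotation sampling use separate
deterministic substreams of the spec seed.

What the benchmark does *not* emulate, and hence what passing it does
not establish for real data: missing values and peptide-level
aggregation, correlated (non-i.i.d.) noise across time points,
heavy-tailed site variation, kinases with widely varying substrate
counts, overlapping kinase groups with shared substrates, and any
mismatch between the clustered quantity (ratios vs log-ratios) and the
annotation universe. Real-data performance also depends entirely on the
quality and coverage of the annotation database used.

### Benchmark problem sizes

The shipped acceptance run (`scripts/acceptance.py`) and the heavy
tests keep every protocol parameter at its reference value (σ = 1,
100 × 50 database, k = 2..20, 10 restarts, 10 replicates) and vary only
the number of sites per template. The 14-template scenario runs at the
reference 500 sites per template: distinguishing k = 14 from k = 15
depends on per-cluster site density, and at 200 sites a minority of
replicates over-split by one. The 4-template and annotation-noise
scenarios are insensitive to this and run at 200 sites per template,
which keeps a full benchmark run to minutes on a single core. The
noise-robustness scenario fixes g = 5 informative groups on a
5-template dataset, so every template has informative coverage and the
mis-assignment fraction is the only degraded quantity.

## Motif scoring

A kinase's PSSM is the plain per-position empirical frequency matrix of
its substrates' aligned windows (typically ±7 residues, width 15, but
the width is taken from the input). No pseudocounts by default — the
matrix is an observed frequency, with an optional pseudocount for sparse
training sets — and no background correction: a window scores
Σ_j P(window_j, j) ∈ [0, width]. Placeholder characters (X for unknown,
`_`/`-`/`*` for window padding at protein termini) are excluded from
training counts (the position is renormalized over what remains) and
contribute 0 when scoring. Per-cluster motif enrichment is the median
site score; ties at the maximum report all tied clusters.

## Annotation handling

Phosphosite identifiers are gene symbol + residue concatenated with a
configurable separator (default `;`, e.g. `BAD;S136`); residues are
S/T/Y with a 1-based position. Gene symbols are upper-cased for human
(symbol convention) and preserved as-is otherwise. A site annotated to
several kinases counts once under each kinase. Before scoring, the
database is intersected with the clustered sites and kinases with fewer
than 2 surviving substrates are dropped — a single-substrate kinase
cannot be meaningfully enriched but would still compete in the
per-cluster minimum. Multiple-testing correction is deliberately absent
from the score itself (the min-p/Fisher construction is the method);
the per-cluster kinase report can optionally apply Benjamini-Hochberg
across kinases, off by default.

## Known limitations

* E_k values are comparable across k for one dataset + database, not
  across datasets or databases.
* The chi-squared combination assumes independent per-cluster p-values;
  clusters share the universe, so this is approximate by construction.
* Very low-noise data with weak annotation coverage can over-split (see
  above); inspecting the score curve rather than just its argmax is
  recommended whenever it is flat around the maximum.
* The fold-change pre-filter assumes the first (or stated) time point is
  a valid unstimulated reference.
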