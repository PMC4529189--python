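# clue

Knowledge-based cluster evaluation for time-series phosphoproteomics.

In a quantitative phosphoproteomics time course, thousands of
phosphorylation sites are measured over a handful of time points, and
substrates of the same kinase tend to share a temporal profile.
Partitioning the sites into clusters with k-means-style algorithms is
therefore a standard first step toward identifying the active kinases —
but the result depends critically on the chosen number of clusters *k*.
`clue` selects *k* by asking a biological question instead of a geometric
one: **which partitioning is most enriched for known kinase-substrate
relationships?**

For a candidate clustering into clusters *i* = 1…*k*, each (cluster *i*,
kinase *j*) pair defines a 2×2 contingency table (*a₍ᵢⱼ₎* substrates of
*j* inside cluster *i*, *b₍ᵢⱼ₎* outside, *c₍ᵢⱼ₎* cluster members not
annotated to *j*, *d₍ᵢⱼ₎* the rest), tested one-sided for
over-representation with Fisher's exact test. Each cluster is summarized
by its best kinase, *p*(cluster *i*) = minⱼ *p₍ᵢⱼ₎*, and the per-cluster
p-values are combined with Fisher's combined probability test:

    P_k = P( χ²_{2k} > −2 Σᵢ ln p(cluster i) ),      E_k = −log₁₀ P_k

The *k* maximizing the mean enrichment score *E_k* over random restarts
is reported, together with the kinases enriched in each cluster of the
winning clustering (Fisher p < α) and, optionally, per-cluster motif
enrichment against a kinase's position-specific scoring matrix (PSSM).

The package also ships the full simulation benchmark used to validate
this selection rule: 14 canonical 7-point temporal templates, Gaussian
site noise, and matched synthetic kinase-substrate databases with a
controllable number of informative kinase groups and a controllable
fraction of mis-assigned substrates.

## Worked example

Simulate a 3-template dataset with matched annotations, then let the
sweep find the number of clusters:

```sh
clue simulate --clusters 3 --sites-per-cluster 100 --sigma 1.0 \
    --groups 20 --group-size 50 --g 3 --seed 0 --out sim/
# wrote 300 sites x 7 time points to sim

clue sweep --matrix sim/matrix.tsv --annotations sim/annotations.gmt \
    --k-min 2 --k-max 6 --repeats 3 --seed 1 --out sweep/
# optimal k = 3 (mean E_k = 78.943)
```

The sweep writes `sweep_scores.tsv` (mean and per-run *E_k* for every
*k*), `best_clustering.tsv` (hard cluster, membership score, and full
fuzzy membership vector per site), `enriched_kinases.tsv` (per cluster,
kinases with Fisher p < 0.05 sorted by p-value), and `manifest.json`
(all parameters and seeds plus input digests, sufficient to re-execute
the run bit-identically). Here the mean enrichment score peaks at
*k* = 3 — the three informative kinase groups each land intact in one
cluster, so *E_k* drops whenever the sweep merges two templates (their
substrates dilute each other) or splits one (its substrates scatter).

The same analysis on a real dataset replaces `sim/matrix.tsv` with a
site × time-point table (first column site IDs such as `BAD;S136`) and
`sim/annotations.gmt` with either a GMT kinase-set file or a
PhosphoSitePlus-style kinase-substrate table (`--species human`);
`--fold-change 2` reproduces the usual "≥2-fold change vs the first
time point" pre-filter.

From Python, the same pipeline is:

```python
from clue import (TemporalMatrix, read_gmt, restrict_to_dataset,
                  standardize_rows, sweep_k, enriched_kinases)

matrix = standardize_rows(TemporalMatrix.from_tsv("sim/matrix.tsv"))
db = restrict_to_dataset(read_gmt("sim/annotations.gmt"), matrix.site_ids)
result = sweep_k(matrix, db, k_range=range(2, 7), repeats=3, base_seed=1)
result.optimal_k            # 3
enriched_kinases(result.best_table)[0][:1]   # [('KIN003', 2.36e-26)]
```

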