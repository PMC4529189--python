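"""Position-specific scoring matrices for kinase recognition motifs.

Kinases recognize their substrates partly through the amino acids
flanking the phosphorylated residue.  Given the aligned fixed-width
sequence windows of a kinase's known substrates (typically +/-7 residues
around the phosphosite, width 15), the PSSM records the empirical
frequency P_{a,j} of amino acid a at window position j.  A candidate
window is scored by summing the matrix frequencies of its residues,

    score(w) = sum_j P_{w[j], j},

a raw frequency sum in [0, width] (no background correction).  Scoring
every site in a clustering and taking the per-cluster median highlights
the cluster whose members best match the kinase's motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterModel

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: characters that carry no motif information (unknown residue, window padding)
PLACEHOLDERS = frozenset("X_-*")


@dataclass
class PSSM:
    """Empirical per-position amino-acid frequencies of substrate windows."""

    probabilities: np.ndarray = field(repr=False)  # width x 20
    kinase: str = ""
    n_sequences: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != len(AMINO_ACIDS):
            raise ValueError(f"probabilities must be width x {len(AMINO_ACIDS)}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        self.probabilities = p

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probabilities,
            index=[f"pos{j + 1}" for j in range(self.width)],
            columns=list(AMINO_ACIDS),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "position"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kinase: str = "") -> "PSSM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(probabilities=df[list(AMINO_ACIDS)].to_numpy(dtype=float), kinase=kinase)


def build_pssm(
    sequences: list[str],
    kinase: str = "",
    pseudocount: float = 0.0,
) -> PSSM:
    """Empirical frequency PSSM from aligned equal-width windows.

    Placeholder characters (X, _, -, *) are excluded from the counts and
    the position renormalized over what remains; a position with no
    countable character becomes a uniform column (with a warning).  The
    optional ``pseudocount`` is added to every (position, amino acid)
    cell before normalization; the default of 0 keeps the matrix a plain
    observed frequency.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    width = len(sequences[0])
    seqs = [s.upper() for s in sequences]
    bad = [s for s in seqs if len(s) != width]
    if bad:
        raise ValueError(
            f"all windows must share width {width}; offending window {bad[0]!r}"
        )
    counts = np.full((width, len(AMINO_ACIDS)), float(pseudocount))
    for s in seqs:
        for j, ch in enumerate(s):
            if ch in _AA_INDEX:
                counts[j, _AA_INDEX[ch]] += 1.0
            elif ch not in PLACEHOLDERS:
                raise ValueError(f"unknown character {ch!r} in window {s!r}")
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning(
            "no countable residues at position(s) %s; using uniform frequencies",
            list(np.where(empty)[0] + 1),
        )
        counts[empty] = 1.0
        totals[empty] = len(AMINO_ACIDS)
    return PSSM(probabilities=counts / totals[:, None], kinase=kinase, n_sequences=len(seqs))


def motif_score(window: str, pssm: PSSM) -> float:
    """Sum of PSSM frequencies of the window's residues, in [0, width].

    Placeholder characters contribute 0.
    """
    window = window.upper()
    if len(window) != pssm.width:
        raise ValueError(f"window width {len(window)} != PSSM width {pssm.width}")
    score = 0.0
    for j, ch in enumerate(window):
        if ch in _AA_INDEX:
            score += pssm.probabilities[j, _AA_INDEX[ch]]
        elif ch not in PLACEHOLDERS:
            raise ValueError(f"unknown character {ch!r} in window {window!r}")
    return float(score)


def cluster_motif_enrichment(
    model: ClusterModel,
    windows: dict[str, str],
    pssm: PSSM,
) -> tuple[dict[int, float], list[int]]:
    """Median motif score per cluster and the top-scoring cluster(s).

    Sites without a sequence window are skipped (their count is logged);
    clusters in which no site has a window get a median of NaN and never
    win.  Ties at the maximum report all tied clusters.
    """
    scores: dict[int, list[float]] = {i: [] for i in range(model.k)}
    missing = 0
    for site, cluster in zip(model.site_ids, model.hard_assignment):
        w = windows.get(site)
        if w is None:
            missing += 1
            continue
        scores[int(cluster)].append(motif_score(w, pssm))
    if missing:
        logger.info("%d of %d sites lack a sequence window", missing, model.n_sites)
    if all(not v for v in scores.values()):
        raise ValueError("no clustered site has a sequence window")
    medians = {
        i: (float(np.median(v)) if v else float("nan")) for i, v in scores.items()
    }
    best = np.nanmax(list(medians.values()))
    top = [i for i, v in medians.items() if v == best]
    return medians, top


def read_windows(path: str | Path) -> dict[str, str]:
    """Read site -> window, from FASTA (IDs are record names) or from a
    two-column TSV (site ID, window) with or without a header."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        from Bio import SeqIO

        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns (site, window)")
    first_window = str(df.iloc[0, 1])
    if not all(ch in _AA_INDEX or ch in PLACEHOLDERS for ch in first_window.upper()):
        df = df.iloc[1:]  # header row
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].str.upper()))
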