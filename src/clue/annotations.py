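"""Kinase-substrate annotation databases and phosphosite identifiers.

A phosphosite is identified by its host protein's official gene symbol plus
the phosphorylated residue (one-letter amino acid and 1-based position),
e.g. ``BAD;S136``.  An :class:`AnnotationDB` maps each kinase to the set of
such identifiers it is known to phosphorylate; a site phosphorylated by
several kinases appears under each of them, and every kinase is counted
independently in downstream enrichment tests.

Supported on-disk formats are PhosphoSitePlus-style kinase-substrate tables
(tab-separated, ``KINASE`` / ``SUBSTRATE`` / ``SUB_ORG`` columns plus a
residue column) and GMT kinase-set files.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SEPARATOR = ";"

_RESIDUE_RE = re.compile(r"^([STY])([1-9][0-9]*)$")


class AnnotationFormatError(ValueError):
    """Raised when an annotation file does not match its declared format."""


@dataclass(frozen=True, order=True)
class PhosphoSiteID:
    """A phosphorylation site: gene symbol + residue (e.g. gene=BAD, residue=S136).

    The residue letter must be one of S/T/Y (serine, threonine, tyrosine)
    and the position a positive integer.
    """

    gene: str
    residue: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("empty gene symbol")
        if not _RESIDUE_RE.match(self.residue):
            raise ValueError(
                f"invalid residue {self.residue!r} for gene {self.gene!r}: "
                "expected one of S/T/Y followed by a positive position, e.g. 'S136'"
            )

    @property
    def amino_acid(self) -> str:
        return self.residue[0]

    @property
    def position(self) -> int:
        return int(self.residue[1:])

    def render(self, separator: str = DEFAULT_SEPARATOR) -> str:
        """Concatenate gene and residue into the dataset identifier."""
        return f"{self.gene}{separator}{self.residue}"

    @classmethod
    def parse(cls, text: str, separator: str = DEFAULT_SEPARATOR) -> "PhosphoSiteID":
        """Inverse of :meth:`render`; ``parse(x.render()) == x``."""
        gene, sep, residue = text.rpartition(separator)
        if not sep or not gene:
            raise ValueError(f"cannot parse phosphosite ID {text!r} with separator {separator!r}")
        return cls(gene=gene, residue=residue)


@dataclass
class AnnotationDB:
    """Kinase -> set of phosphosite identifiers (rendered strings).

    Sites may appear under several kinases; within one kinase each site is
    counted once.  ``species`` is a free-text label carried through I/O.
    """

    substrates_of: dict[str, frozenset[str]] = field(default_factory=dict)
    species: str = ""

    def __post_init__(self) -> None:
        self.substrates_of = {k: frozenset(v) for k, v in self.substrates_of.items() if v}

    @property
    def kinases(self) -> list[str]:
        return sorted(self.substrates_of)

    @property
    def n_kinases(self) -> int:
        return len(self.substrates_of)

    @property
    def n_interactions(self) -> int:
        """Total kinase-substrate pairs; a multi-kinase site counts once per kinase."""
        return sum(len(v) for v in self.substrates_of.values())

    def all_sites(self) -> frozenset[str]:
        out: set[str] = set()
        for v in self.substrates_of.values():
            out |= v
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.substrates_of)

    def __getitem__(self, kinase: str) -> frozenset[str]:
        return self.substrates_of[kinase]

    def __contains__(self, kinase: str) -> bool:
        return kinase in self.substrates_of

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationDB):
            return NotImplemented
        return self.substrates_of == other.substrates_of and self.species == other.species


def parse_phosphositeplus(
    table_path: str | Path,
    species: str,
    separator: str = DEFAULT_SEPARATOR,
    *,
    kinase_column: str = "KINASE",
    substrate_column: str = "SUBSTRATE",
    organism_column: str = "SUB_ORG",
    residue_column: str = "SUB_MOD_RSD",
    uppercase_genes: bool | None = None,
) -> AnnotationDB:
    """Read a PhosphoSitePlus-style kinase-substrate table.

    Only rows whose organism column equals ``species`` (case-insensitive)
    are kept.  Duplicate (kinase, site) rows collapse to one interaction.
    Leading banner lines before the header row are skipped.

    ``uppercase_genes`` defaults to True for human (gene symbols are
    upper-case by convention) and False otherwise; pass an explicit bool
    to override.
    """
    if not species:
        raise ValueError("species must be non-empty")
    required = [kinase_column, substrate_column, organism_column, residue_column]

    path = Path(table_path)
    text = path.read_text()
    header_idx = None
    for idx, line in enumerate(text.splitlines()):
        cols = line.rstrip("\n").split("\t")
        if all(c in cols for c in required[:3]):
            header_idx = idx
            break
    if header_idx is None:
        # no recognizable header at all: report the first missing column of
        # the first non-empty line for a usable message
        first = text.splitlines()[0].split("\t") if text.strip() else []
        missing = next(c for c in required[:3] if c not in first)
        raise AnnotationFormatError(f"missing required column {missing!r} in {path}")

    df = pd.read_csv(io.StringIO(text), sep="\t", skiprows=header_idx, dtype=str)
    for col in required:
        if col not in df.columns:
            raise AnnotationFormatError(f"missing required column {col!r} in {path}")

    if uppercase_genes is None:
        uppercase_genes = species.strip().lower() == "human"

    df = df[df[organism_column].str.strip().str.lower() == species.strip().lower()]
    if df.empty:
        logger.warning("no rows left after filtering %s for species %r", path, species)
        return AnnotationDB(species=species)

    substrates: dict[str, set[str]] = {}
    for kinase, gene, residue in zip(
        df[kinase_column], df[substrate_column], df[residue_column]
    ):
        if pd.isna(kinase) or pd.isna(gene) or pd.isna(residue):
            continue
        gene = str(gene).strip()
        if uppercase_genes:
            gene = gene.upper()
        site = PhosphoSiteID(gene=gene, residue=str(residue).strip().upper())
        substrates.setdefault(str(kinase).strip(), set()).add(site.render(separator))
    return AnnotationDB(substrates_of={k: frozenset(v) for k, v in substrates.items()}, species=species)


def read_gmt(path: str | Path) -> AnnotationDB:
    """Read kinase sets from a GMT file (name, description, members...)."""
    path = Path(path)
    substrates: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: GMT line needs at least 3 tab-separated "
                    f"fields (name, description, >=1 member), got {len(fields)}"
                )
            name = fields[0]
            members = frozenset(m for m in fields[2:] if m)
            substrates[name] = members
    if not substrates:
        logger.warning("GMT file %s contains no kinase sets", path)
    return AnnotationDB(substrates_of=substrates)


def write_gmt(db: AnnotationDB, path: str | Path, description: str = "na") -> None:
    """Write kinase sets as GMT, kinases and members sorted for stable output."""
    path = Path(path)
    with path.open("w") as fh:
        for kinase in db.kinases:
            members = "\t".join(sorted(db.substrates_of[kinase]))
            fh.write(f"{kinase}\t{description}\t{members}\n")


def restrict_to_dataset(
    db: AnnotationDB,
    sites: Iterable[str],
    min_substrates: int = 2,
) -> AnnotationDB:
    """Intersect each kinase's substrates with the dataset's sites.

    Kinases left with fewer than ``min_substrates`` in-dataset sites are
    dropped: a kinase with a single surviving substrate cannot drive
    enrichment and only inflates the per-cluster minimum p-value.
    Idempotent; never adds sites or kinases.
    """
    if min_substrates < 1:
        raise ValueError("min_substrates must be >= 1")
    universe = frozenset(sites)
    kept = {
        kinase: inter
        for kinase, subs in db.substrates_of.items()
        if len(inter := subs & universe) >= min_substrates
    }
    return AnnotationDB(substrates_of=kept, species=db.species)
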