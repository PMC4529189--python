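"""Filtering and standardization of phosphosite time-course matrices.

The clustering substrate is a :class:`TemporalMatrix`: one row per
phosphosite, one column per time point, values being abundance ratios (or
log2 ratios) from a quantitative MS time course.  Before clustering, sites
without a real temporal response are removed by a fold-change filter and
profiles are z-scored row-wise so that Euclidean clustering compares
temporal *shapes* rather than absolute magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TemporalMatrix:
    """Phosphosite x time-point matrix of real-valued profiles.

    ``site_ids`` and ``time_labels`` keep their order across all
    operations; site IDs must be unique and values finite.
    """

    site_ids: list[str]
    time_labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.time_labels = [str(t) for t in self.time_labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, t = self.values.shape
        if n != len(self.site_ids) or t != len(self.time_labels):
            raise ValueError(
                f"shape mismatch: {n} x {t} values vs "
                f"{len(self.site_ids)} sites and {len(self.time_labels)} time points"
            )
        if t < 2:
            raise ValueError("need at least 2 time points")
        if len(set(self.site_ids)) != n:
            seen: set[str] = set()
            dup = next(s for s in self.site_ids if s in seen or seen.add(s))
            raise ValueError(f"duplicate site ID {dup!r}")
        if not np.all(np.isfinite(self.values)):
            bad = [self.site_ids[i] for i in np.where(~np.isfinite(self.values).all(axis=1))[0][:5]]
            raise ValueError(f"non-finite values in rows: {bad}")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.time_labels)

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        df = self.to_frame()
        df.index.name = "site"
        df.to_csv(path, sep=sep)

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str | None = None) -> "TemporalMatrix":
        """Read a matrix whose first column is the site ID, remaining
        columns the time points in order.  ``sep=None`` infers TSV vs CSV
        from the file extension."""
        path = Path(path)
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(
            site_ids=list(df.index.astype(str)),
            time_labels=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
        )

    def subset_sites(self, keep: np.ndarray) -> "TemporalMatrix":
        keep = np.asarray(keep)
        return TemporalMatrix(
            site_ids=[self.site_ids[i] for i in np.where(keep)[0]] if keep.dtype == bool
            else [self.site_ids[i] for i in keep],
            time_labels=list(self.time_labels),
            values=self.values[keep],
        )


def fold_change_filter(
    m: TemporalMatrix,
    threshold: float = 2.0,
    reference_index: int = 0,
    *,
    log2_scale: bool = False,
) -> TemporalMatrix:
    """Keep sites with >= ``threshold``-fold change at any time point
    relative to the reference time point.

    On the ratio scale a site is kept when ``value/ref >= threshold`` or
    ``ref/value >= threshold`` at some non-reference time point; on the
    log2 scale when ``|value - ref| >= log2(threshold)``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1 (a fold change)")
    if not (-m.n_times <= reference_index < m.n_times):
        raise ValueError(f"reference_index {reference_index} out of range")
    ref = m.values[:, reference_index]
    if log2_scale:
        delta = np.abs(m.values - ref[:, None])
        keep_any = delta >= np.log2(threshold)
    else:
        if np.any(m.values <= 0):
            i = int(np.where((m.values <= 0).any(axis=1))[0][0])
            raise ValueError(
                f"non-positive ratio for site {m.site_ids[i]!r}: fold-change "
                "filtering on the ratio scale requires positive values "
                "(pass log2_scale=True for log ratios)"
            )
        keep_any = (m.values / ref[:, None] >= threshold) | (ref[:, None] / m.values >= threshold)
    keep_any[:, reference_index % m.n_times] = False
    return m.subset_sites(keep_any.any(axis=1))


def standardize_rows(m: TemporalMatrix) -> TemporalMatrix:
    """z-score each profile across time points (population SD).

    Constant rows have no temporal shape; they are dropped with a warning.
    Idempotent.
    """
    sd = m.values.std(axis=1)
    const = sd == 0
    if const.any():
        dropped = [m.site_ids[i] for i in np.where(const)[0]]
        logger.warning(
            "dropping %d constant profile(s) with no temporal shape: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
        m = m.subset_sites(~const)
        sd = sd[~const]
    values = (m.values - m.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return TemporalMatrix(site_ids=list(m.site_ids), time_labels=list(m.time_labels), values=values)
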