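"""Taxa-by-sample count tables and community diversity metrics.

The central container is :class:`AbundanceTable`: a taxa × samples count
matrix (pandas DataFrame) plus a taxonomy frame (kingdom / phylum / genus
per taxon) and optional per-sample trophic group labels (L / M / H).
Phytoplankton counts are microscopy cell densities (cells/L); bacterial
counts are ASV reads.  The two are only ever compared after a
relative-abundance transform.

Provides relative abundance (taxon or phylum level), richness, Shannon
diversity (natural log), seeded rarefaction without replacement, and
Bray–Curtis dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

KINGDOMS = ("phytoplankton", "bacteria")
GROUPS = ("L", "M", "H")

__all__ = [
    "AbundanceTable",
    "relative_abundance",
    "shannon",
    "richness",
    "diversity_table",
    "rarefy",
    "bray_curtis",
]


@dataclass
class AbundanceTable:
    """Taxa × samples abundance matrix with taxonomy and group metadata.

    Attributes
    ----------
    counts:
        DataFrame indexed by taxon_id with sample ids as columns; entries
        are non-negative.
    taxonomy:
        DataFrame indexed by taxon_id with columns ``kingdom`` (one of
        ``phytoplankton`` / ``bacteria``), ``phylum`` and optionally
        ``genus``.  Must cover every taxon in ``counts``.
    group:
        Optional Series mapping sample id → trophic group label (L/M/H).
    meta:
        Free-form provenance notes (e.g. whether counts were rarefied).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    group: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon_id(s): {dupes}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in counts table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.taxonomy.index)
        if len(missing) > 0:
            raise ValueError(f"taxa missing from taxonomy: {missing.tolist()[:5]}")
        bad = set(self.taxonomy.loc[self.counts.index, "kingdom"]) - set(KINGDOMS)
        if bad:
            raise ValueError(f"unknown kingdom label(s): {sorted(bad)}")
        if self.group is not None:
            self.group = self.group.reindex(self.counts.columns)

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def kingdom_of(self, taxon: str) -> str:
        return str(self.taxonomy.loc[taxon, "kingdom"])

    def subset_samples(self, samples) -> "AbundanceTable":
        return replace(self, counts=self.counts.loc[:, list(samples)])

    def subset_taxa(self, taxa) -> "AbundanceTable":
        return replace(self, counts=self.counts.loc[list(taxa), :])

    def samples_in_group(self, group: str) -> list[str]:
        if self.group is None:
            raise ValueError("table carries no group labels")
        return [s for s in self.samples if self.group[s] == group]


def relative_abundance(table: AbundanceTable, level: str = "taxon") -> pd.DataFrame:
    """Per-sample proportions, at taxon or phylum level.

    Phylum aggregation sums member taxa before normalizing; each sample
    column sums to 1.  An all-zero sample is an error (its composition is
    undefined).
    """
    if level not in ("taxon", "phylum"):
        raise ValueError(f"level must be 'taxon' or 'phylum', got {level!r}")
    counts = table.counts
    if level == "phylum":
        phyla = table.taxonomy.loc[counts.index, "phylum"]
        counts = counts.groupby(phyla.values).sum()
        counts.index.name = "phylum"
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(f"sample(s) with zero total abundance: {zero.index.tolist()}")
    return counts / totals


def shannon(counts) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ in nats; zero counts contribute 0."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon diversity is undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(counts) -> int:
    """Number of taxa with strictly positive abundance."""
    x = np.asarray(counts, dtype=float)
    return int((x > 0).sum())


def diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Richness and Shannon index per sample."""
    rows = []
    for s in table.samples:
        col = table.counts[s].to_numpy()
        rows.append(
            {"sample_id": s, "richness": richness(col), "shannon": shannon(col)}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Defined on integer read counts only.  Samples whose total is below the
    depth are dropped with a logged warning — resampling with replacement
    would fabricate reads.  Reproducible for a fixed seed.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    arr = table.counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("rarefaction is defined on integer read counts")
    counts = table.counts.round().astype(np.int64)
    rng = np.random.default_rng(seed)
    kept_cols = {}
    dropped = []
    for s in counts.columns:
        col = counts[s].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append((s, total))
            continue
        if total == depth:
            kept_cols[s] = col
        else:
            kept_cols[s] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(f"{s} ({t})" for s, t in dropped),
        )
    if not kept_cols:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = pd.DataFrame(kept_cols, index=counts.index)
    meta = dict(table.meta)
    meta.update(rarefaction_depth=depth, rarefaction_seed=seed,
                dropped_samples=[s for s, _ in dropped])
    return replace(table, counts=out, meta=meta)


def bray_curtis(table_or_matrix, use_relative: bool = False) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities between samples.

    d(x, y) = 1 − 2 Σ min(xᵢ, yᵢ) / (Σ xᵢ + Σ yᵢ), in [0, 1], zero diagonal.
    ``use_relative=True`` normalizes columns to proportions first (used for
    phytoplankton cell densities, which are instrument-scaled); the choice
    is recorded in the result's attrs.
    """
    if isinstance(table_or_matrix, AbundanceTable):
        counts = table_or_matrix.counts
    else:
        counts = pd.DataFrame(table_or_matrix)
    if counts.shape[1] < 2:
        raise ValueError("Bray–Curtis needs at least 2 samples")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"sample(s) with zero total abundance: {bad}")
    if use_relative:
        counts = counts / totals
    d = squareform(pdist(counts.to_numpy().T, metric="braycurtis"))
    out = pd.DataFrame(d, index=counts.columns, columns=counts.columns)
    out.attrs["input"] = "relative" if use_relative else "raw"
    return out
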