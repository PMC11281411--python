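"""Abundance normalization and feature-retention filters.

RPKM converts per-contig mapped-read counts into a length- and
depth-normalized abundance; the retention filter keeps only the most
abundant fraction of features (top 15% of OTUs, top 5% of virome contigs
by default in the study design) so that sparse, zero-heavy features do
not create spurious correlations downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AbundanceTable, ConfigError, FormatError


@dataclass
class ContigStats:
    """Per-contig mapped read counts plus contig lengths and library sizes."""

    lengths: pd.Series  # contig -> length in bases
    mapped_reads: pd.DataFrame  # contigs x samples
    total_mapped: pd.Series  # sample -> library size (mapped reads)

    def __post_init__(self) -> None:
        if not self.lengths.index.equals(self.mapped_reads.index):
            self.lengths = self.lengths.reindex(self.mapped_reads.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()
            raise FormatError(f"missing contig lengths: {missing[:5]}")
        if (self.lengths < 1).any():
            raise FormatError("contig lengths must be >= 1")
        if (self.mapped_reads.to_numpy() < 0).any():
            raise FormatError("mapped read counts must be >= 0")
        totals = self.total_mapped.reindex(self.mapped_reads.columns)
        if totals.isna().any():
            raise FormatError("missing library sizes for some samples")
        if (self.mapped_reads.to_numpy() > totals.to_numpy()[None, :]).any():
            raise FormatError("mapped_reads exceed total_mapped")
        self.total_mapped = totals


def compute_rpkm(stats: ContigStats) -> AbundanceTable:
    """RPKM = reads / ((length/1e3) * (library/1e6)); zero reads give 0."""
    if (stats.total_mapped <= 0).any():
        bad = stats.total_mapped.index[stats.total_mapped <= 0].tolist()
        raise ConfigError(f"samples with zero mapped reads: {bad[:5]}")
    kb = stats.lengths.to_numpy(dtype=float)[:, None] / 1e3
    millions = stats.total_mapped.to_numpy(dtype=float)[None, :] / 1e6
    rpkm = stats.mapped_reads.to_numpy(dtype=float) / (kb * millions)
    values = pd.DataFrame(rpkm, index=stats.mapped_reads.index,
                          columns=stats.mapped_reads.columns)
    return AbundanceTable(layer="virome", values=values)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample column to sum to one."""
    sums = table.values.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ConfigError(f"all-zero samples: {zero[:5]}")
    return AbundanceTable(table.layer, table.values / sums, table.annotations)


def top_fraction(table: AbundanceTable, fraction: float) -> AbundanceTable:
    """Keep the ceil(fraction * n) features with highest mean relative
    abundance across all samples; ties broken by lexicographic feature id;
    original feature order otherwise preserved."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigError("fraction must be in (0, 1]")
    if table.n_features == 0:
        raise ConfigError("empty table")
    rel = to_relative(table)
    mean_rel = rel.values.mean(axis=1)
    k = math.ceil(fraction * table.n_features)
    order = sorted(mean_rel.index, key=lambda f: (-mean_rel[f], f))
    keep = set(order[:k])
    kept_ids = [f for f in table.feature_ids if f in keep]
    return table.subset_features(kept_ids)
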