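"""Prevalence-based core microbiome per weaning period.

A taxon (at genus rank by default) belongs to the period's core when it is
present in at least the prevalence threshold (default 90%) of the period's
samples — all pre-weaning (T0+T1) or post-weaning (T2+T3) columns pooled.
The pre/post cores are compared by full six-rank lineage.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .containers import RANKS, NormalizedTable, OtuTable
from .otu import aggregate_taxonomy


@dataclass
class CoreSet:
    """Core taxa for one period: lineages, prevalences, average counts."""

    period: str
    rank: str
    threshold: float
    entries: pd.DataFrame  # columns: RANKS..., prevalence, avg_count

    @property
    def lineages(self) -> set[str]:
        return set(self.entries.index)

    def __len__(self) -> int:
        return len(self.entries)


def core_taxa(table: OtuTable | NormalizedTable,
              samples=None,
              prevalence_threshold: float = 0.9,
              rank: str = "genus",
              period: str = "all") -> CoreSet:
    """Extract taxa present in >= threshold of the given samples.

    The threshold comparison is exact (rational arithmetic on the presence
    count), so a taxon seen in 9 of 10 samples passes a 0.9 threshold.
    ``avg_count`` is the mean value over the selected samples.
    """
    agg = aggregate_taxonomy(table, rank)
    values = agg.counts if isinstance(agg, OtuTable) else agg.values
    if samples is not None:
        samples = list(samples)
        if not samples:
            raise ValueError("empty sample subset")
        values = values[samples]
    n = values.shape[1]
    thr = Fraction(str(prevalence_threshold))
    present = (values > 0).sum(axis=1)
    keep = present.map(lambda c: Fraction(int(c), n) >= thr)
    entries = agg.lineages.loc[keep].copy()
    entries["prevalence"] = present[keep] / n
    entries["avg_count"] = values.loc[keep].mean(axis=1)
    return CoreSet(period=period, rank=rank,
                   threshold=prevalence_threshold, entries=entries)


def core_by_period(table, prevalence_threshold: float = 0.9,
                   rank: str = "genus") -> dict[str, CoreSet]:
    """Pre- and post-weaning cores from a table with period metadata."""
    out = {}
    for period in ("pre", "post"):
        samples = table.metadata.index[table.metadata["period"] == period]
        out[period] = core_taxa(table, samples=samples,
                                prevalence_threshold=prevalence_threshold,
                                rank=rank, period=period)
    return out


def coreset_from_lineages(entries: pd.DataFrame, period: str,
                          rank: str = "genus",
                          threshold: float = 0.9) -> CoreSet:
    """Build a CoreSet from an explicit list of lineages (e.g. a published
    core-taxon table) with optional ``avg_counts`` column."""
    depth = RANKS.index(rank) + 1
    used = list(RANKS[:depth])
    idx = entries[used].astype(str).agg(";".join, axis=1)
    df = entries.copy()
    df.index = idx
    if df.index.duplicated().any():
        raise ValueError("duplicate lineages in core list")
    return CoreSet(period=period, rank=rank, threshold=threshold, entries=df)


def compare_cores(pre: CoreSet, post: CoreSet) -> dict:
    """Overlap report between two cores at the same rank.

    Matching is on the full lineage string, so e.g. 'uncultured bacterium'
    under different families counts as different taxa.
    """
    if pre.rank != post.rank:
        raise ValueError(
            f"cores at different ranks: {pre.rank!r} vs {post.rank!r}")
    shared = pre.lineages & post.lineages
    return {
        "n_pre": len(pre),
        "n_post": len(post),
        "n_shared": len(shared),
        "shared": sorted(shared),
        "pre_only": sorted(pre.lineages - shared),
        "post_only": sorted(post.lineages - shared),
    }
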