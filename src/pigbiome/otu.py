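"""OTU-table processing: filtering, CSS normalization, aggregation,
relative abundances and rarefaction curves."""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import substream
from .containers import RANKS, NormalizedTable, OtuTable


def filter_otus(table: OtuTable, min_total: int = 10,
                min_samples: int = 2) -> OtuTable:
    """Drop rare OTUs: keep taxa with total count >= ``min_total`` that are
    present (nonzero) in at least ``min_samples`` samples.

    The sample set is unchanged; the operation is idempotent.
    """
    counts = table.counts
    keep = (counts.sum(axis=1) >= min_total) & \
           ((counts > 0).sum(axis=1) >= min_samples)
    if not keep.any():
        raise ValueError(
            "OTU filter removed every taxon; review min_total/min_samples "
            f"(min_total={min_total}, min_samples={min_samples})"
        )
    return table.with_counts(counts.loc[keep])


def _lower_quantile(values: np.ndarray, quantile: float) -> float:
    """Type-1 (inverse empirical CDF) lower quantile of a sorted sample."""
    n = values.size
    k = max(int(math.ceil(quantile * n)), 1)
    return float(values[k - 1])


def css_normalize(table: OtuTable, quantile: float = 0.5,
                  scale_constant: float = 1000.0) -> NormalizedTable:
    """Cumulative sum scaling: divide each sample by the cumulative count up
    to its ``quantile``-th positive-count quantile, times ``scale_constant``.

    The per-sample scaling factor is the sum of the counts not exceeding the
    lower empirical quantile of that sample's positive counts (ties at the
    quantile included). Samples with proportional counts normalize to
    identical columns, removing library-size differences.
    """
    counts = table.counts
    factors = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        positive = np.sort(col[col > 0])
        if positive.size == 0:
            raise ValueError(f"sample {sample!r} has no positive counts")
        q = _lower_quantile(positive, quantile)
        s = float(col[col <= q].sum())
        if s <= 0:
            raise ValueError(
                f"CSS scaling factor is zero for sample {sample!r}"
            )
        factors[sample] = s
    factors = pd.Series(factors)
    values = counts / factors * scale_constant
    return NormalizedTable(
        values=values,
        scaling_factors=factors,
        scale_constant=float(scale_constant),
        lineages=table.lineages,
        metadata=table.metadata,
        quantile=quantile,
    )


def aggregate_taxonomy(table: OtuTable | NormalizedTable, rank: str):
    """Sum values over taxa sharing the lineage prefix down to ``rank``.

    Returns a table of the same kind whose taxon ids are ';'-joined lineage
    prefixes; rank columns below the aggregation rank are left empty.
    Per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    depth = RANKS.index(rank) + 1
    used = list(RANKS[:depth])
    values = table.counts if isinstance(table, OtuTable) else table.values
    key = table.lineages[used].astype(str).agg(";".join, axis=1)
    grouped = values.groupby(key, sort=True).sum()
    lineages = pd.DataFrame(
        [k.split(";") for k in grouped.index], index=grouped.index,
        columns=used,
    )
    for r in RANKS[depth:]:
        lineages[r] = ""
    lineages = lineages[list(RANKS)]
    if isinstance(table, OtuTable):
        return OtuTable(counts=grouped, lineages=lineages,
                        metadata=table.metadata[
                            ["pig", "treatment", "timepoint"]])
    return NormalizedTable(
        values=grouped, scaling_factors=table.scaling_factors,
        scale_constant=table.scale_constant, lineages=lineages,
        metadata=table.metadata, quantile=table.quantile,
    )


def distinct_lineage_counts(table: OtuTable | NormalizedTable) -> pd.Series:
    """Number of distinct lineages at every rank from phylum to genus."""
    out = {}
    for rank in RANKS[1:]:
        depth = RANKS.index(rank) + 1
        key = table.lineages[list(RANKS[:depth])].astype(str).agg(
            ";".join, axis=1)
        out[rank] = int(key.nunique())
    return pd.Series(out)


def relative_abundance(table: OtuTable | NormalizedTable,
                       rank: str | None = None,
                       min_rel: float = 0.0,
                       by: Sequence[str] = ("treatment", "timepoint"),
                       ) -> pd.DataFrame:
    """Mean per-sample proportions per treatment x timepoint cell.

    Taxa whose mean proportion stays below ``min_rel`` in every cell are
    pooled into an ``other`` row, so every cell's proportions (including
    ``other``) sum to 1.
    """
    if rank is not None:
        table = aggregate_taxonomy(table, rank)
    values = table.counts if isinstance(table, OtuTable) else table.values
    props = values / values.sum(axis=0)
    meta = table.metadata
    cells = props.T.groupby(
        [meta[c] for c in by]).mean().T  # taxa x cells
    if min_rel > 0:
        major = (cells >= min_rel).any(axis=1)
        pooled = cells.loc[~major].sum(axis=0)
        cells = cells.loc[major]
        if pooled.any():
            cells.loc["other"] = pooled
    return cells


def rarefaction_curves(table: OtuTable, depths: Iterable[int],
                       reps: int = 10, mode: str = "sequence",
                       seed: int = 0) -> pd.DataFrame:
    """Rarefaction curves of observed taxon richness.

    ``sequence`` mode subsamples reads without replacement at each depth per
    sample (multivariate hypergeometric); ``sample`` mode accumulates
    distinct taxa over random sample orderings. Returns a long table with
    columns mode, unit, depth, mean, sd.
    """
    rng = substream(seed, f"rarefaction:{mode}")
    depths = sorted(int(d) for d in depths)
    rows = []
    if mode == "sequence":
        for sample in table.counts.columns:
            col = table.counts[sample].to_numpy()
            total = int(col.sum())
            for depth in depths:
                if depth > total:
                    continue
                obs = [
                    int((rng.multivariate_hypergeometric(col, depth) > 0)
                        .sum())
                    for _ in range(reps)
                ]
                rows.append(("sequence", sample, depth,
                             float(np.mean(obs)), float(np.std(obs, ddof=0))))
    elif mode == "sample":
        presence = (table.counts.to_numpy() > 0)
        n = presence.shape[1]
        for depth in depths:
            if depth > n:
                continue
            obs = []
            for _ in range(reps):
                order = rng.permutation(n)[:depth]
                obs.append(int(presence[:, order].any(axis=1).sum()))
            rows.append(("sample", "all", depth,
                         float(np.mean(obs)), float(np.std(obs, ddof=0))))
    else:
        raise ValueError(f"mode must be 'sequence' or 'sample', got {mode!r}")
    return pd.DataFrame(rows, columns=["mode", "unit", "depth", "mean", "sd"])
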