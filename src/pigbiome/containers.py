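"""Central in-memory containers for the piglet gut-microbiome pipeline.

The pipeline revolves around a taxa-by-samples count table annotated with
six-rank lineages and per-sample metadata (pig, diet treatment, timepoint).
Timepoints T0/T1 fall before weaning (days 1 and 12), T2/T3 at weaning and
after (days 26 and 58); the derived ``period`` column encodes that split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Taxonomic ranks carried by every lineage, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

TIMEPOINTS = ("T0", "T1", "T2", "T3")
TIMEPOINT_DAYS = {"T0": 1, "T1": 12, "T2": 26, "T3": 58}
TREATMENTS = ("white", "traditional", "oil")

#: Pre-weaning covers T0/T1, post-weaning T2/T3 (weaning at day 26).
PERIOD_OF_TIMEPOINT = {"T0": "pre", "T1": "pre", "T2": "post", "T3": "post"}

METADATA_COLUMNS = ("pig", "treatment", "timepoint")


def lineage_string(ranks: pd.Series | dict) -> str:
    """Join the six rank labels into a ';'-delimited lineage string."""
    return ";".join(str(ranks[r]) for r in RANKS)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame and attach the derived period column.

    Parameters
    ----------
    metadata
        Indexed by sample id with columns ``pig``, ``treatment``,
        ``timepoint``.

    Returns
    -------
    A copy with a ``period`` column (``pre``/``post``).
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    bad_tp = set(metadata["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints in metadata: {sorted(bad_tp)}")
    if metadata.index.duplicated().any():
        dups = metadata.index[metadata.index.duplicated()].tolist()
        raise ValueError(f"duplicated sample ids in metadata: {dups}")
    pairs = metadata[["pig", "timepoint"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise ValueError("metadata contains duplicate (pig, timepoint) pairs")
    # a pig must sit in exactly one treatment arm
    per_pig = metadata.groupby("pig")["treatment"].nunique()
    if (per_pig > 1).any():
        bad = per_pig[per_pig > 1].index.tolist()
        raise ValueError(f"pigs assigned to more than one treatment: {bad}")
    out = metadata.copy()
    out["period"] = out["timepoint"].map(PERIOD_OF_TIMEPOINT)
    return out


@dataclass
class OtuTable:
    """A non-negative OTU count matrix (taxa x samples) with annotations.

    Attributes
    ----------
    counts
        Integer counts, rows indexed by taxon id, columns by sample id.
    lineages
        One row per taxon, columns :data:`RANKS`.
    metadata
        One row per sample column; validated, with derived ``period``.
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError("counts must be numeric")
            bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    "counts must be non-negative integers; offending entry at "
                    f"taxon {counts.index[i]!r}, sample {counts.columns[j]!r} "
                    f"= {arr[i, j]}"
                )
        if counts.index.duplicated().any():
            raise ValueError("taxon ids must be unique")
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "taxon_id"
        self.counts.columns.name = None
        missing_lin = counts.index.difference(self.lineages.index)
        if len(missing_lin):
            raise ValueError(f"taxa without lineage: {missing_lin.tolist()}")
        self.lineages = self.lineages.loc[counts.index, list(RANKS)]
        self.lineages.index.name = "taxon_id"
        meta = validate_metadata(self.metadata)
        missing_meta = counts.columns.difference(meta.index)
        if len(missing_meta):
            raise ValueError(
                f"samples without metadata: {missing_meta.tolist()}"
            )
        self.metadata = meta.loc[counts.columns]
        self.metadata.index.name = "sample"

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Per-sample total counts (sequencing depth after filtering)."""
        return self.counts.sum(axis=0)

    def lineage_strings(self) -> pd.Series:
        return self.lineages.apply(lineage_string, axis=1)

    def select_samples(self, sample_ids) -> "OtuTable":
        """Restrict to a subset of sample columns (taxa unchanged)."""
        sample_ids = list(sample_ids)
        return OtuTable(
            counts=self.counts[sample_ids],
            lineages=self.lineages,
            metadata=self.metadata.loc[sample_ids, list(METADATA_COLUMNS)],
        )

    def with_counts(self, counts: pd.DataFrame) -> "OtuTable":
        """New table with replaced counts, keeping annotations aligned."""
        return OtuTable(
            counts=counts,
            lineages=self.lineages.loc[counts.index],
            metadata=self.metadata.loc[counts.columns, list(METADATA_COLUMNS)],
        )


@dataclass
class NormalizedTable:
    """CSS-normalized abundances: counts / per-sample scaling factor * scale.

    Keeps the raw table's annotations; ``values`` are non-negative reals on a
    common scale so that samples are comparable despite uneven depth.
    """

    values: pd.DataFrame
    scaling_factors: pd.Series
    scale_constant: float
    lineages: pd.DataFrame
    metadata: pd.DataFrame
    quantile: float = 0.5

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def lineage_strings(self) -> pd.Series:
        return self.lineages.apply(lineage_string, axis=1)
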