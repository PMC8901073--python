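"""Readers and writers for the plain-text formats the pipeline touches.

OTU tables travel as TSV with a taxon-id column, six lineage-rank columns
and one column per sample (taxa as rows — the orientation of published
core-microbiome tables). Metadata, growth tables and result tables are TSV;
FASTQ is standard 4-line Phred+33, parsed through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import METADATA_COLUMNS, RANKS, OtuTable
from .qc import ReadRecord

TAXON_COLUMN = "taxon_id"


# ---------------------------------------------------------------- FASTQ

def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream reads from a Phred+33 FASTQ file.

    Raises ``ValueError`` naming the record index on truncated records or
    sequence/quality length mismatches. An empty file yields nothing.
    """
    with open(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {index} in {path}: {exc}"
                ) from exc
            yield ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                quality=np.asarray(
                    rec.letter_annotations["phred_quality"], dtype=np.int64
                ),
            )
            index += 1


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quality]
        records.append(rec)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fastq")


# ------------------------------------------------------------ OTU table

def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise ValueError(f"metadata {path} lacks a 'sample' column")
    return meta.set_index("sample")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata[list(METADATA_COLUMNS)].copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_otu_table(path, metadata_path) -> OtuTable:
    """Read a taxa-by-samples TSV count table plus its sample metadata.

    The table must carry ``taxon_id``, the six rank columns and one numeric
    column per sample. A table whose header lacks the rank columns but looks
    like a sample-per-row layout is rejected as transposed rather than
    silently flipped.
    """
    df = pd.read_csv(path, sep="\t")
    missing_ranks = [r for r in RANKS if r not in df.columns]
    if missing_ranks:
        hint = ""
        lowered = [c.lower() for c in df.columns]
        if TAXON_COLUMN not in df.columns or "sample" in lowered:
            hint = " (the table appears to be transposed: expected taxa as rows)"
        raise ValueError(
            f"OTU table {path} lacks lineage rank columns {missing_ranks}{hint}"
        )
    if TAXON_COLUMN not in df.columns:
        raise ValueError(f"OTU table {path} lacks a '{TAXON_COLUMN}' column")
    df = df.set_index(TAXON_COLUMN)
    lineages = df[list(RANKS)].astype(str)
    counts = df.drop(columns=list(RANKS))
    for col in counts.columns:
        values = pd.to_numeric(counts[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values != np.floor(values))
        if bad.any():
            taxon = counts.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-integer or negative count at taxon {taxon!r}, "
                f"sample {col!r} in {path}"
            )
        counts[col] = values.astype(np.int64)
    metadata = read_metadata(metadata_path)
    missing = counts.columns.difference(metadata.index)
    if len(missing):
        raise ValueError(
            f"no metadata for sample(s) {missing.tolist()} in {metadata_path}"
        )
    return OtuTable(counts=counts, lineages=lineages,
                    metadata=metadata.loc[counts.columns])


def write_otu_table(table: OtuTable, path, metadata_path=None) -> None:
    out = pd.concat([table.lineages, table.counts], axis=1)
    out.index.name = TAXON_COLUMN
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        write_metadata(table.metadata, metadata_path)


# --------------------------------------------------------- growth table

GROWTH_COLUMNS = ("pig", "group", "bw_d1", "bw_d26", "bw_d58",
                  "alive_pre", "alive_post")


def read_growth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"growth table {path} lacks columns {missing}")
    df["alive_pre"] = df["alive_pre"].astype(bool)
    df["alive_post"] = df["alive_post"].astype(bool)
    return df


def write_growth_table(records: pd.DataFrame, path) -> None:
    out = records[list(GROWTH_COLUMNS)].copy()
    out["alive_pre"] = out["alive_pre"].astype(int)
    out["alive_post"] = out["alive_post"].astype(int)
    out.to_csv(path, sep="\t", index=False)
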