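"""Readers and writers for the pipeline's plain-text table formats.

Everything is TSV or JSON: gene counts (genes x samples), gene lengths
(two columns), sample metadata, MSP profiles, response/effect/
differential tables, and the MSP catalogue as JSON.  Writers emit a
deterministic column order and 15 significant digits, so identical runs
produce byte-identical files.  Round-trips are identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engraftment import SampleMetadata
from .gene_profiles import GeneCountTable
from .msp_quant import GeneHit, MSPCatalogue, MSPEntry, MSPProfileTable

__all__ = [
    "read_gene_counts",
    "write_gene_counts",
    "read_metadata",
    "write_metadata",
    "read_catalogue",
    "write_catalogue",
    "read_msp_profiles",
    "write_msp_profiles",
    "write_table",
    "read_table",
]

FLOAT_FORMAT = "%.15g"


def read_gene_counts(counts_path: str | Path, lengths_path: str | Path) -> GeneCountTable:
    """Load a gene-count TSV plus a (gene_id, length) TSV.

    Raises distinct errors for duplicate ids, non-integral counts and
    genes missing a length, naming the offending gene and sample.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()][:5]
        raise ValueError(f"duplicate gene ids: {', '.join(map(str, dups))}")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in header")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac = arr != np.floor(arr)
        if frac.any():
            g, s = np.argwhere(frac)[0]
            raise ValueError(
                f"non-integer count {arr[g, s]} for gene {counts.index[g]} "
                f"in sample {counts.columns[s]}"
            )
        counts = counts.astype(np.int64)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise ValueError(
            f"genes missing a length: {', '.join(map(str, missing[:5]))}"
        )
    return GeneCountTable(counts=counts, lengths=lengths.astype(np.int64))


def write_gene_counts(
    table: GeneCountTable, counts_path: str | Path, lengths_path: str | Path
) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    table.lengths.rename("length").to_csv(
        lengths_path, sep="\t", index_label="gene_id"
    )


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(table=pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def write_catalogue(cat: MSPCatalogue, path: str | Path) -> None:
    payload = {}
    for entry in cat.entries.values():
        payload[entry.msp_id] = {
            "genes": entry.genes,
            "signature": entry.signature,
            "lineage": entry.lineage,
            "assignment_rank": entry.assignment_rank,
            "hits": {
                g: (
                    None
                    if h is None
                    else {
                        "lineage": h.lineage,
                        "identity": h.identity,
                        "coverage": h.coverage,
                    }
                )
                for g, h in entry.hits.items()
            },
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_catalogue(path: str | Path) -> MSPCatalogue:
    payload = json.loads(Path(path).read_text())
    entries = {}
    for mid, rec in payload.items():
        hits = {
            g: (None if h is None else GeneHit(**h))
            for g, h in rec.get("hits", {}).items()
        }
        entries[mid] = MSPEntry(
            msp_id=mid,
            genes=rec["genes"],
            signature=rec["signature"],
            hits=hits,
            lineage=rec.get("lineage", {}),
            assignment_rank=rec.get("assignment_rank"),
        )
    return MSPCatalogue(entries=entries)


def write_msp_profiles(profiles: MSPProfileTable, path: str | Path) -> None:
    profiles.abundances.to_csv(
        path, sep="\t", index_label="msp_id", float_format=FLOAT_FORMAT
    )


def read_msp_profiles(path: str | Path) -> MSPProfileTable:
    return MSPProfileTable(abundances=pd.read_csv(path, sep="\t", index_col=0))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Generic deterministic TSV writer for result tables."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
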