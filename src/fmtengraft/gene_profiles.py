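"""Depth standardization and normalization of gene-count tables.

Shotgun metagenomic samples are sequenced to unequal depth.  Before any
community-level comparison the gene abundance table is (1) rarefied —
randomly subsampled without replacement to a common number of mapped
reads — and (2) normalized FPKM-style: each count is divided by its gene
length and the column is rescaled to sum to one, yielding per-sample
gene frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneCountTable",
    "GeneFrequencyTable",
    "rarefy",
    "fpkm_normalize",
]


@dataclass
class GeneCountTable:
    """Genes x samples integer read counts plus per-gene lengths (bp).

    ``counts`` is a DataFrame indexed by gene id with sample ids as
    columns; ``lengths`` is a Series indexed by the same gene ids.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing) > 0:
            raise ValueError(
                f"genes missing a length: {', '.join(map(str, missing[:5]))}"
            )
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths < 1).any():
            raise ValueError("gene lengths must be >= 1 bp")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class GeneFrequencyTable:
    """Genes x samples real-valued frequencies (columns sum to 1 or 0)."""

    frequencies: pd.DataFrame
    all_zero_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        freq = self.frequencies.to_numpy()
        if (freq < 0).any():
            raise ValueError("frequencies must be non-negative")
        sums = freq.sum(axis=0)
        bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0))
        if bad.any():
            names = self.frequencies.columns[bad]
            raise ValueError(
                f"sample columns do not sum to 1: {', '.join(map(str, names[:5]))}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.frequencies.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.frequencies.columns


def _rarefy_column(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``depth`` reads without replacement from one sample.

    The sampling law is multivariate hypergeometric over genes, which is
    exactly a uniform subsample of the mapped reads.
    """
    total = int(counts.sum())
    if total == depth:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth, method="marginals")


def rarefy(
    table: GeneCountTable,
    depth: int | str = 12_000_000,
    seed: int | np.random.SeedSequence | None = None,
) -> GeneCountTable:
    """Rarefy every sample to a fixed number of mapped reads.

    Parameters
    ----------
    table
        Input gene counts.
    depth
        Target reads per sample (default 12 million).  ``"auto"`` uses
        the minimum sample total, i.e. the largest threshold that keeps
        every sample.
    seed
        Seed for the subsampling; one independent stream is derived per
        sample so per-sample results do not depend on column order.

    Raises
    ------
    ValueError
        If any sample has fewer reads than ``depth``.
    """
    totals = table.sample_totals()
    if depth == "auto":
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    shallow = totals[totals < depth]
    if len(shallow) > 0:
        raise ValueError(
            f"samples below rarefaction depth {depth}: "
            + ", ".join(f"{s} ({int(t)} reads)" for s, t in shallow.items())
        )

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(table.counts.shape[1])
    out = np.empty_like(table.counts.to_numpy())
    for j, child in enumerate(children):
        rng = np.random.default_rng(child)
        out[:, j] = _rarefy_column(table.counts.iloc[:, j].to_numpy(), depth, rng)
    rarefied = pd.DataFrame(out, index=table.gene_ids, columns=table.sample_ids)
    return GeneCountTable(counts=rarefied, lengths=table.lengths)


def fpkm_normalize(table: GeneCountTable) -> GeneFrequencyTable:
    """Length-normalize counts and report each sample as frequencies.

    frequency(g, s) = (count(g, s) / length(g)) / sum_g' (count(g', s) / length(g'))

    All-zero samples stay all-zero and are listed on the result for the
    run report.  The formula is invariant to per-sample count rescaling,
    so total-read normalization order is immaterial.
    """
    per_length = table.counts.to_numpy(dtype=float) / table.lengths.to_numpy()[:, None]
    col_sums = per_length.sum(axis=0)
    zero_cols = col_sums == 0.0
    safe = np.where(zero_cols, 1.0, col_sums)
    freq = per_length / safe
    freq[:, zero_cols] = 0.0
    return GeneFrequencyTable(
        frequencies=pd.DataFrame(freq, index=table.gene_ids, columns=table.sample_ids),
        all_zero_samples=[str(s) for s in table.sample_ids[zero_cols]],
    )
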