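"""Metagenomic species (MSP) quantification, richness, and taxonomy.

An MSP — a metagenomic species pangenome — is a cluster of co-abundant
genes belonging to one microbial species.  Its abundance in a sample is
the arithmetic mean frequency of its best-ranked core ("signature")
genes, 50 by default.  Taxonomy is assigned per MSP by majority vote
over the member genes' best reference hits: species level requires a
strict majority of all member genes hitting one reference species at
high identity and coverage; otherwise the deepest rank from genus up to
superkingdom with a strict gene majority wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_profiles import GeneFrequencyTable

__all__ = [
    "RANKS",
    "GeneHit",
    "MSPEntry",
    "MSPCatalogue",
    "AnnotationThresholds",
    "MSPProfileTable",
    "quantify_msp",
    "richness",
    "annotate_taxonomy",
    "aggregate_taxa",
]

# ordered shallow -> deep
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class GeneHit:
    """Best reference hit of one gene: a lineage plus alignment quality."""

    lineage: dict[str, str]  # rank -> taxon name (possibly partial)
    identity: float  # percent
    coverage: float  # percent of gene length

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0 and 0.0 <= self.coverage <= 100.0):
            raise ValueError("identity and coverage must lie in [0, 100]")


@dataclass
class MSPEntry:
    msp_id: str
    genes: list[str]
    signature: list[str]  # ranked, best first
    hits: dict[str, GeneHit | None] = field(default_factory=dict)  # gene -> hit or None
    lineage: dict[str, str] = field(default_factory=dict)
    assignment_rank: str | None = None

    def __post_init__(self) -> None:
        if not set(self.signature) <= set(self.genes):
            raise ValueError(f"{self.msp_id}: signature genes not all members")


@dataclass
class MSPCatalogue:
    """Collection of MSP entries; every gene belongs to exactly one MSP."""

    entries: dict[str, MSPEntry]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for entry in self.entries.values():
            for g in entry.genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g} in both {seen[g]} and {entry.msp_id}"
                    )
                seen[g] = entry.msp_id

    @property
    def msp_ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def gene_to_msp(self) -> dict[str, str]:
        return {g: e.msp_id for e in self.entries.values() for g in e.genes}

    def lineage_at(self, msp_id: str, rank: str) -> str | None:
        return self.entries[msp_id].lineage.get(rank)


@dataclass(frozen=True)
class AnnotationThresholds:
    """Majority-vote and species-hit quality thresholds (percent scale)."""

    majority_fraction: float = 0.50  # strict >
    species_identity: float = 95.0
    species_coverage: float = 90.0

    def __post_init__(self) -> None:
        for v in (self.species_identity, self.species_coverage):
            if not 0.0 < v <= 100.0:
                raise ValueError("thresholds must lie in (0, 100]")
        if not 0.0 < self.majority_fraction < 1.0:
            raise ValueError("majority fraction must lie in (0, 1)")


@dataclass
class MSPProfileTable:
    """MSP x samples relative abundances."""

    abundances: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def msp_ids(self) -> pd.Index:
        return self.abundances.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundances.columns


def quantify_msp(
    freq: GeneFrequencyTable, cat: MSPCatalogue, n_signature: int = 50
) -> MSPProfileTable:
    """Abundance of each MSP = mean frequency of its best core genes.

    Only the first ``min(n_signature, |signature|)`` ranked signature
    genes contribute.  Every signature gene must be a row of ``freq``.
    """
    used_genes: list[str] = []
    offsets: list[int] = []
    msp_ids: list[str] = []
    for entry in cat.entries.values():
        if not entry.signature:
            raise ValueError(f"{entry.msp_id} has an empty signature list")
        offsets.append(len(used_genes))
        used_genes.extend(entry.signature[: min(n_signature, len(entry.signature))])
        msp_ids.append(entry.msp_id)
    pos = freq.gene_ids.get_indexer(used_genes)
    if (pos < 0).any():
        missing = [g for g, p in zip(used_genes, pos) if p < 0]
        raise ValueError(
            "signature genes absent from frequency table: "
            + ", ".join(missing[:10])
        )
    sig_rows = freq.frequencies.to_numpy()[pos]
    sums = np.add.reduceat(sig_rows, offsets, axis=0)
    sizes = np.diff(offsets + [len(used_genes)])
    table = pd.DataFrame(
        sums / sizes[:, None],
        index=pd.Index(msp_ids, name="msp_id"),
        columns=freq.sample_ids,
    )
    return MSPProfileTable(abundances=table)


def richness(profile: MSPProfileTable, threshold: float = 0.0) -> pd.Series:
    """Per-sample count of MSP with abundance strictly above ``threshold``.

    Rarefaction upstream already standardizes depth, so the default
    detection cutoff is strict positivity.
    """
    return (profile.abundances > threshold).sum(axis=0)


def _majority(names: list[str | None], n_total: int, fraction: float) -> str | None:
    """Taxon held by a strict majority of n_total genes, else None."""
    counts: dict[str, int] = {}
    for n in names:
        if n is not None:
            counts[n] = counts.get(n, 0) + 1
    if not counts:
        return None
    best = max(sorted(counts), key=counts.get)
    if counts[best] > fraction * n_total:
        return best
    return None


def annotate_taxonomy(
    cat: MSPCatalogue, th: AnnotationThresholds = AnnotationThresholds()
) -> MSPCatalogue:
    """Assign each MSP a lineage by majority vote over gene hits.

    Species level: one reference species must account for a strict
    majority of ALL member genes (no-hit genes count in the denominator)
    with identity and coverage at or above the species thresholds.
    Failing that, ranks are walked genus -> superkingdom and the deepest
    rank at which one taxon holds a strict majority is assigned; with no
    majority anywhere the MSP is left unclassified.  The vote is
    independent of gene listing order (ties broken alphabetically, but a
    tie can never reach a strict majority anyway).
    """
    for entry in cat.entries.values():
        n_total = len(entry.genes)
        hits = [entry.hits.get(g) for g in entry.genes]

        species_names = [
            h.lineage.get("species")
            if (
                h is not None
                and h.identity >= th.species_identity
                and h.coverage >= th.species_coverage
            )
            else None
            for h in hits
        ]
        species = _majority(species_names, n_total, th.majority_fraction)

        assigned_rank: str | None = None
        lineage: dict[str, str] = {}
        if species is not None:
            assigned_rank = "species"
            # lineage of the winning species, from any supporting hit
            for h in hits:
                if h is not None and h.lineage.get("species") == species:
                    lineage = dict(h.lineage)
                    break
        else:
            for rank in reversed(RANKS[:-1]):  # genus ... superkingdom
                names = [h.lineage.get(rank) if h is not None else None for h in hits]
                taxon = _majority(names, n_total, th.majority_fraction)
                if taxon is not None:
                    assigned_rank = rank
                    for h in hits:
                        if h is not None and h.lineage.get(rank) == taxon:
                            upto = RANKS[: RANKS.index(rank) + 1]
                            lineage = {r: h.lineage[r] for r in upto if r in h.lineage}
                            break
                    break
        entry.lineage = lineage
        entry.assignment_rank = assigned_rank
    return cat


def aggregate_taxa(
    profile: MSPProfileTable, cat: MSPCatalogue, rank: str
) -> pd.DataFrame:
    """Sum member-MSP abundances per taxon at ``rank`` (taxon x sample).

    MSP without an annotation at that rank are pooled under
    ``"unclassified"``, so per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = [
        cat.lineage_at(str(mid), rank) or "unclassified" for mid in profile.msp_ids
    ]
    return profile.abundances.groupby(pd.Index(labels, name=rank)).sum()
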