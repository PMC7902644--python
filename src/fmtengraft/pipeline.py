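"""End-to-end orchestration: counts -> profiles -> engraftment -> stats.

A run either loads a gene-count table, catalogue and metadata from
disk, or simulates them first, then executes the fixed stage order:
rarefaction, FPKM normalization, MSP quantification, richness and
taxon aggregation, engraftment response, mixed ANOVA with assumption
checks and post-hocs, and per-group differential screens.  One master
seed governs all randomness; every output records it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as fio
from .differential import (
    DifferentialThresholds,
    differential_msp,
    summarize_differential,
)
from .engraftment import SampleMetadata, build_response_table
from .gene_profiles import GeneCountTable, fpkm_normalize, rarefy
from .inference import (
    check_assumptions,
    mixed_anova,
    pairwise_comparisons,
    simple_main_effects,
)
from .msp_quant import MSPCatalogue, aggregate_taxa, quantify_msp, richness

logger = logging.getLogger("fmtengraft")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds and the master seed of one pipeline run."""

    counts: str | Path
    lengths: str | Path
    catalogue: str | Path
    metadata: str | Path
    out_dir: str | Path
    depth: int | str = 12_000_000
    seed: int = 0
    q_cutoff: float = 0.05
    lfc_cutoff: float = 2.0
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON).

    Inputs are validated before any output is written: every metadata
    sample must be a column of the count table and every signature gene
    a row.  Any stage failure aborts with the stage name in the error.
    """
    report: dict = {
        "seed": config.seed,
        "inputs": {
            k: {"path": str(getattr(config, k)), "sha256": _checksum(getattr(config, k))}
            for k in ("counts", "lengths", "catalogue", "metadata")
        },
        "stages": {},
        "warnings": [],
    }

    counts = fio.read_gene_counts(config.counts, config.lengths)
    cat = fio.read_catalogue(config.catalogue)
    meta = fio.read_metadata(config.metadata)

    missing = set(meta.table["sample_id"]) - set(map(str, counts.sample_ids))
    if missing:
        raise ValueError(
            f"validation: metadata samples absent from counts: {sorted(missing)[:5]}"
        )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage rarefy: depth=%s", config.depth)
    rarefied = rarefy(counts, config.depth, seed=config.seed)
    depth_used = int(rarefied.sample_totals().iloc[0])
    report["depth"] = depth_used
    report["stages"]["rarefy"] = {"samples": int(rarefied.counts.shape[1])}

    logger.info("stage normalize")
    freq = fpkm_normalize(rarefied)
    if freq.all_zero_samples:
        report["warnings"].append(f"all-zero samples: {freq.all_zero_samples}")
    report["stages"]["normalize"] = {"genes": int(freq.frequencies.shape[0])}

    logger.info("stage quantify: %d MSP", len(cat))
    profiles = quantify_msp(freq, cat)
    fio.write_msp_profiles(profiles, out / "msp_profiles.tsv")
    report["stages"]["quantify"] = {"msp": int(len(profiles.msp_ids))}

    rich = richness(profiles)
    fio.write_table(
        rich.rename("richness").rename_axis("sample_id").reset_index(),
        out / "richness.tsv",
    )
    report["stages"]["richness"] = {"median": float(rich.median())}

    for rank in ("phylum", "family"):
        agg = aggregate_taxa(profiles, cat, rank)
        fio.write_table(agg.reset_index(), out / f"abundance_by_{rank}.tsv")
    report["stages"]["aggregate"] = {"ranks": ["phylum", "family"]}

    logger.info("stage engraftment")
    resp = build_response_table(profiles, meta)
    fio.write_table(resp, out / "engraftment_response.tsv")
    report["stages"]["engraftment"] = {"rows": int(len(resp))}

    logger.info("stage anova")
    effects = mixed_anova(resp, sphericity_alpha=config.alpha)
    fio.write_table(effects, out / "anova_effects.tsv")
    assumptions = check_assumptions(resp)
    (out / "assumptions.json").write_text(
        json.dumps(
            {
                "levene": assumptions.levene.to_dict(orient="records"),
                "box_m": {
                    "statistic": assumptions.box_m[0],
                    "p": assumptions.box_m[1],
                },
                "mauchly": {
                    "W": assumptions.mauchly[0],
                    "p": assumptions.mauchly[1],
                },
                "n_outliers": int(len(assumptions.outliers)),
            },
            indent=1,
            default=float,
        )
    )
    fio.write_table(simple_main_effects(resp), out / "simple_main_effects.tsv")
    fio.write_table(pairwise_comparisons(resp), out / "pairwise_comparisons.tsv")
    report["stages"]["anova"] = {"effects": int(len(effects))}

    logger.info("stage differential")
    th = DifferentialThresholds(q_cutoff=config.q_cutoff, lfc_cutoff=config.lfc_cutoff)
    diff_summary = {}
    for group in meta.experimental_groups():
        table = differential_msp(profiles, meta, group, th)
        label = f"{group[0]}_{group[1]}"
        fio.write_table(table, out / f"differential_{label}.tsv")
        diff_summary[label] = summarize_differential(table, cat)
    (out / "differential_summary.json").write_text(
        json.dumps(diff_summary, indent=1, default=float)
    )
    report["stages"]["differential"] = {
        g: s["impacted_fraction_pct"] for g, s in diff_summary.items()
    }

    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
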