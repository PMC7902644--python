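"""Synthetic gnotobiotic-colonization studies with known ground truth.

Generates gene-count tables, MSP catalogues and sample metadata with
the statistical structure the engraftment analysis assumes: a donor
inoculum with log-normally distributed MSP abundances, germ-free mice
colonized at a diluent- and storage-dependent fidelity, family-biased
extinction of *Lachnospiraceae*/*Ruminococcaceae*, humanization shifts
at the phylum level (Firmicutes down, Bacteroidetes and Proteobacteria
up), per-mouse random effects persisting across observation days, and
multinomial read sampling over genes.

Engraftment degradation is governed by a single scenario parameter
theta in [0, 1]: theta scales the per-MSP extinction probability, the
log-scale abundance noise and the bloom magnitudes, so the expected
similarity of a mouse to the fresh-transplant controls decreases
monotonically in theta.  ``calibrate_engraftment`` inverts that
relationship by bisection, finding the theta that reproduces a target
mean Spearman correlation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engraftment import SampleMetadata, pairwise_to_control
from .gene_profiles import GeneCountTable, fpkm_normalize, rarefy
from .msp_quant import GeneHit, MSPCatalogue, MSPEntry, quantify_msp

__all__ = [
    "StudyDesign",
    "GeneratorParams",
    "Scenario",
    "GroundTruth",
    "Inoculum",
    "CalibrationError",
    "DEFAULT_FAMILY_TABLE",
    "generate_catalogue",
    "generate_inoculum",
    "simulate_study",
    "default_scenarios",
    "mean_correlation_to_control",
    "calibrate_engraftment",
]

# (family, phylum, number of MSP); counts sum to 400.  Lachnospiraceae
# and Ruminococcaceae dominate, as in human gut catalogues, with 91
# Lachnospiraceae MSP.
DEFAULT_FAMILY_TABLE: tuple[tuple[str, str, int], ...] = (
    ("Lachnospiraceae", "Firmicutes", 91),
    ("Ruminococcaceae", "Firmicutes", 60),
    ("Clostridiaceae", "Firmicutes", 20),
    ("Erysipelotrichaceae", "Firmicutes", 20),
    ("Veillonellaceae", "Firmicutes", 15),
    ("Streptococcaceae", "Firmicutes", 9),
    ("Bacteroidaceae", "Bacteroidetes", 45),
    ("Prevotellaceae", "Bacteroidetes", 25),
    ("Rikenellaceae", "Bacteroidetes", 20),
    ("Porphyromonadaceae", "Bacteroidetes", 20),
    ("Enterobacteriaceae", "Proteobacteria", 25),
    ("Desulfovibrionaceae", "Proteobacteria", 10),
    ("Bifidobacteriaceae", "Actinobacteria", 20),
    ("Coriobacteriaceae", "Actinobacteria", 15),
    ("Akkermansiaceae", "Verrucomicrobia", 5),
)

BIASED_FAMILIES = ("Lachnospiraceae", "Ruminococcaceae")

# phylum-level multiplicative humanization shift applied to every mouse
# (including controls); the inoculum itself is untouched
DEFAULT_HUMANIZATION: dict[str, float] = {
    "Firmicutes": 0.4,
    "Actinobacteria": 0.3,
    "Bacteroidetes": 2.5,
    "Proteobacteria": 2.0,
    "Verrucomicrobia": 1.0,
}


class CalibrationError(RuntimeError):
    """Raised when no theta in [0, 1] reaches the target correlation."""


@dataclass(frozen=True)
class StudyDesign:
    """Group layout: one fresh control plus frozen diluent x week groups."""

    groups: tuple[tuple[str, str], ...] = (
        ("CTRL", "none"),
        ("NaCl", "W1"),
        ("NaCl", "W7"),
        ("MD", "W1"),
        ("MD", "W7"),
        ("TR", "W1"),
        ("TR", "W7"),
    )
    mice_per_group: int = 4
    days: tuple[str, ...] = ("D2", "D4", "D15")

    def __post_init__(self) -> None:
        ctrl = [g for g in self.groups if g[0] == "CTRL"]
        if len(ctrl) != 1 or ctrl[0][1] != "none":
            raise ValueError("design needs exactly one CTRL group with week 'none'")
        for dil, week in self.groups:
            if dil != "CTRL" and week == "none":
                raise ValueError(f"non-CTRL group {dil} needs a storage week")
        if self.mice_per_group < 1 or len(self.days) < 1:
            raise ValueError("need at least 1 mouse and 1 day")


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic community and sequencing model.

    Log-normal parameters are (mu, sigma) on the natural-log scale;
    sigmas must be non-negative.  ``read_depth`` is the multinomial
    total per sample and must cover any downstream rarefaction depth.
    """

    n_msp: int = 400
    family_table: tuple[tuple[str, str, int], ...] = DEFAULT_FAMILY_TABLE
    genes_per_msp: tuple[int, int] = (60, 200)
    signature_size: int = 50
    gene_length_lognormal: tuple[float, float] = (6.8, 0.4)  # median ~900 bp
    donor_abundance_lognormal: tuple[float, float] = (0.0, 1.5)
    gene_jitter_sigma: float = 0.1
    read_depth: int = 15_000_000
    humanization_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HUMANIZATION)
    )
    day_drift_sigma: float = 0.15
    mouse_effect_sigma: float = 0.30
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_msp != sum(c for _, _, c in self.family_table):
            raise ValueError("family_table counts must sum to n_msp")
        if self.genes_per_msp[0] > self.genes_per_msp[1] or self.genes_per_msp[0] < 1:
            raise ValueError("invalid genes_per_msp range")
        for s in (
            self.gene_length_lognormal[1],
            self.donor_abundance_lognormal[1],
            self.gene_jitter_sigma,
            self.day_drift_sigma,
            self.mouse_effect_sigma,
        ):
            if s < 0:
                raise ValueError("sigmas must be >= 0")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """Engraftment-degradation scenario for one mouse group.

    ``theta`` in [0, 1] scales all degradation channels: extinction
    probabilities (``theta * extinction_base``, multiplied by
    ``family_bias`` for the vulnerable families, clipped to [0, 1]),
    log-scale abundance noise (``theta * abundance_noise_sigma``) and
    bloom folds (``fold ** theta``).  ``bloomers`` entries are
    (selector, fold) with selector an MSP id, ``"family:<name>"`` or
    ``"random:<count>"``.  With ``consistent_extinctions`` the extinct
    set is drawn once per group (identical in every mouse) with its
    size fixed to the expected count — planted, recoverable truth.
    """

    name: str
    theta: float
    extinction_base: float = 0.35
    family_bias: float = 3.0
    abundance_noise_sigma: float = 1.2
    bloomers: tuple[tuple[str, float], ...] = ()
    consistent_extinctions: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.extinction_base < 0 or self.abundance_noise_sigma < 0:
            raise ValueError("rates and sigmas must be >= 0")
        if self.family_bias < 1:
            raise ValueError("family_bias must be >= 1")


@dataclass
class Inoculum:
    """Donor community: MSP relative abundances and gene-level weights."""

    msp_abundance: pd.Series  # sums to 1
    gene_weight: pd.Series  # unnormalized per-gene expected frequency

    @property
    def gene_frequency(self) -> pd.Series:
        return self.gene_weight / self.gene_weight.sum()


@dataclass
class GroundTruth:
    """Recovery-test oracle: what the generator actually planted."""

    donor_abundance: pd.Series
    theta: dict[str, float]  # "diluent:week" -> theta
    status: dict[str, dict[str, str]]  # group -> msp -> extinct/bloomed/unchanged
    per_mouse_extinct: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.donor_abundance.sum(), 1.0):
            raise ValueError("donor abundances must sum to 1")


def _stream(master_seed: int, *labels) -> np.random.Generator:
    """Independent, order-insensitive random stream keyed by labels."""
    key = [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *key]))


def generate_catalogue(params: GeneratorParams) -> MSPCatalogue:
    """Build an MSP catalogue with genes, ranked signatures and taxonomy.

    Each MSP carries its true lineage and per-gene best-hit evidence
    consistent with it: most MSP have species-grade evidence (>50% of
    genes hitting one reference species at >=95% identity, >=90%
    coverage), some only genus- or family-grade, a few no hits at all,
    so majority-vote annotation is exercised across its branches.
    """
    rng = _stream(params.master_seed, "catalogue")
    entries: dict[str, MSPEntry] = {}
    gene_counter = 0
    msp_idx = 0
    for family, phylum, count in params.family_table:
        for i in range(count):
            msp_idx += 1
            mid = f"msp_{msp_idx:04d}"
            n_genes = int(
                rng.integers(params.genes_per_msp[0], params.genes_per_msp[1] + 1)
            )
            genes = [f"gene_{gene_counter + j:06d}" for j in range(n_genes)]
            gene_counter += n_genes
            lineage = {
                "superkingdom": "Bacteria",
                "phylum": phylum,
                "class": f"{phylum}_class",
                "order": f"{family}_order",
                "family": family,
                "genus": f"{family[:-4]}us_{i % 5 + 1}",
                "species": f"{family[:-4]}us_sp{i + 1}",
            }
            grade = rng.choice(
                ["species", "genus", "family", "none"], p=[0.75, 0.15, 0.07, 0.03]
            )
            hits: dict[str, GeneHit | None] = {}
            for g in genes:
                u = rng.random()
                if grade == "species" and u < 0.7:
                    hits[g] = GeneHit(
                        lineage=dict(lineage),
                        identity=float(np.clip(rng.normal(97, 1), 95, 100)),
                        coverage=float(np.clip(rng.normal(95, 2), 90, 100)),
                    )
                elif grade in ("species", "genus") and u < 0.8:
                    # genus-grade: right genus, scattered species, weak alignment
                    lin = dict(lineage)
                    lin["species"] = f"{lineage['genus']}_other{int(u * 100) % 7}"
                    hits[g] = GeneHit(
                        lineage=lin,
                        identity=float(rng.uniform(80, 94)),
                        coverage=float(rng.uniform(60, 89)),
                    )
                elif grade == "family" and u < 0.8:
                    lin = {
                        r: lineage[r]
                        for r in ("superkingdom", "phylum", "class", "order", "family")
                    }
                    lin["genus"] = f"{family[:-4]}us_{int(u * 1000) % 9 + 1}"
                    hits[g] = GeneHit(
                        lineage=lin,
                        identity=float(rng.uniform(75, 90)),
                        coverage=float(rng.uniform(50, 85)),
                    )
                else:
                    hits[g] = None
            entries[mid] = MSPEntry(
                msp_id=mid,
                genes=genes,
                signature=genes[: min(params.signature_size, n_genes)],
                hits=hits,
                lineage=dict(lineage),
                assignment_rank={"species": "species", "genus": "genus",
                                 "family": "family", "none": None}[str(grade)],
            )
    return MSPCatalogue(entries=entries)


def _gene_arrays(cat: MSPCatalogue) -> tuple[pd.Index, np.ndarray]:
    """All gene ids (catalogue order) and their MSP index positions."""
    gene_ids: list[str] = []
    msp_pos: list[int] = []
    for k, entry in enumerate(cat.entries.values()):
        gene_ids.extend(entry.genes)
        msp_pos.extend([k] * len(entry.genes))
    return pd.Index(gene_ids), np.asarray(msp_pos)


def generate_inoculum(cat: MSPCatalogue, params: GeneratorParams) -> Inoculum:
    """Draw the donor community: log-normal MSP abundances, sum 1.

    Every member gene of an MSP receives a base weight equal to the
    MSP's abundance (all genes of a species share its coverage), times
    a small per-gene log-normal jitter; with ``gene_jitter_sigma = 0``
    all signature genes of an MSP have identical expected frequency.
    """
    rng = _stream(params.master_seed, "inoculum")
    mu, sigma = params.donor_abundance_lognormal
    a = rng.lognormal(mu, sigma, size=len(cat)) if sigma > 0 else np.full(
        len(cat), np.exp(mu)
    )
    a = a / a.sum()
    msp_abund = pd.Series(a, index=pd.Index(cat.msp_ids, name="msp_id"))
    gene_ids, msp_pos = _gene_arrays(cat)
    jitter = (
        rng.lognormal(0.0, params.gene_jitter_sigma, size=len(gene_ids))
        if params.gene_jitter_sigma > 0
        else np.ones(len(gene_ids))
    )
    weight = pd.Series(a[msp_pos] * jitter, index=gene_ids)
    return Inoculum(msp_abundance=msp_abund, gene_weight=weight)


def _gene_lengths(cat: MSPCatalogue, params: GeneratorParams) -> pd.Series:
    rng = _stream(params.master_seed, "lengths")
    gene_ids, _ = _gene_arrays(cat)
    mu, sigma = params.gene_length_lognormal
    lengths = np.maximum(1, np.round(rng.lognormal(mu, sigma, size=len(gene_ids))))
    return pd.Series(lengths.astype(np.int64), index=gene_ids)


def _family_bias_vector(cat: MSPCatalogue, bias: float) -> np.ndarray:
    fams = np.array([e.lineage.get("family", "") for e in cat.entries.values()])
    return np.where(np.isin(fams, BIASED_FAMILIES), bias, 1.0)


def _resolve_bloomers(
    scenario: Scenario,
    cat: MSPCatalogue,
    rng: np.random.Generator,
    exclude: set[str],
    donor: pd.Series | None = None,
) -> dict[str, float]:
    """Map bloomer selectors to concrete MSP ids with fold increases.

    ``rare:<k>`` samples among MSP below the median donor abundance, so
    large planted blooms do not redistribute much community mass onto
    the unaffected MSP (a compositional artifact that would otherwise
    masquerade as depletion).
    """
    folds: dict[str, float] = {}
    ids = cat.msp_ids
    for selector, fold in scenario.bloomers:
        if selector.startswith("family:"):
            fam = selector.split(":", 1)[1]
            chosen = [
                m for m in ids
                if cat.entries[m].lineage.get("family") == fam and m not in exclude
            ]
        elif selector.startswith("random:"):
            k = int(selector.split(":", 1)[1])
            pool = [m for m in ids if m not in exclude and m not in folds]
            chosen = list(rng.choice(pool, size=min(k, len(pool)), replace=False))
        elif selector.startswith("rare:"):
            if donor is None:
                raise ValueError("'rare:' bloomer selector needs donor abundances")
            k = int(selector.split(":", 1)[1])
            cutoff = float(donor.median())
            pool = [
                m for m in ids
                if m not in exclude and m not in folds and donor[m] <= cutoff
            ]
            chosen = list(rng.choice(pool, size=min(k, len(pool)), replace=False))
        else:
            if selector not in cat.entries:
                raise ValueError(f"unknown bloomer selector {selector!r}")
            chosen = [] if selector in exclude else [selector]
        for m in chosen:
            folds[m] = float(fold) ** scenario.theta
    return folds


def default_scenarios(
    thetas: dict[tuple[str, str], float] | None = None,
    ctrl_theta: float = 0.05,
    **scenario_kwargs,
) -> dict[tuple[str, str], Scenario]:
    """One scenario per group of the default design.

    ``thetas`` overrides the per-group degradation strengths; the
    control keeps a small theta representing fresh-transplant
    remodeling only.  Defaults order the frozen diluents as observed:
    MD best preserved, TR intermediate, NaCl worst, W7 worse than W1.
    """
    base = {
        ("CTRL", "none"): ctrl_theta,
        ("MD", "W1"): 0.25,
        ("TR", "W1"): 0.40,
        ("NaCl", "W1"): 0.60,
        ("MD", "W7"): 0.45,
        ("TR", "W7"): 0.50,
        ("NaCl", "W7"): 0.70,
    }
    if thetas:
        base.update(thetas)
    return {
        g: Scenario(name=f"{g[0]}:{g[1]}", theta=t, **scenario_kwargs)
        for g, t in base.items()
    }


def simulate_study(
    design: StudyDesign,
    params: GeneratorParams,
    scenarios: dict[tuple[str, str], Scenario],
    catalogue: MSPCatalogue | None = None,
    inoculum: Inoculum | None = None,
) -> tuple[GeneCountTable, SampleMetadata, GroundTruth]:
    """Simulate one full study: counts, metadata and planted truth.

    One sample per mouse per day; each sample's reads are multinomial
    over genes with total exactly ``params.read_depth``.  Extinctions
    and mouse random effects are drawn once per mouse and persist
    across days (positive within-subject correlation); day drift is
    redrawn per (mouse, day).  The phylum humanization shift applies to
    every mouse group including CTRL, never to the inoculum.  Streams
    are keyed hierarchically off ``params.master_seed`` by (group,
    mouse, day), so any subset of mice reproduces independently.
    """
    for g in design.groups:
        if g not in scenarios:
            raise ValueError(f"missing scenario for group {g}")
    if catalogue is None:
        catalogue = generate_catalogue(params)
    if inoculum is None:
        inoculum = generate_inoculum(catalogue, params)

    gene_ids, msp_pos = _gene_arrays(catalogue)
    lengths = _gene_lengths(catalogue, params)
    donor = inoculum.msp_abundance.to_numpy()
    base_gene_w = inoculum.gene_weight.to_numpy()
    # per-gene weight relative to its MSP abundance (jitter * donor share)
    rel_gene_w = base_gene_w / np.where(donor[msp_pos] > 0, donor[msp_pos], 1.0)
    phyla = np.array(
        [e.lineage.get("phylum", "") for e in catalogue.entries.values()]
    )
    human = np.array(
        [params.humanization_shift.get(ph, 1.0) for ph in phyla]
    )
    msp_ids = np.array(catalogue.msp_ids)
    n_msp = len(msp_ids)
    length_arr = lengths.to_numpy().astype(float)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    status: dict[str, dict[str, str]] = {}
    thetas: dict[str, float] = {}
    per_mouse_extinct: dict[str, list[str]] = {}

    for diluent, week in design.groups:
        scenario = scenarios[(diluent, week)]
        glabel = f"{diluent}:{week}"
        thetas[glabel] = scenario.theta
        grng = _stream(params.master_seed, "group", glabel)
        p_ext = np.clip(
            scenario.theta
            * scenario.extinction_base
            * _family_bias_vector(catalogue, scenario.family_bias),
            0.0,
            1.0,
        )
        group_extinct: np.ndarray | None = None
        if scenario.consistent_extinctions:
            k = int(round(p_ext.sum()))
            group_extinct = np.zeros(n_msp, dtype=bool)
            if k > 0 and p_ext.sum() > 0:
                chosen = grng.choice(
                    n_msp, size=min(k, int((p_ext > 0).sum())), replace=False,
                    p=p_ext / p_ext.sum(),
                )
                group_extinct[chosen] = True
        bloom_exclude = set(msp_ids[group_extinct]) if group_extinct is not None else set()
        folds = _resolve_bloomers(
            scenario, catalogue, grng, bloom_exclude, donor=inoculum.msp_abundance
        )
        bloom_vec = np.ones(n_msp)
        for m, f in folds.items():
            bloom_vec[np.searchsorted(msp_ids, m)] = f

        gstatus = {m: "unchanged" for m in msp_ids}
        for m in folds:
            gstatus[m] = "bloomed"
        if group_extinct is not None:
            for m in msp_ids[group_extinct]:
                gstatus[m] = "extinct"
        status[glabel] = gstatus

        for i in range(1, design.mice_per_group + 1):
            mouse_id = f"{diluent}-{week}-m{i}" if week != "none" else f"CTRL-m{i}"
            mrng = _stream(params.master_seed, "mouse", glabel, i)
            if group_extinct is not None:
                extinct = group_extinct
            else:
                extinct = mrng.random(n_msp) < p_ext
            per_mouse_extinct[mouse_id] = [str(m) for m in msp_ids[extinct]]
            mouse_eff = (
                mrng.lognormal(0.0, params.mouse_effect_sigma, n_msp)
                if params.mouse_effect_sigma > 0
                else np.ones(n_msp)
            )
            noise_sigma = scenario.theta * scenario.abundance_noise_sigma
            eng_noise = (
                mrng.lognormal(0.0, noise_sigma, n_msp)
                if noise_sigma > 0
                else np.ones(n_msp)
            )
            base = donor * human * mouse_eff * eng_noise * bloom_vec
            base[extinct] = 0.0
            for day in design.days:
                drng = _stream(params.master_seed, "day", glabel, i, day)
                drift = (
                    drng.lognormal(0.0, params.day_drift_sigma, n_msp)
                    if params.day_drift_sigma > 0
                    else np.ones(n_msp)
                )
                abund = base * drift
                gene_p = abund[msp_pos] * rel_gene_w * length_arr
                total = gene_p.sum()
                if total <= 0:
                    raise ValueError(f"mouse {mouse_id} lost every MSP")
                counts = drng.multinomial(params.read_depth, gene_p / total)
                sid = f"{mouse_id}_{day}"
                columns[sid] = counts
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "mouse_id": mouse_id,
                        "diluent": diluent,
                        "week": week,
                        "day": day,
                    }
                )

    counts_df = pd.DataFrame(columns, index=gene_ids)
    table = GeneCountTable(counts=counts_df, lengths=lengths)
    meta = SampleMetadata(table=pd.DataFrame(meta_rows))
    truth = GroundTruth(
        donor_abundance=inoculum.msp_abundance,
        theta=thetas,
        status=status,
        per_mouse_extinct=per_mouse_extinct,
    )
    return table, meta, truth


def mean_correlation_to_control(
    counts: GeneCountTable,
    meta: SampleMetadata,
    catalogue: MSPCatalogue,
    group: tuple[str, str],
    rarefaction_depth: int | None = None,
    seed: int = 0,
    n_signature: int = 50,
) -> float:
    """Pipeline measurement: mean pairwise rho of a group to control.

    Runs rarefaction (optional), FPKM normalization and MSP
    quantification, then averages all experimental x control pairwise
    Spearman correlations over every observation day.
    """
    table = counts
    if rarefaction_depth is not None:
        table = rarefy(table, rarefaction_depth, seed=seed)
    profiles = quantify_msp(fpkm_normalize(table), catalogue, n_signature)
    vals = []
    for day in meta.days:
        mat = pairwise_to_control(profiles, meta, group, day)
        vals.append(mat.rho.to_numpy().ravel())
    return float(np.concatenate(vals).mean())


def calibrate_engraftment(
    target_rho: float,
    scenario_template: Scenario,
    design: StudyDesign,
    params: GeneratorParams,
    tol: float = 0.01,
    max_iter: int = 30,
    rarefaction_depth: int | None = None,
    ctrl_theta: float = 0.05,
    eval_seed: int | None = None,
    n_eval_replicates: int = 2,
) -> tuple[float, float]:
    """Find theta whose simulated mean correlation to control hits a target.

    Bisection on theta in [0, 1] against a deterministic evaluation: a
    two-group study (control plus one experimental group, with the
    design's mice and days) simulated with fixed evaluation seeds per
    iterate and measured through the full engraftment pipeline; the
    objective averages ``n_eval_replicates`` such studies to shrink its
    Monte Carlo error.  The mean correlation is monotone non-increasing
    in theta, so bisection converges; iteration stops when within
    ``tol`` of the target.

    Returns (theta, achieved mean correlation).
    """
    if not 0.0 < target_rho < 1.0:
        raise ValueError("target_rho must lie in (0, 1)")
    eval_seed = params.master_seed if eval_seed is None else eval_seed
    eval_design = StudyDesign(
        groups=(("CTRL", "none"), ("NaCl", "W1")),
        mice_per_group=design.mice_per_group,
        days=design.days,
    )
    eval_sets = []
    for r in range(n_eval_replicates):
        p = replace(params, master_seed=eval_seed + 7919 * r)
        cat = generate_catalogue(p)
        eval_sets.append((p, cat, generate_inoculum(cat, p)))
    ctrl = Scenario(
        name="fresh",
        theta=ctrl_theta,
        extinction_base=scenario_template.extinction_base,
        family_bias=scenario_template.family_bias,
        abundance_noise_sigma=scenario_template.abundance_noise_sigma,
    )

    def evaluate(theta: float) -> float:
        scen = replace(scenario_template, theta=theta)
        rhos = []
        for p, cat, ino in eval_sets:
            counts, meta, _ = simulate_study(
                eval_design,
                p,
                {("CTRL", "none"): ctrl, ("NaCl", "W1"): scen},
                catalogue=cat,
                inoculum=ino,
            )
            rhos.append(
                mean_correlation_to_control(
                    counts, meta, cat, ("NaCl", "W1"),
                    rarefaction_depth=rarefaction_depth, seed=p.master_seed,
                )
            )
        return float(np.mean(rhos))

    lo, hi = 0.0, 1.0
    rho_lo = evaluate(lo)
    if rho_lo <= target_rho:
        raise CalibrationError(
            f"correlation at theta=0 ({rho_lo:.3f}) does not exceed target {target_rho}"
        )
    best = (0.0, rho_lo)
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        rho_mid = evaluate(mid)
        if abs(rho_mid - target_rho) < abs(best[1] - target_rho):
            best = (mid, rho_mid)
        if abs(rho_mid - target_rho) <= tol:
            return mid, rho_mid
        if rho_mid > target_rho:
            lo = mid
        else:
            hi = mid
    if abs(best[1] - target_rho) <= 3 * tol:
        return best
    raise CalibrationError(
        f"target rho {target_rho} not reached within [0, 1] after {max_iter} "
        f"iterations; best achieved {best[1]:.3f} at theta={best[0]:.3f}"
    )
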