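"""Differential engraftment screening of MSP by Wilcoxon rank-sum + BH.

Each experimental group's pooled samples (all mice, all observation
days) are compared MSP-by-MSP against the control group's pooled
samples with a two-sided Wilcoxon rank-sum test.  p-values are
Benjamini-Hochberg adjusted across the tested MSP, and MSP passing
q < 0.05 with |log2 fold change| >= 2 are classified as extinguishing
(depleted) or proliferating (enriched) relative to the fresh-transplant
controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .engraftment import SampleMetadata
from .msp_quant import MSPCatalogue, MSPProfileTable

__all__ = [
    "DifferentialThresholds",
    "wilcoxon_ranksum",
    "bh_adjust",
    "differential_msp",
    "impacted_fraction",
    "summarize_differential",
]

EXACT_MAX_N = 12


@dataclass(frozen=True)
class DifferentialThresholds:
    """Significance and effect-size cutoffs for the MSP screen."""

    q_cutoff: float = 0.05
    lfc_cutoff: float = 2.0
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.q_cutoff < 1.0:
            raise ValueError("q cutoff must lie in (0, 1)")
        if self.lfc_cutoff <= 0:
            raise ValueError("fold-change cutoff must be positive")


def _exact_ranksum_p(scores2: np.ndarray, n_x: int, obs2: int) -> float:
    """Exact two-sided p of the rank-sum via subset-sum counting.

    ``scores2`` are the pooled midranks doubled (integers, tie-aware);
    the null draws ``n_x`` of them uniformly without replacement.  A
    dynamic program counts subsets of each size by sum, giving the full
    permutation distribution, so ties need no separate treatment.
    """
    total = int(scores2.sum())
    n = len(scores2)
    # ways[j][s]: subsets of size j summing to s
    ways = np.zeros((n_x + 1, total + 1), dtype=float)
    ways[0, 0] = 1.0
    for sc in scores2:
        sc = int(sc)  # doubled midranks are >= 2
        for j in range(n_x, 0, -1):
            ways[j, sc:] += ways[j - 1, : ways.shape[1] - sc]
    dist = ways[n_x]
    mean2 = n_x * total / n
    dev = abs(obs2 - mean2)
    sums = np.arange(total + 1)
    p = dist[np.abs(sums - mean2) >= dev - 1e-9].sum() / comb(n, n_x)
    return float(min(1.0, p))


def wilcoxon_ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of x vs y.

    Returns (W, p) with W the midrank sum of ``x`` in the pooled
    ordering.  When both samples have at most 12 observations the
    p-value is exact — the permutation distribution of the midrank sum
    is enumerated by dynamic programming, which handles ties without
    approximation.  Larger samples use the normal approximation with
    the usual tie-corrected variance and a continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n_x].sum())

    if n_x <= EXACT_MAX_N and n_y <= EXACT_MAX_N:
        scores2 = np.round(2 * ranks).astype(int)
        p = _exact_ranksum_p(scores2, n_x, int(round(2 * w)))
        return w, p

    mean = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mean) - 0.5) / np.sqrt(var)  # continuity-corrected
    return w, float(min(1.0, 2 * stats.norm.sf(z)))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(1.0, q_sorted)
    return q


def differential_msp(
    profiles: MSPProfileTable,
    meta: SampleMetadata,
    exp_group: tuple[str, str],
    th: DifferentialThresholds = DifferentialThresholds(),
    inoculum: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-MSP differential screen of one experimental group vs control.

    All observation days are pooled on each side.  Tested MSP are those
    detected (> 0) in at least one sample of the two compared groups or
    in the donor inoculum when provided.  The fold change uses a
    scale-adaptive pseudocount — half the smallest nonzero abundance in
    the compared sub-table — so extinctions yield finite log2FC.

    Returns a DataFrame with columns msp_id, mean_ctrl, mean_exp,
    log2FC, p, q, class.
    """
    diluent, week = exp_group
    exp_ids = list(meta.samples_of(diluent, week)["sample_id"])
    ctrl_ids = list(meta.samples_of("CTRL")["sample_id"])
    if not exp_ids:
        raise ValueError(f"no samples for group {exp_group}")
    if not ctrl_ids:
        raise ValueError("no control samples")

    sub = profiles.abundances[exp_ids + ctrl_ids]
    detected = (sub > 0).any(axis=1)
    if inoculum is not None:
        ino = inoculum.reindex(profiles.msp_ids).fillna(0.0)
        detected |= ino > 0
    universe = profiles.msp_ids[detected]
    if len(universe) == 0:
        raise ValueError("no MSP detected in the compared groups")

    nonzero = sub.to_numpy()[sub.to_numpy() > 0]
    delta = nonzero.min() / 2.0 if nonzero.size else 1.0

    rows = []
    for mid in universe:
        x = sub.loc[mid, exp_ids].to_numpy()
        y = sub.loc[mid, ctrl_ids].to_numpy()
        _, p = wilcoxon_ranksum(x, y)
        mean_exp = float(x.mean())
        mean_ctrl = float(y.mean())
        lfc = float(
            np.log2((mean_exp + delta) / (mean_ctrl + delta))
            / np.log2(th.log_base)
        )
        rows.append(
            {
                "msp_id": mid,
                "mean_ctrl": mean_ctrl,
                "mean_exp": mean_exp,
                "log2FC": lfc,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    sig = out["q"] < th.q_cutoff
    out["class"] = "unchanged"
    out.loc[sig & (out["log2FC"] <= -th.lfc_cutoff), "class"] = "extinguishing"
    out.loc[sig & (out["log2FC"] >= th.lfc_cutoff), "class"] = "proliferating"
    return out


def impacted_fraction(table: pd.DataFrame) -> float:
    """Percentage of tested MSP classified extinguishing or proliferating."""
    if len(table) == 0:
        raise ValueError("empty differential table")
    affected = (table["class"] != "unchanged").sum()
    return 100.0 * affected / len(table)


def summarize_differential(
    table: pd.DataFrame, cat: MSPCatalogue | None = None
) -> dict:
    """Roll-up: impacted fraction plus per-class counts by family and genus."""
    summary: dict = {
        "n_tested": int(len(table)),
        "n_extinguishing": int((table["class"] == "extinguishing").sum()),
        "n_proliferating": int((table["class"] == "proliferating").sum()),
        "impacted_fraction_pct": impacted_fraction(table),
    }
    if cat is not None:
        for rank in ("family", "genus"):
            counts: dict[str, dict[str, int]] = {}
            for _, row in table[table["class"] != "unchanged"].iterrows():
                taxon = cat.lineage_at(str(row["msp_id"]), rank) or "unclassified"
                counts.setdefault(taxon, {"extinguishing": 0, "proliferating": 0})
                counts[taxon][row["class"]] += 1
            summary[f"by_{rank}"] = counts
    return summary
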