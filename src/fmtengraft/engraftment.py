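"""Engraftment scoring: Spearman similarity of MSP profiles to controls.

Engraftment of a transplanted community is scored by how closely the
recipient's MSP relative-abundance profile resembles that of control
mice which received the fresh preparation.  Similarity is the Spearman
rank correlation, computed pairwise between every experimental mouse
and every control mouse sampled on the same day, over a fixed MSP
universe (all MSP detected somewhere in the dataset, zeros retained).
Averaging each mouse's correlations to the control group yields one
response value per mouse per day — the repeated-measures ANOVA input.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .msp_quant import MSPProfileTable

__all__ = [
    "DILUENTS",
    "SampleMetadata",
    "EngraftmentMatrix",
    "spearman",
    "detected_universe",
    "pairwise_to_control",
    "build_response_table",
    "within_group_consistency",
]

DILUENTS = ("CTRL", "NaCl", "MD", "TR")


@dataclass
class SampleMetadata:
    """Per-sample design labels: mouse, diluent group, storage week, day.

    ``table`` columns: sample_id, mouse_id, diluent, week, day.  CTRL
    mice (fresh transplant) carry week "none"; every frozen group has a
    storage week.  One sample per (mouse, day).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "mouse_id", "diluent", "week", "day")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        if t.duplicated(["mouse_id", "day"]).any():
            raise ValueError("more than one sample per (mouse, day)")
        bad = set(t["diluent"]) - set(DILUENTS)
        if bad:
            raise ValueError(f"unknown diluents: {sorted(bad)}")
        ctrl = t["diluent"] == "CTRL"
        if (t.loc[ctrl, "week"] != "none").any() or (
            t.loc[~ctrl, "week"] == "none"
        ).any():
            raise ValueError("week must be 'none' iff diluent is CTRL")

    @property
    def days(self) -> list[str]:
        return list(pd.unique(self.table["day"]))

    def samples_of(
        self, diluent: str, week: str | None = None, day: str | None = None
    ) -> pd.DataFrame:
        t = self.table
        mask = t["diluent"] == diluent
        if week is not None:
            mask &= t["week"] == week
        if day is not None:
            mask &= t["day"] == day
        return t[mask]

    def experimental_groups(self) -> list[tuple[str, str]]:
        t = self.table[self.table["diluent"] != "CTRL"]
        return sorted(set(zip(t["diluent"], t["week"])))


@dataclass
class EngraftmentMatrix:
    """Experimental x control pairwise Spearman rho at one day."""

    rho: pd.DataFrame  # index: experimental sample ids, columns: control sample ids
    day: str

    def __post_init__(self) -> None:
        vals = self.rho.to_numpy()
        if ((vals < -1 - 1e-12) | (vals > 1 + 1e-12)).any():
            raise ValueError("correlations outside [-1, 1]")


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Ties receive average ranks.  Constant vectors have no rank ordering
    and raise rather than returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def detected_universe(profiles: MSPProfileTable) -> pd.Index:
    """MSP with abundance > 0 in at least one sample of the dataset.

    Fixing the universe once, dataset-wide, keeps every pairwise
    correlation on the same dimension; zeros are retained.
    """
    return profiles.msp_ids[(profiles.abundances > 0).any(axis=1)]


def _profile_matrix(profiles: MSPProfileTable, sample_ids: list[str]) -> np.ndarray:
    universe = detected_universe(profiles)
    return profiles.abundances.loc[universe, sample_ids].to_numpy().T


def pairwise_to_control(
    profiles: MSPProfileTable,
    meta: SampleMetadata,
    group: tuple[str, str],
    day: str,
) -> EngraftmentMatrix:
    """All pairwise rho between a group's mice and control mice at one day."""
    diluent, week = group
    exp = meta.samples_of(diluent, week, day)
    ctrl = meta.samples_of("CTRL", day=day)
    if exp.empty:
        raise ValueError(f"no samples for group {group} at {day}")
    if ctrl.empty:
        raise ValueError(f"no control samples at {day}")
    exp_ids = list(exp["sample_id"])
    ctrl_ids = list(ctrl["sample_id"])
    x = _profile_matrix(profiles, exp_ids)
    y = _profile_matrix(profiles, ctrl_ids)
    rho = np.array([[spearman(xi, yj) for yj in y] for xi in x])
    return EngraftmentMatrix(
        rho=pd.DataFrame(rho, index=exp_ids, columns=ctrl_ids), day=day
    )


def build_response_table(
    profiles: MSPProfileTable, meta: SampleMetadata
) -> pd.DataFrame:
    """One engraftment value per experimental mouse per day.

    value(mouse, day) = mean Spearman rho between that mouse's sample
    and each control mouse's sample at the same day.  Raw correlation
    means are used (no Fisher z-transform).  Requires a balanced design:
    every experimental mouse observed at every day.

    Returns a tidy DataFrame with columns mouse_id, diluent, week, day,
    engraftment.
    """
    groups = meta.experimental_groups()
    if not groups:
        raise ValueError("no experimental groups in metadata")
    days = meta.days
    rows = []
    for diluent, week in groups:
        group_meta = meta.samples_of(diluent, week)
        mice = sorted(set(group_meta["mouse_id"]))
        for day in days:
            mat = pairwise_to_control(profiles, meta, (diluent, week), day)
            day_meta = meta.samples_of(diluent, week, day).set_index("sample_id")
            if sorted(set(day_meta["mouse_id"])) != mice:
                raise ValueError(
                    f"unbalanced design: group {(diluent, week)} mice differ across days"
                )
            for sid, mean_rho in mat.rho.mean(axis=1).items():
                rows.append(
                    {
                        "mouse_id": day_meta.loc[sid, "mouse_id"],
                        "diluent": diluent,
                        "week": week,
                        "day": day,
                        "engraftment": mean_rho,
                    }
                )
    out = pd.DataFrame(rows)
    counts = out.groupby(["diluent", "week"])["mouse_id"].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: group sizes differ")
    return out.sort_values(["diluent", "week", "mouse_id", "day"]).reset_index(
        drop=True
    )


def within_group_consistency(
    profiles: MSPProfileTable,
    meta: SampleMetadata,
    group: tuple[str, str],
    day: str,
) -> list[float]:
    """All C(n, 2) pairwise rho among one group's mice at one day."""
    diluent, week = group
    sel = meta.samples_of(diluent, None if diluent == "CTRL" else week, day)
    ids = list(sel["sample_id"])
    if len(ids) < 2:
        raise ValueError(f"group {group} has fewer than 2 mice at {day}")
    x = _profile_matrix(profiles, ids)
    return [spearman(x[i], x[j]) for i, j in combinations(range(len(ids)), 2)]
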