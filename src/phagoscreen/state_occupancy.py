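"""Perturbation-level transcriptomic-state occupancy from per-cell labels.

Given per-cell (perturbation, cluster) assignments — as produced by a
CROP-seq style experiment after upstream demultiplexing and clustering —
this module computes each perturbation's cluster occupancy (fraction of its
cells in each state), the occupancy change relative to the non-targeting
controls, and the correlation between two states' occupancy changes across
perturbations (e.g. the interferon/chemokine trade-off). A multinomial
generator provides synthetic assignments with known baseline and shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OccupancyTable",
    "occupancy",
    "delta_occupancy",
    "state_correlation",
    "simulate_states",
    "bootstrap_delta_ci",
    "UNDEFINED_CORRELATION",
]

logger = logging.getLogger(__name__)

#: Sentinel for a correlation that is undefined (zero variance in a state).
UNDEFINED_CORRELATION = float("nan")

REFERENCE = "NTC"


@dataclass
class OccupancyTable:
    """Row-stochastic perturbation x cluster fractions plus cell counts."""

    fractions: pd.DataFrame  # index perturbation, columns cluster
    n_cells: pd.Series  # index perturbation


def _validate_assignments(assignments: pd.DataFrame, strict: bool) -> pd.DataFrame:
    required = {"cell_id", "perturbation", "cluster"}
    missing = required - set(assignments.columns)
    if missing:
        raise ValueError(f"assignment table missing column(s) {sorted(missing)}")
    df = assignments.copy()
    if strict:
        df = df.drop_duplicates(subset="cell_id", keep=False)
    for col in ("perturbation", "cluster"):
        if (df[col].astype(str).str.len() == 0).any():
            raise ValueError(f"empty labels in column {col!r}")
    return df


def occupancy(assignments: pd.DataFrame, *, min_cells: int = 10,
              strict: bool = False) -> OccupancyTable:
    """Cluster occupancy per perturbation.

    ``fraction(p, c) = #cells(p, c) / #cells(p)``. Perturbations with fewer
    than ``min_cells`` cells are excluded with a logged warning rather than
    an error. ``strict=True`` drops cells whose id appears more than once
    (ambiguous sgRNA assignment should be filtered upstream).
    """
    df = _validate_assignments(assignments, strict)
    counts = pd.crosstab(df["perturbation"], df["cluster"])
    n = counts.sum(axis=1)
    small = n[n < min_cells]
    if len(small):
        logger.warning("excluding %d perturbation(s) below %d cells: %s",
                       len(small), min_cells, list(small.index))
        counts = counts.loc[n >= min_cells]
        n = n[n >= min_cells]
    if counts.empty:
        raise ValueError("no perturbation passes the min-cell filter")
    return OccupancyTable(counts.div(n, axis=0), n)


def delta_occupancy(table: OccupancyTable, reference: str = REFERENCE) -> pd.DataFrame:
    """Occupancy change relative to the reference perturbation.

    ``delta(p, c) = fraction(p, c) - fraction(ref, c)``; each row sums to 0
    and the reference row is identically 0.
    """
    if reference not in table.fractions.index:
        raise ValueError(f"reference perturbation {reference!r} not in table")
    return table.fractions - table.fractions.loc[reference]


def state_correlation(deltas: pd.DataFrame, state_a: str, state_b: str,
                      reference: str = REFERENCE) -> float:
    """Pearson correlation of two states' occupancy changes across perturbations.

    The reference row (identically zero) is excluded. Returns NaN when either
    state has zero variance.
    """
    for s in (state_a, state_b):
        if s not in deltas.columns:
            raise ValueError(f"state {s!r} not in delta table")
    sub = deltas.drop(index=reference, errors="ignore")
    if len(sub) < 3:
        raise ValueError("need at least 3 perturbations for a correlation")
    a, b = sub[state_a].to_numpy(), sub[state_b].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return UNDEFINED_CORRELATION
    return float(stats.pearsonr(a, b).statistic)


def simulate_states(
    perturbations: Sequence[str],
    baseline: Mapping[str, float],
    shifts: Mapping[str, Mapping[str, float]] | None = None,
    cells_per_perturbation: int = 500,
    seed: int = 0,
    reference: str = REFERENCE,
) -> pd.DataFrame:
    """Draw multinomial cell-state assignments per perturbation.

    ``baseline`` maps cluster -> probability (must sum to 1); ``shifts``
    maps perturbation -> {cluster: additive probability shift}. Shifted
    probabilities are renormalised; any negative shifted probability is an
    error. The reference perturbation is appended automatically (no shift)
    if absent. Deterministic per seed.
    """
    clusters = list(baseline)
    base = np.array([baseline[c] for c in clusters], dtype=float)
    if not np.isclose(base.sum(), 1.0):
        raise ValueError("baseline fractions must sum to 1")
    perts = list(perturbations)
    if reference not in perts:
        perts.append(reference)
    rng = np.random.default_rng(seed)
    rows = []
    for p in perts:
        probs = base.copy()
        for c, dv in (shifts or {}).get(p, {}).items():
            probs[clusters.index(c)] += dv
        if (probs < 0).any():
            raise ValueError(f"negative shifted probability for {p!r}")
        probs = probs / probs.sum()
        draws = rng.multinomial(cells_per_perturbation, probs)
        i = 0
        for c, k in zip(clusters, draws):
            for _ in range(k):
                rows.append((f"{p}_{i}", p, c))
                i += 1
    return pd.DataFrame(rows, columns=["cell_id", "perturbation", "cluster"])


def bootstrap_delta_ci(assignments: pd.DataFrame, perturbation: str, cluster: str,
                       reference: str = REFERENCE, n_boot: int = 1000,
                       seed: int = 0, level: float = 0.95,
                       min_cells: int = 1) -> tuple[float, float]:
    """Percentile bootstrap CI for one occupancy delta (cells resampled per arm)."""
    rng = np.random.default_rng(seed)
    def frac(labels: np.ndarray) -> float:
        return float(np.mean(labels == cluster))
    arm = assignments.loc[assignments["perturbation"] == perturbation, "cluster"]
    ref = assignments.loc[assignments["perturbation"] == reference, "cluster"]
    if len(arm) < min_cells or len(ref) < min_cells:
        raise ValueError("too few cells for bootstrap")
    arm_v, ref_v = arm.to_numpy(), ref.to_numpy()
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        deltas[i] = (frac(rng.choice(arm_v, len(arm_v)))
                     - frac(rng.choice(ref_v, len(ref_v))))
    lo, hi = np.quantile(deltas, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
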