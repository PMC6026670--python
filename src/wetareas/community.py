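"""Plot-level diversity summaries and indicator species analysis.

Per plot: total percent cover (sum over species), species richness
(count of species with cover > 0) and diversity as the inverse Simpson
index 1 / sum(p_i^2) — the Hill number of order 2, an effective number
of species. Plots are binned into wetness classes by depth-to-water
(wet 0-0.5 m, moist 0.5-2 m, dry > 2 m) and indicator species analysis
(Dufrene-Legendre) scores each species' association with a class as
IV = 100 * A * B, A being its relative mean abundance in the class and
B its relative frequency there, with significance from a
group-size-preserving permutation null.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DiversitySummary", "WETNESS_CLASSES", "summarize_plot",
    "summarize_plots", "classify_wetness", "indicator_value_analysis",
    "species_accumulation",
]

#: Wetness class bounds in meters DTW: label -> (lower, upper]; the wet
#: class is closed at 0. The gap the field convention leaves between
#: 0.5 m and 0.6 m is closed by treating moist as (0.5, 2].
WETNESS_CLASSES = {"wet": (0.0, 0.5), "moist": (0.5, 2.0),
                   "dry": (2.0, np.inf)}


@dataclass
class DiversitySummary:
    total_cover: float
    richness: int
    inverse_simpson: float


def summarize_plot(covers) -> DiversitySummary:
    """Total cover, richness and inverse Simpson diversity of one plot.

    An empty plot (no cover at all) returns (0, 0, 0) by convention —
    field data do include zero-cover quadrats.
    """
    c = np.asarray(covers, dtype=float)
    if (c < 0).any():
        raise ValueError("covers must be >= 0")
    total = float(c.sum())
    richness = int((c > 0).sum())
    if total == 0:
        return DiversitySummary(0.0, 0, 0.0)
    p = c[c > 0] / total
    return DiversitySummary(total, richness, float(1.0 / np.sum(p ** 2)))


def summarize_plots(table: pd.DataFrame, species: list[str]) -> pd.DataFrame:
    """Apply :func:`summarize_plot` across a wide plot x species table."""
    mat = table[species].to_numpy(dtype=float)
    out = table.drop(columns=species).copy()
    summaries = [summarize_plot(row) for row in mat]
    out["total_cover"] = [s.total_cover for s in summaries]
    out["richness"] = [s.richness for s in summaries]
    out["inverse_simpson"] = [s.inverse_simpson for s in summaries]
    return out


def classify_wetness(dtw) -> np.ndarray | str:
    """Wetness class of DTW value(s): wet [0, 0.5], moist (0.5, 2], dry (2, inf)."""
    arr = np.asarray(dtw, dtype=float)
    if (arr < 0).any():
        raise ValueError("DTW must be >= 0")
    out = np.where(arr <= 0.5, "wet", np.where(arr <= 2.0, "moist", "dry"))
    if np.isscalar(dtw) or arr.ndim == 0:
        return str(out)
    return out


def _iv_matrix(mat: np.ndarray, onehot: np.ndarray, counts: np.ndarray
               ) -> np.ndarray:
    """Indicator values, species x groups, IV = 100 * A * B."""
    mean_cover = (onehot.T @ mat) / counts[:, None]          # groups x species
    denom = mean_cover.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, mean_cover / denom, 0.0)
    B = (onehot.T @ (mat > 0)) / counts[:, None]
    return (100.0 * A * B).T                                  # species x groups


def indicator_value_analysis(table: pd.DataFrame, species: list[str],
                             groups, n_perm: int = 999,
                             seed: int | None = None) -> pd.DataFrame:
    """Indicator species analysis with a permutation null.

    Each species is reported for its maximizing group with its observed
    IV, the mean and SD of the maximum IV under ``n_perm`` random
    reassignments of plots to groups (group sizes preserved), and
    p = (#{perm IV >= observed} + 1) / (n_perm + 1). Species with zero
    total abundance are dropped with a log message.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    mat = table[species].to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        dropped = [s for s, t in zip(species, totals) if t == 0]
        logger.info("dropping %d species with zero total abundance: %s",
                    len(dropped), dropped)
        species = [s for s, t in zip(species, totals) if t > 0]
        mat = mat[:, totals > 0]
    n, _ = mat.shape
    onehot = np.eye(len(labels))[inv]
    counts = onehot.sum(axis=0)
    if (counts == 0).any():
        raise ValueError("every group must contain at least one plot")

    iv = _iv_matrix(mat, onehot, counts)
    best_group = iv.argmax(axis=1)
    observed = iv.max(axis=1)

    rng = np.random.default_rng(seed)
    perm_max = np.empty((n_perm, len(species)))
    for k in range(n_perm):
        perm = rng.permutation(n)
        perm_iv = _iv_matrix(mat[perm], onehot, counts)
        perm_max[k] = perm_iv.max(axis=1)
    exceed = (perm_max >= observed[None, :] - 1e-12).sum(axis=0)
    pvals = (exceed + 1) / (n_perm + 1)
    return pd.DataFrame({
        "species": species,
        "group": labels[best_group],
        "indicator_value": observed,
        "randomized_mean": perm_max.mean(axis=0),
        "randomized_sd": perm_max.std(axis=0, ddof=1),
        "p_value": pvals,
    })


def species_accumulation(table: pd.DataFrame, species: list[str],
                         n_perm: int = 999,
                         seed: int | None = None) -> np.ndarray:
    """Mean species accumulation curve over random plot orderings.

    Entry k-1 is the mean number of distinct species captured by the
    first k plots, averaged over ``n_perm`` random orderings; the curve
    is non-decreasing and ends at the total richness.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if table.empty:
        raise ValueError("empty plot table")
    presence = table[species].to_numpy(dtype=float) > 0
    n = presence.shape[0]
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        seen = np.maximum.accumulate(presence[order], axis=0)
        acc += seen.sum(axis=1)
    return acc / n_perm
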