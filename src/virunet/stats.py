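"""Response variables: relatedness, virulence summaries, prevalence,
densities, and local parasite extinction, with degree-stratified
aggregation.

Within-patch parasite relatedness is the probability that two neutral
alleles drawn with replacement from the parasites of one patch are
identical, ``R_x = sum_k p_k**2`` — the expected homozygosity of the local
allele-frequency spectrum.  Under the infinite-allele mutation scheme,
identity implies common descent since the last mutation, so R_x tracks
local kin structure.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .core import MetapopState, SimulationResult
from .landscapes import LandscapeGraph

__all__ = [
    "relatedness",
    "relatedness_from_alleles",
    "local_extinction",
    "evolved_virulence",
    "prevalence_and_density",
    "patch_statistics",
    "landscape_relatedness",
    "degree_stratified",
]


def _nanmean_cols(arr: np.ndarray) -> np.ndarray:
    """Column nanmean that returns NaN (silently) for all-NaN columns."""
    arr = np.asarray(arr, dtype=float)
    if arr.size == 0:
        return np.full(arr.shape[-1] if arr.ndim > 1 else 0, np.nan)
    valid = ~np.isnan(arr)
    n = valid.sum(axis=0)
    total = np.where(valid, arr, 0.0).sum(axis=0)
    return np.divide(total, n, out=np.full(arr.shape[1], np.nan), where=n > 0)


def relatedness(allele_counts) -> float:
    """Probability of drawing two identical neutral alleles (with
    replacement) from one patch: ``sum_k p_k**2`` over allele frequencies.

    Returns NaN (a missing value, not 0 or 1) for an empty parasite
    population.
    """
    counts = np.asarray(list(allele_counts), dtype=float)
    if np.any(counts < 0):
        raise ValueError("allele counts must be non-negative")
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts / total
    return float(np.sum(p ** 2))


def relatedness_from_alleles(alleles) -> float:
    """Relatedness from a list of per-parasite allele identifiers."""
    alleles = np.asarray(alleles)
    if alleles.size == 0:
        return float("nan")
    _, counts = np.unique(alleles, return_counts=True)
    return relatedness(counts)


def local_extinction(patch_series) -> float:
    """Fraction of a time window during which the patch holds no parasite."""
    series = np.asarray(patch_series)
    if series.size == 0:
        raise ValueError("empty window")
    return float(np.mean(series == 0))


def evolved_virulence(
    final_state: MetapopState | SimulationResult, persisted_only: bool = True
) -> float:
    """Median virulence over all infected hosts landscape-wide at the final
    step.  If the parasite is extinct the result is NaN; with
    ``persisted_only=False`` the caller's aggregator is expected to treat
    that NaN as an included (missing) observation rather than dropping the
    run.
    """
    state = (
        final_state.final_state
        if isinstance(final_state, SimulationResult)
        else final_state
    )
    if state.n_infected == 0:
        return float("nan")
    return float(np.median(state.inf_v))


def prevalence_and_density(S_series, I_series) -> tuple[float, float, float]:
    """Time-averaged (prevalence, infected density, susceptible density)
    for one patch over a window.

    Prevalence averages I/(S+I) over the time points with at least one
    host and is NaN if the patch is empty throughout.
    """
    S = np.asarray(S_series, dtype=float)
    I = np.asarray(I_series, dtype=float)
    if S.size == 0 or S.shape != I.shape:
        raise ValueError("empty or mismatched window")
    N = S + I
    occupied = N > 0
    prev = float(np.mean(I[occupied] / N[occupied])) if occupied.any() else float("nan")
    return prev, float(I.mean()), float(S.mean())


def patch_statistics(
    result: SimulationResult,
    g: LandscapeGraph | None = None,
    window: int = 100,
) -> pd.DataFrame:
    """Per-patch summary over the trailing ``window`` generations.

    One row per patch with: degree, window bounds, relatedness (mean of
    the per-time-point identity probability over parasite-occupied time
    points; NaN if never occupied), mean infected and susceptible
    densities, prevalence, local extinction fraction, and mean virulence.
    """
    g = g or result.landscape
    n = g.n_patches
    deg = g.degrees
    T = result.T
    t0 = max(0, T - window + 1)
    S_win = result.S[t0 : T + 1]
    I_win = result.I[t0 : T + 1]
    rec_mask = result.rec_times >= t0
    R_win = result.relatedness[rec_mask]
    v_win = result.mean_v[rec_mask]
    rows = []
    R_mean = _nanmean_cols(R_win)
    v_mean = _nanmean_cols(v_win)
    for x in range(n):
        prev, mi, ms = prevalence_and_density(S_win[:, x], I_win[:, x])
        rows.append(
            {
                "patch": x,
                "degree": int(deg[x]),
                "t_start": t0,
                "t_end": T,
                "relatedness": float(R_mean[x]),
                "mean_infected": mi,
                "mean_susceptible": ms,
                "prevalence": prev,
                "local_extinction": local_extinction(I_win[:, x]),
                "mean_virulence": float(v_mean[x]),
            }
        )
    return pd.DataFrame(rows)


def landscape_relatedness(
    result: SimulationResult, window: int = 100, occupancy_weighted: bool = False
) -> float:
    """Landscape-level relatedness over the trailing window.

    Default: the unweighted mean over patch-window relatedness values,
    excluding patches never occupied in the window.  With
    ``occupancy_weighted`` each patch-time point is weighted by its
    infected count instead.
    """
    T = result.T
    t0 = max(0, T - window + 1)
    rec_mask = result.rec_times >= t0
    R = result.relatedness[rec_mask]
    if occupancy_weighted:
        I = result.I[result.rec_times[rec_mask]]
        w = np.where(np.isnan(R), 0.0, I.astype(float))
        if w.sum() == 0:
            return float("nan")
        return float(np.nansum(np.nan_to_num(R) * w) / w.sum())
    per_patch = _nanmean_cols(R)
    if np.all(np.isnan(per_patch)):
        return float("nan")
    return float(np.nanmean(per_patch))


def degree_stratified(
    records: pd.DataFrame,
    stats: Iterable[str] = (
        "relatedness",
        "mean_infected",
        "mean_susceptible",
        "prevalence",
        "local_extinction",
        "mean_virulence",
    ),
    degrees: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-degree medians and inter-quartile ranges of patch statistics.

    ``records`` is a (possibly pooled, multi-replicate) table with a
    ``degree`` column, e.g. concatenated :func:`patch_statistics` outputs.
    ``degrees`` restricts to specific degree classes (e.g. [1, 5] for
    headwater vs. hub patches); empty classes are omitted.
    """
    if "degree" not in records.columns:
        raise ValueError("records must carry a 'degree' column")
    stats = [s for s in stats if s in records.columns]
    df = records
    if degrees is not None:
        df = df[df["degree"].isin(list(degrees))]
    out = []
    for degree, grp in df.groupby("degree"):
        row: dict = {"degree": int(degree), "n_patches": len(grp)}
        for s in stats:
            vals = grp[s].dropna()
            if len(vals):
                row[f"{s}_median"] = float(vals.median())
                row[f"{s}_iqr"] = float(vals.quantile(0.75) - vals.quantile(0.25))
            else:
                row[f"{s}_median"] = float("nan")
                row[f"{s}_iqr"] = float("nan")
        out.append(row)
    return pd.DataFrame(out)
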