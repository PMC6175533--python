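"""Vesicle-pool summary statistics and group comparisons.

Covers the morphometric arithmetic reported for CCV/DCV pools: class
ratios, inner-radius-to-diameter conversion (+9 nm membrane correction),
two-sided Mann-Whitney U comparisons (exact enumeration for small groups),
distance-to-active-zone distributions (empirical CDF and Gaussian KDE with
the bandwidth rule 0.07 x data maximum), and per-group feature summaries
with per-tomogram min-max normalization.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .features import minmax_normalize

__all__ = [
    "dcv_ratio",
    "diameter_conversion",
    "mann_whitney_u",
    "distance_distributions",
    "cell_size_change",
    "summarize_groups",
    "MEMBRANE_DIAMETER_CORRECTION_NM",
    "KDE_BANDWIDTH_FACTOR",
]

#: added to the inner diameter to estimate the outer diameter (nm)
MEMBRANE_DIAMETER_CORRECTION_NM = 9.0

#: KDE bandwidth = factor x maximum of the dataset
KDE_BANDWIDTH_FACTOR = 0.07

#: significance-star thresholds
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def dcv_ratio(n_dcv: int, n_total: int, decimals: int = 0) -> float:
    """DCV percentage 100*n_dcv/n_total, rounded half away from zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_dcv <= n_total:
        raise ValueError("need 0 <= n_dcv <= n_total")
    pct = 100.0 * n_dcv / n_total
    factor = 10.0 ** decimals
    return math.floor(pct * factor + 0.5) / factor


def diameter_conversion(r_inner_nm: float) -> tuple[float, float]:
    """Inner and estimated outer diameter from a measured inner radius.

    inner = 2r; outer = 2r + 9 nm (membrane contribution, 4.5 nm per side).
    """
    if r_inner_nm < 0:
        raise ValueError("radius must be non-negative")
    inner = 2.0 * r_inner_nm
    return inner, inner + MEMBRANE_DIAMETER_CORRECTION_NM


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U_A by direct pairwise counting (ties count 1/2)."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float],
                   exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U_A, p).  For groups of at most ``exact_max_n`` each, the p
    value is computed by exhaustive enumeration of all group assignments
    (valid under ties); larger samples use the normal approximation with
    tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_a = _u_statistic(a, b)
    n, m = a.size, b.size
    if n <= exact_max_n and m <= exact_max_n:
        pooled = np.concatenate([a, b])
        mean_u = n * m / 2.0
        obs_dev = abs(u_a - mean_u)
        count = total = 0
        for idx_a in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx_a)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mean_u) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        _, p = sp_stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
        p = float(p)
    return u_a, min(p, 1.0)


def distance_distributions(values: Sequence[float],
                           bandwidth_factor: float = KDE_BANDWIDTH_FACTOR,
                           grid_points: int = 256,
                           ) -> dict:
    """Empirical CDF and Gaussian KDE of a distance sample.

    The KDE bandwidth is ``bandwidth_factor`` x max(values) (default
    factor 0.07).  Returns a dict with the sorted sample and CDF values
    (reaching 1 at the maximum), a KDE evaluation grid padded by 3
    bandwidths, the density on it, and the bandwidth used.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    if vals.size < 2:
        raise ValueError("need at least 2 values")
    cdf = np.arange(1, vals.size + 1) / vals.size
    bw = bandwidth_factor * float(vals.max())
    if bw <= 0:
        raise ValueError("bandwidth is non-positive (all-zero data?)")
    grid = np.linspace(vals.min() - 3 * bw, vals.max() + 3 * bw, grid_points)
    # fixed-bandwidth Gaussian KDE: mixture of N(x_i, bw^2)
    dens = np.exp(-0.5 * ((grid[:, None] - vals[None, :]) / bw) ** 2)
    dens = dens.sum(axis=1) / (vals.size * bw * math.sqrt(2 * math.pi))
    return {"sorted_values": vals, "cdf": cdf,
            "grid": grid, "density": dens, "bandwidth": bw}


def cell_size_change(first_extent: tuple[float, float],
                     last_extent: tuple[float, float]) -> float:
    """Overall cell-size change |dx| + |dy| between first and last slice (nm)."""
    (x1, y1), (x2, y2) = first_extent, last_extent
    if min(x1, y1, x2, y2) <= 0:
        raise ValueError("extents must be positive")
    return abs(x1 - x2) + abs(y1 - y2)


def _stars(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return "n.s."


def summarize_groups(tables: Iterable[pd.DataFrame],
                     states: Sequence[str] | None = None,
                     class_column: str = "class",
                     bonferroni: bool = False) -> dict:
    """Per state-x-class feature summaries with pairwise Mann-Whitney tests.

    ``tables`` are classified per-tomogram tables; ``states`` gives each
    table's condition annotation (e.g. "adult"/"dauer", default from
    ``attrs``).  gv and distAZ are min-max normalized per tomogram before
    pooling.  Returns group summaries (n, median/mean/SD of r, GVSD and
    the normalized gv/distAZ medians) plus pairwise two-sided tests per
    feature with significance stars; no multiple-testing correction by
    default, optional Bonferroni.
    """
    tables = list(tables)
    frames = []
    for i, tab in enumerate(tables):
        state = (states[i] if states is not None
                 else tab.attrs.get("state", tab.attrs.get("source", f"t{i}")))
        sub = tab.copy()
        sub["state"] = state
        if not sub.empty:
            sub["gv_norm"] = minmax_normalize(sub["gv"].to_numpy())
            sub["distAZ_norm"] = minmax_normalize(sub["distAZ"].to_numpy())
        frames.append(sub)
    pooled = pd.concat(frames, ignore_index=True)
    features = {"r": "r", "GVSD": "GVSD", "gv_norm": "gv_norm",
                "distAZ_norm": "distAZ_norm"}

    groups: dict[tuple[str, str], pd.DataFrame] = {}
    for (state, cls), sub in pooled.groupby(["state", class_column]):
        if len(sub) == 0:
            continue
        groups[(state, cls)] = sub

    summaries = {}
    for (state, cls), sub in groups.items():
        entry = {"n": int(len(sub))}
        for name, col in features.items():
            vals = sub[col].to_numpy(dtype=float)
            entry[name] = {"median": float(np.median(vals)),
                           "mean": float(vals.mean()),
                           "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
        summaries[f"{state}/{cls}"] = entry

    tests = []
    keys = sorted(groups)
    pairs = list(itertools.combinations(keys, 2))
    n_tests = len(pairs) * len(features)
    for ka, kb in pairs:
        for name, col in features.items():
            a = groups[ka][col].to_numpy(dtype=float)
            b = groups[kb][col].to_numpy(dtype=float)
            u, p = mann_whitney_u(a, b)
            if bonferroni:
                p = min(1.0, p * n_tests)
            tests.append({"group_a": "/".join(ka), "group_b": "/".join(kb),
                          "feature": name, "U": u, "p": p, "stars": _stars(p)})
    if len(keys) < 2:
        tests = []
    return {"groups": summaries, "tests": tests}
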