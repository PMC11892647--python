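"""Nonparametric comparison battery for measured cell populations.

Implements the two tests used for the morphometric comparisons — the
Mann–Whitney U test (rank-sum, tie-corrected, exact for small untied
samples) and Spearman's rank correlation — plus the four-comparison
battery run on a measured cell table: left vs right volumes, dorsal vs
ventral volumes, superficial vs internalized volumes, and the
depth–volume correlation among internalized cells. Nonparametric tests
are always used; a Shapiro–Wilk normality flag is reported descriptively
and never gates the choice of test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm, rankdata, shapiro
from scipy.stats import t as t_dist

from .morphometry import CellRecord, records_to_frame

__all__ = [
    "TestResult",
    "PopulationSummary",
    "mann_whitney",
    "spearman",
    "run_battery",
    "raincloud_data",
]

log = logging.getLogger("somamorph")

EXACT_MAX_N = 14  # exact U enumeration limit (untied pooled samples)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one group comparison."""

    method: str               # "mann_whitney" | "spearman"
    statistic: float          # min(U1, U2) for Mann-Whitney; rs for Spearman
    p_value: float
    n1: int
    n2: int = 0               # unused for spearman
    exact: bool = False       # exact enumeration vs large-sample approximation
    label: str = ""           # which comparison this is, in battery output


@dataclass
class PopulationSummary:
    """Descriptive summary of the included cell population."""

    n_total: int
    n_included: int
    counts_by_side: dict
    counts_by_face: dict
    counts_by_depth_class: dict
    fraction_internalized: float
    volume_quantiles_um3: dict
    log10_volume_bin_edges: list[float]
    log10_volume_bin_counts: list[int]
    shapiro_p_volume: Optional[float] = None  # descriptive normality flag only


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_from_ranks(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1, n2 = len(a), len(b)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, n1 * n2 - u1


def _exact_p(values: np.ndarray, n1: int, u_min: float) -> float:
    """P(min(U1, U2) <= observed) over all C(n1+n2, n1) group labelings."""
    n = len(values)
    ranks = rankdata(values)
    total = 0
    hits = 0
    offset = n1 * (n1 + 1) / 2.0
    nn = n1 * (n - n1)
    for combo in itertools.combinations(range(n), n1):
        u1 = ranks[list(combo)].sum() - offset
        total += 1
        if min(u1, nn - u1) <= u_min + 1e-9:
            hits += 1
    return hits / total


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test.

    U is computed from midranks; the reported statistic is min(U1, U2)
    with U1 + U2 = n1*n2. For untied pooled samples with n1 + n2 <= 14
    the p-value is exact — the probability, over all equally likely group
    labelings, of a min-U at least as extreme as observed. Otherwise the
    normal approximation with tie correction and continuity correction is
    used.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u1, u2 = _u_from_ranks(a, b)
    u_min = min(u1, u2)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and (n1 + n2) <= EXACT_MAX_N:
        p = _exact_p(pooled, n1, u_min)
        return TestResult("mann_whitney", float(u_min), float(p), n1, n2, exact=True)
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mu = n1 * n2 / 2.0
    if sigma2 <= 0:  # all values identical
        return TestResult("mann_whitney", float(u_min), 1.0, n1, n2, exact=False)
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult("mann_whitney", float(u_min), p, n1, n2, exact=False)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman's rank correlation with two-sided t-approximation p-value.

    rs is the Pearson correlation of midranks (tie-safe); p uses the
    t distribution with n - 2 degrees of freedom. Constant input makes
    the ranks degenerate and is an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rs = float(np.corrcoef(rx, ry)[0, 1])
    rs = max(-1.0, min(1.0, rs))
    if abs(abs(rs) - 1.0) < 1e-12:  # snap exact monotone relations
        rs = math.copysign(1.0, rs)
    if abs(rs) == 1.0:
        p = 0.0
    else:
        t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
        p = float(2.0 * t_dist.sf(abs(t), df=n - 2))
    return TestResult("spearman", rs, p, n1=n, n2=0, exact=False)


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

def _summary(df: pd.DataFrame) -> PopulationSummary:
    inc = df[df.included]
    vols = inc.volume_mesh_um3.to_numpy()
    qs = {q: float(np.quantile(vols, q)) for q in (0.0, 0.01, 0.25, 0.5, 0.75, 0.99, 1.0)}
    lo, hi = np.log10(vols.min()), np.log10(vols.max())
    edges = np.linspace(lo, hi, 31)
    counts, _ = np.histogram(np.log10(vols), bins=edges)
    frac_int = float((inc.depth_class == "internalized").mean())
    shap = float(shapiro(vols).pvalue) if 3 <= len(vols) <= 5000 else None
    return PopulationSummary(
        n_total=int(len(df)),
        n_included=int(len(inc)),
        counts_by_side=inc.side.value_counts().to_dict(),
        counts_by_face=inc.face.value_counts().to_dict(),
        counts_by_depth_class=inc.depth_class.value_counts().to_dict(),
        fraction_internalized=frac_int,
        volume_quantiles_um3=qs,
        log10_volume_bin_edges=[float(e) for e in edges],
        log10_volume_bin_counts=[int(c) for c in counts],
        shapiro_p_volume=shap,
    )


def run_battery(
    records: Sequence[CellRecord] | pd.DataFrame,
    volume_column: str = "volume_mesh_um3",
) -> tuple[PopulationSummary, list[TestResult]]:
    """Run the four standard morphometric comparisons on a cell table.

    1. left vs right soma volumes (Mann–Whitney),
    2. dorsal vs ventral soma volumes (Mann–Whitney, superficial faces),
    3. superficial vs internalized soma volumes (Mann–Whitney),
    4. Spearman correlation of volume with surface distance among
       internalized cells.

    Only ``included`` cells enter. A comparison with an empty group is
    skipped with a logged warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) == 0:
        raise ValueError("no records")
    inc = df[df.included]
    vol = inc[volume_column]
    results: list[TestResult] = []

    def _mw(label: str, mask1, mask2) -> None:
        g1, g2 = vol[mask1].to_numpy(), vol[mask2].to_numpy()
        if len(g1) == 0 or len(g2) == 0:
            log.warning("battery_skip comparison=%s n1=%d n2=%d", label, len(g1), len(g2))
            return
        res = mann_whitney(g1, g2)
        results.append(field_replace(res, label=label))

    _mw("left_vs_right_volume", inc.side == "left", inc.side == "right")
    _mw("dorsal_vs_ventral_volume", inc.face == "dorsal", inc.face == "ventral")
    _mw(
        "superficial_vs_internalized_volume",
        inc.depth_class == "superficial",
        inc.depth_class == "internalized",
    )
    internal = inc[inc.depth_class == "internalized"]
    if len(internal) >= 3:
        res = spearman(internal.surface_distance_um.to_numpy(), internal[volume_column].to_numpy())
        results.append(field_replace(res, label="volume_vs_depth_internalized"))
    else:
        log.warning("battery_skip comparison=volume_vs_depth_internalized n=%d", len(internal))
    return _summary(df), results


def field_replace(res: TestResult, **kw) -> TestResult:
    import dataclasses

    return dataclasses.replace(res, **kw)


# ---------------------------------------------------------------------------
# plot-ready distributional data
# ---------------------------------------------------------------------------

def raincloud_data(values: Sequence[float], n_kde: int = 128) -> dict:
    """Plot-ready pieces of a raincloud panel for one group.

    Returns the jittered points (the values themselves), the quartile box
    (min, q1, median, q3, max), and a Gaussian kernel density evaluated
    on an evenly spaced abscissa spanning the data range. Rendering is
    left to the caller.
    """
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    qs = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
    grid = np.linspace(v.min(), v.max(), n_kde)
    if np.ptp(v) == 0:
        dens = np.zeros_like(grid)
    else:
        dens = gaussian_kde(v)(grid)
    return {
        "points": v,
        "quartiles": {
            "min": float(qs[0]),
            "q1": float(qs[1]),
            "median": float(qs[2]),
            "q3": float(qs[3]),
            "max": float(qs[4]),
        },
        "kde_x": grid,
        "kde_density": dens,
    }
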