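"""Protection equality: the Gini-based index G'.

The inequality of the PEx values across the ``n`` classes of a gradient is
measured with the rank-based Gini coefficient

    G = (2/n) * sum_j(x_(j) * j) / sum_j(x_(j)) - (n+1)/n,

where x_(j) are the PEx values sorted ascending and j their ranks. Equality is
G' = 1 - G: 1 when every class is protected at the same rate, and 1/n (the
rank-formula minimum for finite n) when a single class holds all protection.
Before averaging per-variable G' values into a territory-level score,
collinear gradients are pruned with Kendall's tau over consecutive variable
pairs in the fixed analysis order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import PHYSICAL_VARIABLES
from . import representation as rep


class UndefinedEqualityError(ValueError):
    """All-zero PEx: 'no protection at all' is not 'maximally unequal protection'."""


def gini(values) -> float:
    """Rank-based Gini coefficient of a nonnegative vector (sorted ascending first).

    Scale-invariant; G in [0, (n-1)/n]. Raises :class:`UndefinedEqualityError`
    on an all-zero vector, which carries a different meaning (no protection)
    than a concentrated one.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("gini needs at least 2 values")
    if np.any(x < 0):
        raise ValueError("gini is defined for nonnegative values")
    total = x.sum()
    if total <= 0:
        raise UndefinedEqualityError("undefined equality: no protection")
    j = np.arange(1, n + 1)
    return float((2.0 / n) * (x @ j) / total - (n + 1) / n)


def equality_index(pex_vector) -> float:
    """G' = 1 - Gini of the PEx vector; 1 is perfectly even representation."""
    return 1.0 - gini(pex_vector)


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall's tau-b between two paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("kendall_tau needs two equal-length samples of size >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("kendall_tau undefined for a constant margin")
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


@dataclass
class CollinearityReport:
    """Audit trail of the consecutive-pair pruning pass."""

    threshold: float
    tau_matrix: pd.DataFrame
    decisions: list = field(default_factory=list)  # dicts: pair, tau, eliminated


def prune_collinear(values, variables=None, threshold=0.55, iterative=False):
    """Drop collinear variables by a left-to-right pass over consecutive pairs.

    ``values`` is a cells-by-variables frame in the fixed analysis order. When
    |tau| between an active variable and the next active one exceeds the
    threshold, the EARLIER variable is eliminated and the pass continues from
    the survivor. ``iterative=True`` repeats passes until stable. Returns
    ``(retained, report)``; the report records every comparison.
    """
    if variables is None:
        variables = [v for v in values.columns]
    if len(variables) < 1:
        raise ValueError("no variables to prune")
    tau_matrix = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    for a in range(len(variables)):
        for b in range(a + 1, len(variables)):
            t = kendall_tau(values[variables[a]], values[variables[b]])
            tau_matrix.iloc[a, b] = tau_matrix.iloc[b, a] = t
    report = CollinearityReport(threshold=threshold, tau_matrix=tau_matrix)
    active = list(variables)
    while True:
        eliminated_any = False
        i = 0
        while i < len(active) - 1:
            t = tau_matrix.loc[active[i], active[i + 1]]
            decision = {"pair": (active[i], active[i + 1]), "tau": float(t)}
            if abs(t) > threshold:
                decision["eliminated"] = active[i]
                active.pop(i)
                eliminated_any = True
            else:
                decision["eliminated"] = None
                i += 1
            report.decisions.append(decision)
        if not (iterative and eliminated_any):
            break
    if len(active) < 2:
        warnings.warn(
            "fewer than 2 variables survive collinearity pruning; the mean G' "
            "rests on a single gradient",
            stacklevel=2,
        )
    return active, report


@dataclass
class EqualityResult:
    """Per-territory equality: per-variable G', retained set, and their mean."""

    territory: str
    period: int
    basis: str  # "physical" or "biogeographical"
    per_variable: dict  # variable -> G' or None where undefined
    retained: list
    mean_gprime: float | None
    extent_pct: float
    warnings: list = field(default_factory=list)


def territory_equality(histograms, retained, extent_pct, basis="physical") -> EqualityResult:
    """Average the per-variable G' of the retained gradients for one territory.

    ``histograms`` maps variable -> RepresentationHistogram (one period). A
    variable whose PEx is all zero is reported as undefined and skipped from
    the mean, with a warning recorded.
    """
    per_var = {}
    warns = []
    some = next(iter(histograms.values()))
    for var, hist in histograms.items():
        try:
            per_var[var] = equality_index(hist.pex)
        except UndefinedEqualityError:
            per_var[var] = None
            warns.append(f"{var}: equality undefined (no protection)")
    vals = [per_var[v] for v in retained if per_var.get(v) is not None]
    mean = float(np.mean(vals)) if vals else None
    if mean is None:
        warns.append("no retained variable has defined equality")
    return EqualityResult(
        territory=some.territory,
        period=some.period,
        basis=basis,
        per_variable=per_var,
        retained=list(retained),
        mean_gprime=mean,
        extent_pct=float(extent_pct),
        warnings=warns,
    )


def ecoregion_equality(pex_table, territory, period, extent_pct) -> EqualityResult:
    """G' across the PEx values of a territory's biogeographical units.

    A territory with a single ecoregion carries no gradient to balance; its
    equality is undefined (flagged, not zero).
    """
    warns = []
    pex = pex_table["pex_pct"].to_numpy(dtype=float)
    if len(pex) < 2:
        gp = None
        warns.append("single biogeographical unit: equality undefined")
    else:
        try:
            gp = equality_index(pex)
        except UndefinedEqualityError:
            gp = None
            warns.append("equality undefined (no protection)")
    return EqualityResult(
        territory=territory,
        period=int(period),
        basis="biogeographical",
        per_variable={"ecoregion": gp},
        retained=["ecoregion"],
        mean_gprime=gp,
        extent_pct=float(extent_pct),
        warnings=warns,
    )


def protection_extent_pct(cell_table, territory, period) -> float:
    """Percent of the territory's land protected at the period's cutoff."""
    sub = cell_table[
        (cell_table["territory"] == territory) & (cell_table["period"] == period)
    ]
    land = sub["land_km2"].sum()
    if land <= 0:
        raise ValueError(f"territory {territory} has no land area")
    return float(100.0 * sub["protected_km2"].sum() / land)


@dataclass
class TrajectoryPoint:
    territory: str
    cutoff_year: int
    extent_pct: float
    mean_gprime: float | None
    efficiency: float | None  # dG'/dExtent vs the previous decade


def territory_periods(cell_table, territory):
    sub = cell_table[cell_table["territory"] == territory]
    return sorted(sub["period"].unique())


def compute_equality(cell_table, territory, period, basis="physical", n_bins=10,
                     threshold=0.55, variables=PHYSICAL_VARIABLES,
                     iterative_pruning=False) -> EqualityResult:
    """End-to-end equality for one territory/period from the tidy cell table."""
    extent = protection_extent_pct(cell_table, territory, period)
    if basis == "biogeographical":
        tab = rep.ecoregion_pex(cell_table, territory, period)
        return ecoregion_equality(tab, territory, period, extent)
    sub = cell_table[cell_table["territory"] == territory].drop_duplicates("cell_id")
    retained, _ = prune_collinear(sub[list(variables)], list(variables),
                                  threshold=threshold, iterative=iterative_pruning)
    hists = {}
    for var in variables:
        edges = rep.territory_edges(cell_table, territory, var, n_bins=n_bins)
        hists[var] = rep.build_histogram(cell_table, territory, var, period, edges)
    return territory_equality(hists, retained, extent)


def trajectory(cell_table, territory, basis="physical", n_bins=10,
               threshold=0.55, variables=PHYSICAL_VARIABLES) -> list:
    """Decadal extent/equality trajectory with decade-to-decade efficiency.

    Efficiency is (G'_t - G'_{t-1}) / (extent_t - extent_{t-1}); undefined
    (None) when the network did not grow in the decade.
    """
    points = []
    prev = None
    for period in territory_periods(cell_table, territory):
        res = compute_equality(cell_table, territory, period, basis=basis,
                               n_bins=n_bins, threshold=threshold,
                               variables=variables)
        eff = None
        if prev is not None and prev.mean_gprime is not None \
                and res.mean_gprime is not None:
            d_ext = res.extent_pct - prev.extent_pct
            if d_ext > 0:
                eff = (res.mean_gprime - prev.mean_gprime) / d_ext
        pt = TrajectoryPoint(territory, int(period), res.extent_pct,
                             res.mean_gprime, eff)
        points.append(pt)
        prev = pt
    return points
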