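"""Conservation-priority mapping.

Each grid cell's priority is its mean shortfall from full protection across
the retained physical gradients:

    Pr_k = (1/m) * sum_i (100% - PEx_i(bin of cell k)),

so cells sitting in poorly represented conditions score high. Scores are
classified into quantile classes of equal cell count (quartiles for the main
maps, deciles for the detailed ones), nationally (per territory histograms) or
continentally (the whole extent as a single unit of analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import PHYSICAL_VARIABLES
from . import representation as rep
from .equality import prune_collinear


@dataclass
class PriorityMap:
    """Per-cell priority scores and quantile classes for one scope."""

    scope: str  # "national" or "continental"
    period: int
    table: pd.DataFrame  # cell_id, territory, lon, lat, pr, [class]
    retained: dict  # scope unit -> retained variable list
    degenerate: bool = False  # all scores tied when classified


def cell_priority(pex_by_variable) -> float:
    """Mean over retained variables of (100 - PEx of the cell's bin)."""
    vals = [100.0 - p for p in pex_by_variable if p is not None and not np.isnan(p)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def _scores_for_unit(cell_table, unit_rows, territory, period, n_bins, threshold,
                     variables):
    """Pr for every cell of one analysis unit (a territory, or the whole extent)."""
    cells = unit_rows.drop_duplicates("cell_id").set_index("cell_id")
    retained, _ = prune_collinear(cells[list(variables)], list(variables),
                                  threshold=threshold)
    pex_cols = {}
    for var in retained:
        edges = rep.territory_edges(unit_rows, territory, var, n_bins=n_bins) \
            if territory is not None else _extent_edges(unit_rows, var, n_bins)
        hist = _unit_histogram(unit_rows, territory, var, period, edges)
        vals = cells[var].to_numpy(dtype=float)
        pex = np.full(len(cells), np.nan)
        ok = ~np.isnan(vals)
        pex[ok] = hist.pex[rep.assign_bins(vals[ok], edges)]
        pex_cols[var] = pex
    mat = np.column_stack(list(pex_cols.values()))
    with np.errstate(invalid="ignore"):
        pr = np.nanmean(100.0 - mat, axis=1)
    flagged = np.isnan(mat).any(axis=1) & ~np.isnan(pr)
    out = pd.DataFrame(
        {
            "cell_id": cells.index,
            "territory": territory if territory is not None else "ALL",
            "lon": cells["lon"].to_numpy(),
            "lat": cells["lat"].to_numpy(),
            "pr": pr,
            "partial": flagged,
        }
    )
    return out, retained


def _extent_edges(rows, var, n_bins):
    cells = rows.drop_duplicates("cell_id")
    vals = cells[var].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    return rep.trimmed_equal_width_edges(vals[ok], cells["land_km2"].to_numpy()[ok],
                                         n_bins=n_bins)


def _unit_histogram(rows, territory, var, period, edges):
    if territory is not None:
        return rep.build_histogram(rows, territory, var, period, edges)
    # continental scope: all territories pooled as one unit of analysis
    pooled = rows[rows["period"] == period].copy()
    pooled["territory"] = "ALL"
    return rep.build_histogram(pooled, "ALL", var, period, edges)


def compute_priority(cell_table, scope="national", period=None, n_bins=10,
                     threshold=0.55, variables=PHYSICAL_VARIABLES) -> PriorityMap:
    """Priority scores for the current (latest) period at the requested scope.

    National scope bins and prunes per territory; continental scope treats the
    full extent as a single unit, so a condition common in one country but
    rare overall scores differently in the two maps.
    """
    if scope not in ("national", "continental"):
        raise ValueError(f"unknown scope {scope!r}")
    if period is None:
        period = int(cell_table["period"].max())
    frames, retained = [], {}
    if scope == "national":
        for terr in sorted(cell_table["territory"].unique()):
            rows = cell_table[cell_table["territory"] == terr]
            tab, kept = _scores_for_unit(cell_table, rows, terr, period,
                                         n_bins, threshold, variables)
            frames.append(tab)
            retained[terr] = kept
    else:
        tab, kept = _scores_for_unit(cell_table, cell_table, None, period,
                                     n_bins, threshold, variables)
        frames.append(tab)
        retained["ALL"] = kept
    table = pd.concat(frames, ignore_index=True)
    return PriorityMap(scope=scope, period=int(period), table=table,
                       retained=retained)


def classify_quantiles(priority_map: PriorityMap, k_classes=4) -> PriorityMap:
    """Rank-based classes of equal cell count (+-1), 1 = lowest priority.

    Ties are broken by cell_id so maps are reproducible; a map where every
    score ties is still balanced and flagged degenerate.
    """
    if k_classes not in (4, 10):
        raise ValueError("k_classes must be 4 (quartiles) or 10 (deciles)")
    tab = priority_map.table.copy()
    scored = tab[~tab["pr"].isna()]
    if len(scored) < k_classes:
        raise ValueError(
            f"only {len(scored)} scored cells; need at least {k_classes}"
        )
    order = scored.sort_values(["pr", "cell_id"], kind="stable").index
    classes = np.empty(len(order), dtype=int)
    for c, chunk in enumerate(np.array_split(np.arange(len(order)), k_classes)):
        classes[chunk] = c + 1
    tab.loc[order, "class"] = classes
    degenerate = scored["pr"].nunique() == 1
    return PriorityMap(
        scope=priority_map.scope,
        period=priority_map.period,
        table=tab,
        retained=priority_map.retained,
        degenerate=degenerate,
    )
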