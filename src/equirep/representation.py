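"""Protection histograms along continuous gradients.

For a territory and a continuous variable, the territory's land is binned into
``n`` classes of the variable (default 10, equal-width between the 0.025 and
0.975 area-weighted percentiles, with the tails absorbed into the first and
last class rather than discarded). Per class ``j`` the histogram records the
total land area, the protected area, and their ratio ``PEx_ij`` in percent —
the single quantity all downstream equality and priority statistics consume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import PHYSICAL_VARIABLES

log = logging.getLogger(__name__)


class DegenerateGradientError(ValueError):
    """Raised when a variable is constant over the territory: no gradient to bin."""


def weighted_quantile(values, weights, q):
    """Area-weighted quantile with linear interpolation between order statistics.

    Sorted values x_(k) with weights w_(k) are placed at cumulative positions
    p_k = (S_k - w_k) / (S_n - w_n) where S_k is the running weight sum; the
    quantile interpolates linearly between neighbouring positions. With equal
    weights this reduces exactly to numpy's default 'linear' rule.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    s = np.cumsum(w)
    denom = s[-1] - w[-1]
    if denom <= 0:
        # all mass on the last order statistic
        return np.full(np.shape(q), v[-1]) if np.ndim(q) else float(v[-1])
    p = (s - w) / denom
    return np.interp(q, p, v)


def trimmed_equal_width_edges(values, weights=None, n_bins=10, p_lo=0.025, p_hi=0.975):
    """Bin edges: ``n_bins`` equal-width intervals between the trimming quantiles.

    The outer edges extend to the data min/max so that tail observations are
    grouped into the first and last class (no observation is discarded).
    """
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != values.shape:
            raise ValueError("weights must match values")
    ok = ~np.isnan(values)
    values, weights = values[ok], weights[ok]
    if values.size < 2 or np.min(values) == np.max(values):
        raise DegenerateGradientError(
            "degenerate gradient: variable is constant (or near-empty); "
            "equality along it is undefined"
        )
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    q_lo, q_hi = weighted_quantile(values, weights, [p_lo, p_hi])
    inner = np.linspace(q_lo, q_hi, n_bins + 1)[1:-1]
    edges = np.concatenate(([values.min()], inner, [values.max()]))
    return edges


def sturges_edges(values, weights=None, p_lo=0.025, p_hi=0.975):
    """Edges with the Sturges bin count ``ceil(1 + log2(N))``, same trimming rule."""
    values = np.asarray(values, dtype=float)
    n = int(np.sum(~np.isnan(values)))
    if n < 1:
        raise DegenerateGradientError("no values for Sturges binning")
    n_bins = math.ceil(1 + math.log2(n))
    return trimmed_equal_width_edges(values, weights, n_bins=n_bins, p_lo=p_lo, p_hi=p_hi)


def assign_bins(values, edges) -> np.ndarray:
    """0-based bin index per value; intervals are [lo, hi) with the last closed."""
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, values, side="right") - 1
    # values equal to the last edge belong to the last bin (closed upper end)
    n_bins = len(edges) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    return idx


@dataclass
class RepresentationHistogram:
    """Binned protection along one continuous variable for one territory/period."""

    territory: str
    variable: str
    period: int
    edges: np.ndarray
    area_km2: np.ndarray
    protected_km2: np.ndarray
    skipped_area_km2: float = 0.0

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def pex(self) -> np.ndarray:
        """Relative extent under protection per class, in percent (0 where empty)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 100.0 * self.protected_km2 / self.area_km2
        return np.where(self.area_km2 > 0, p, 0.0)

    @property
    def empty_bins(self) -> np.ndarray:
        return self.area_km2 <= 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "territory": self.territory,
                "variable": self.variable,
                "period": self.period,
                "bin": np.arange(1, self.n_bins + 1),
                "lo": self.edges[:-1],
                "hi": self.edges[1:],
                "area_km2": self.area_km2,
                "protected_km2": self.protected_km2,
                "pex_pct": self.pex,
            }
        )


def build_histogram(cell_table, territory, variable, period, edges) -> RepresentationHistogram:
    """Accumulate land and protected area of one territory/period into bins.

    ``cell_table`` is the tidy per-cell table (one row per cell x territory x
    period) with ``land_km2``, ``protected_km2`` and one column per variable.
    Cells with a missing value of ``variable`` are skipped and their area
    logged, never silently dropped.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) < 0):
        raise ValueError("bin edges must be ascending")
    sub = cell_table[
        (cell_table["territory"] == territory) & (cell_table["period"] == period)
    ]
    vals = sub[variable].to_numpy(dtype=float)
    missing = np.isnan(vals)
    skipped = float(sub.loc[missing, "land_km2"].sum())
    if skipped > 0:
        log.info(
            "territory %s, variable %s: skipped %.3f km2 with missing values",
            territory, variable, skipped,
        )
    sub = sub.loc[~missing]
    vals = vals[~missing]
    n_bins = len(edges) - 1
    idx = assign_bins(vals, edges)
    area = np.bincount(idx, weights=sub["land_km2"].to_numpy(), minlength=n_bins)
    prot = np.bincount(idx, weights=sub["protected_km2"].to_numpy(), minlength=n_bins)
    return RepresentationHistogram(
        territory=territory,
        variable=variable,
        period=int(period),
        edges=edges,
        area_km2=area,
        protected_km2=prot,
        skipped_area_km2=skipped,
    )


def territory_edges(cell_table, territory, variable, n_bins=10, p_lo=0.025, p_hi=0.975,
                    area_weighted=True):
    """Trimmed edges for one territory's cells (any period; values are static).

    ``n_bins`` may be the string ``"sturges"`` to use the Sturges count.
    """
    sub = cell_table[cell_table["territory"] == territory]
    sub = sub.drop_duplicates(subset="cell_id") if "cell_id" in sub.columns else sub
    vals = sub[variable].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    weights = sub["land_km2"].to_numpy()[ok] if area_weighted else None
    vals = vals[ok]
    if isinstance(n_bins, str) and n_bins == "sturges":
        return sturges_edges(vals, weights, p_lo=p_lo, p_hi=p_hi)
    return trimmed_equal_width_edges(vals, weights, n_bins=n_bins, p_lo=p_lo, p_hi=p_hi)


def ecoregion_pex(cell_table, territory, period) -> pd.DataFrame:
    """PEx per biogeographical unit within one territory and period.

    Returns a frame (ecoregion, area_km2, protected_km2, pex_pct); ecoregions
    with zero area inside the territory are absent.
    """
    sub = cell_table[
        (cell_table["territory"] == territory) & (cell_table["period"] == period)
    ]
    g = sub.groupby("ecoregion")[["land_km2", "protected_km2"]].sum()
    g = g[g["land_km2"] > 0]
    out = g.rename(columns={"land_km2": "area_km2"}).reset_index()
    out["pex_pct"] = 100.0 * out["protected_km2"] / out["area_km2"]
    return out
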