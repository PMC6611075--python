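"""Human drivers of protection placement.

Protection along the five human-related gradients is described with the same
trimmed histograms as the physical gradients, and the gradients' relative
importance is ranked with a regression random forest: the response is each
cell's protected fraction, and a variable's importance (VI) is how much the
out-of-bag mean squared error grows when that variable is permuted in the OOB
data, per tree, averaged over trees and scaled by its standard error — the
convention of the classic randomForest %IncMSE. Reported importances are
normalized to percentage shares so they are comparable across territories, and
their uncertainty comes from refitting on bootstrap resamples of the cells.

The forest is assembled from individual regression trees with explicit
bootstrap bookkeeping because the OOB permutation accounting needs per-tree
in-bag/out-of-bag membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .grid import HUMAN_VARIABLES
from . import representation as rep

#: Minimum cells for a meaningful forest fit.
MIN_CELLS = 50


@dataclass
class RFSettings:
    """Forest hyperparameters; defaults follow the analysis convention."""

    ntree: int = 500
    nodesize: int = 1  # minimum terminal-node size
    mtry: int | None = None  # None -> select by OOB-MSE

    def validate(self, n_predictors):
        if self.mtry is not None and not (1 <= self.mtry <= n_predictors):
            raise ValueError(f"mtry must be in 1..{n_predictors}")


@dataclass
class ImportanceResult:
    """Relative VI (percentage shares of total importance) with bootstrap spread."""

    territory: str
    variables: tuple
    vi_mean: np.ndarray  # % shares, mean over bootstrap replicates
    vi_sd: np.ndarray
    raw_mean: np.ndarray  # unnormalized scaled %IncMSE, mean over replicates
    raw_sd: np.ndarray
    top_counts: dict  # variable -> replicates where it ranked first
    settings: RFSettings
    mtry: int
    n_bootstrap: int
    seed: int
    n_cells: int
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "territory": self.territory,
                "variable": self.variables,
                "vi_mean_pct_mse": self.vi_mean,
                "vi_sd_pct_mse": self.vi_sd,
                "ntree": self.settings.ntree,
                "nodesize": self.settings.nodesize,
                "mtry": self.mtry,
                "n_bootstrap": self.n_bootstrap,
            }
        )


def driver_histograms(cell_table, territory, period=None, n_bins=10):
    """Trimmed protection histograms along the five human gradients."""
    if period is None:
        period = int(cell_table["period"].max())
    out = {}
    for var in HUMAN_VARIABLES:
        edges = rep.territory_edges(cell_table, territory, var, n_bins=n_bins)
        out[var] = rep.build_histogram(cell_table, territory, var, period, edges)
    return out


def _fit_forest(X, y, ntree, mtry, nodesize, rng, groups=None):
    """Bagged regression trees with recorded bootstrap membership.

    ``groups`` carries a cell identity per row. When the training data itself
    is a bootstrap resample (duplicated cells), a row only counts as
    out-of-bag if NO copy of its cell is in the tree's bag — otherwise deep
    trees have memorized the cell and every permutation looks important.
    """
    n = len(y)
    if groups is None:
        groups = np.arange(n)
    trees, inbag = [], []
    for _ in range(ntree):
        idx = rng.integers(0, n, n)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=nodesize,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        seen = np.isin(groups, groups[idx])
        inbag.append(seen)
    return trees, inbag


def _aggregate_oob_mse(trees, inbag, X, y) -> float:
    """MSE of the per-sample OOB-aggregated prediction (model selection metric)."""
    n = len(y)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for tree, mask in zip(trees, inbag):
        oob = ~mask
        if not oob.any():
            continue
        pred_sum[oob] += tree.predict(X[oob])
        pred_cnt[oob] += 1
    seen = pred_cnt > 0
    if not seen.any():
        raise ValueError("no out-of-bag samples; increase ntree")
    resid = y[seen] - pred_sum[seen] / pred_cnt[seen]
    return float(np.mean(resid**2))


def _permutation_importance(trees, inbag, X, y, rng) -> np.ndarray:
    """Scaled per-tree OOB permutation importance (%IncMSE convention).

    For each tree and variable: MSE on the tree's OOB cells with the variable
    permuted, minus the unpermuted OOB MSE; the per-tree differences are
    averaged and divided by their standard error. Zero-spread differences fall
    back to the raw mean.
    """
    n_vars = X.shape[1]
    deltas = np.zeros((len(trees), n_vars))
    for t, (tree, mask) in enumerate(zip(trees, inbag)):
        oob = np.flatnonzero(~mask)
        if oob.size == 0:
            continue
        Xo = X[oob]
        base = np.mean((y[oob] - tree.predict(Xo)) ** 2)
        for v in range(n_vars):
            Xp = Xo.copy()
            Xp[:, v] = Xp[rng.permutation(oob.size), v]
            deltas[t, v] = np.mean((y[oob] - tree.predict(Xp)) ** 2) - base
    mean = deltas.mean(axis=0)
    se = deltas.std(axis=0, ddof=1) / np.sqrt(len(trees))
    out = np.where(se > 0, mean / np.where(se > 0, se, 1.0), mean)
    return out


def _relative_shares(raw: np.ndarray) -> np.ndarray:
    """Clip negative importances to zero and normalize to percentage shares."""
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        return np.full_like(raw, 100.0 / len(raw))
    return 100.0 * clipped / total


def _territory_xy(cell_table, territory, period, variables):
    sub = cell_table[
        (cell_table["territory"] == territory) & (cell_table["period"] == period)
    ]
    sub = sub.dropna(subset=list(variables))
    X = sub[list(variables)].to_numpy(dtype=float)
    y = (sub["protected_km2"] / sub["land_km2"]).to_numpy(dtype=float)
    return X, y


def select_mtry(cell_table, territory, candidate_mtrys=(1, 2, 3, 4, 5),
                seed=0, ntree=500, nodesize=1, period=None) -> int:
    """Pick the candidate mtry minimizing the aggregated OOB-MSE; ties -> smallest."""
    if period is None:
        period = int(cell_table["period"].max())
    X, y = _territory_xy(cell_table, territory, period, HUMAN_VARIABLES)
    if len(y) < MIN_CELLS:
        raise ValueError(
            f"insufficient cells for RF: territory {territory} has {len(y)} < {MIN_CELLS}"
        )
    candidates = sorted(set(candidate_mtrys))
    if not all(1 <= m <= X.shape[1] for m in candidates):
        raise ValueError(f"candidate mtry values must lie in 1..{X.shape[1]}")
    best_mtry, best_mse = None, np.inf
    ss = np.random.SeedSequence(seed)
    for m, child in zip(candidates, ss.spawn(len(candidates))):
        rng = np.random.default_rng(child)
        trees, inbag = _fit_forest(X, y, ntree, m, nodesize, rng)
        mse = _aggregate_oob_mse(trees, inbag, X, y)
        if mse < best_mse:  # strict: ties keep the smaller mtry
            best_mse, best_mtry = mse, m
    return best_mtry


def vi_bootstrap(cell_table, territory, settings: RFSettings | None = None,
                 B=1000, seed=0, period=None,
                 variables=HUMAN_VARIABLES) -> ImportanceResult:
    """Variable importance with bootstrap uncertainty.

    Per replicate: resample cells with replacement at full size, fit the
    forest, compute scaled OOB permutation importances, normalize to shares.
    Reported per variable: mean and sd over the B replicates, plus how often
    each variable ranked first (used by planted-driver recovery checks).
    """
    settings = settings or RFSettings()
    settings.validate(len(variables))
    if period is None:
        period = int(cell_table["period"].max())
    X, y = _territory_xy(cell_table, territory, period, variables)
    n = len(y)
    if n < MIN_CELLS:
        raise ValueError(
            f"insufficient cells for RF: territory {territory} has {n} < {MIN_CELLS}"
        )
    if np.all(y == y[0]):
        raise ValueError("no variance to explain: constant protected fraction")
    if B < 1:
        raise ValueError("B must be >= 1")
    mtry = settings.mtry
    if mtry is None:
        mtry = select_mtry(cell_table, territory, seed=seed,
                           ntree=settings.ntree, nodesize=settings.nodesize,
                           period=period)
    flags = []
    shares = np.zeros((B, len(variables)))
    raws = np.zeros((B, len(variables)))
    top = np.zeros(len(variables), dtype=int)
    ss = np.random.SeedSequence((seed, 0x5EED))
    for b, child in enumerate(ss.spawn(B)):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, n)
        Xb, yb = X[idx], y[idx]
        if np.all(yb == yb[0]):
            flags.append(f"replicate {b}: resample had constant response; redrawn")
            idx = rng.integers(0, n, n)
            Xb, yb = X[idx], y[idx]
        trees, inbag = _fit_forest(Xb, yb, settings.ntree, mtry,
                                   settings.nodesize, rng, groups=idx)
        raw = _permutation_importance(trees, inbag, Xb, yb, rng)
        raws[b] = raw
        shares[b] = _relative_shares(raw)
        top[np.argmax(raw)] += 1
    if B > 1:
        sd = shares.std(axis=0, ddof=1)
        raw_sd = raws.std(axis=0, ddof=1)
    else:
        sd = raw_sd = np.zeros(len(variables))
        flags.append("B=1: bootstrap spread undefined, reported as 0")
    return ImportanceResult(
        territory=territory,
        variables=tuple(variables),
        vi_mean=shares.mean(axis=0),
        vi_sd=sd,
        raw_mean=raws.mean(axis=0),
        raw_sd=raw_sd,
        top_counts={v: int(c) for v, c in zip(variables, top)},
        settings=settings,
        mtry=mtry,
        n_bootstrap=B,
        seed=seed,
        n_cells=n,
        flags=flags,
    )
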