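"""Spatial summaries of coupling sensitivities.

Sensitivity maps are summarised three ways: medians across climate zones,
means across aridity x temperature bins (a bin is suppressed when it holds
fewer than 10 cells with significant slopes), and partial Spearman
correlations between ecosystem covariates (biodiversity, root-zone water
storage capacity) and the sensitivities within each bin, controlling for
aridity and temperature, with Benjamini-Hochberg adjustment across all bins
and both covariates jointly (bins with fewer than 20 cells are disregarded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "aridity_index",
    "zone_median",
    "bin_means",
    "partial_spearman",
    "benjamini_hochberg",
    "covariate_analysis",
]


def aridity_index(net_radiation_mm, precipitation_mm):
    """Aridity = net radiation (water-equivalent mm) / precipitation (mm).

    Non-positive precipitation yields NaN (flagged undefined).
    """
    r = np.asarray(net_radiation_mm, dtype=float)
    p = np.asarray(precipitation_mm, dtype=float)
    out = np.where(p > 0, r / np.where(p > 0, p, 1.0), np.nan)
    return out if out.ndim else float(out)


def zone_median(sensitivity, zones):
    """Median sensitivity per climate-zone label (empty zones omitted)."""
    s = pd.Series(np.asarray(sensitivity, dtype=float))
    z = pd.Series(np.asarray(zones, dtype=object), index=s.index)
    valid = s.notna()
    return s[valid].groupby(z[valid]).median()


def _bin_index(values, edges):
    """Left-closed, right-open bin index; -1 outside all bins."""
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[(idx < 0) | (idx >= len(edges) - 1) | ~np.isfinite(values)] = -1
    return idx


def bin_means(
    sensitivity,
    significant,
    aridity,
    temperature,
    aridity_edges,
    temperature_edges,
    min_cells=10,
):
    """Mean sensitivity over significant cells per aridity x temperature bin.

    Bins with fewer than ``min_cells`` significant cells are suppressed (no
    statistics reported).  Returns a tidy DataFrame plus an overflow count of
    cells falling outside every bin.
    """
    s = np.asarray(sensitivity, dtype=float)
    sig = np.asarray(significant, dtype=bool)
    ia = _bin_index(aridity, aridity_edges)
    it = _bin_index(temperature, temperature_edges)
    inside = (ia >= 0) & (it >= 0)
    rows = []
    for a in range(len(aridity_edges) - 1):
        for t in range(len(temperature_edges) - 1):
            m = inside & (ia == a) & (it == t)
            msig = m & sig & np.isfinite(s)
            n_sig = int(msig.sum())
            suppressed = n_sig < min_cells
            rows.append(
                {
                    "aridity_lo": aridity_edges[a],
                    "aridity_hi": aridity_edges[a + 1],
                    "temperature_lo": temperature_edges[t],
                    "temperature_hi": temperature_edges[t + 1],
                    "n_cells": int(m.sum()),
                    "n_significant_cells": n_sig,
                    "suppressed": suppressed,
                    "mean_sensitivity": float(s[msig].mean()) if not suppressed else np.nan,
                    "median_sensitivity": float(np.median(s[msig]))
                    if not suppressed
                    else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_overflow"] = int((~inside).sum())
    return out


def partial_spearman(x, y, controls=None):
    """Partial Spearman correlation of x and y given control variables.

    All series are rank-transformed; the partial correlation is the Pearson
    correlation of the rank residuals after regressing out the (ranked)
    controls.  Constant controls are dropped, reducing to the ordinary
    Spearman correlation when none remain.  The two-sided p-value uses the
    t-distribution with n - 2 - k degrees of freedom.

    Returns ``(rho, p)``; NaN when fewer than 4 complete cases remain or x/y
    is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = []
    if controls is not None:
        ctrl = np.atleast_2d(np.asarray(controls, dtype=float))
        if ctrl.shape[0] == x.size and ctrl.shape[1] != x.size:
            ctrl = ctrl.T
        cols = [c for c in ctrl]
    m = np.isfinite(x) & np.isfinite(y)
    for c in cols:
        m &= np.isfinite(c)
    x, y = x[m], y[m]
    cols = [c[m] for c in cols]
    cols = [c for c in cols if np.ptp(c) > 0]
    n = x.size
    k = len(cols)
    if n < 4 or n - 2 - k < 1 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if k:
        Z = np.column_stack([np.ones(n)] + [stats.rankdata(c) for c in cols])
        rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        if rx.std() <= 1e-12 * n or ry.std() <= 1e-12 * n:
            return float("nan"), float("nan")
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    rho = float(np.clip((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)), -1.0, 1.0))
    dof = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    tval = rho * np.sqrt(dof / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(tval), dof))
    return rho, p


def benjamini_hochberg(p_values, q=0.05):
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(reject, p_adjusted)``; NaN p-values are passed through
    unrejected.  Raises on values outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    adj = np.full(p.shape, np.nan)
    if finite.any():
        rej, padj, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")
        reject[finite] = rej
        adj[finite] = padj
    return reject, adj


def covariate_analysis(
    sensitivity,
    significant,
    covariates,
    aridity,
    temperature,
    aridity_edges,
    temperature_edges,
    min_cells=20,
    alpha=0.05,
    q=0.05,
):
    """Partial Spearman links between covariates and sensitivity, per bin.

    Parameters
    ----------
    sensitivity : per-cell sensitivity values (one sensitivity type).
    significant : per-cell boolean significance of the underlying slope (kept
        for reporting; all screened cells enter the correlation).
    covariates : DataFrame of per-cell covariate columns (e.g. biodiversity,
        rootzone_storage).
    min_cells : bins with fewer cells are disregarded entirely.

    The Benjamini-Hochberg family is all populated bins x all covariate
    columns for this sensitivity type.  Returns a tidy DataFrame with raw and
    BH-adjusted significance flags.
    """
    s = np.asarray(sensitivity, dtype=float)
    sig = np.asarray(significant, dtype=bool)
    ar = np.asarray(aridity, dtype=float)
    te = np.asarray(temperature, dtype=float)
    ia = _bin_index(ar, aridity_edges)
    it = _bin_index(te, temperature_edges)
    rows = []
    for a in range(len(aridity_edges) - 1):
        for t in range(len(temperature_edges) - 1):
            m = (ia == a) & (it == t) & np.isfinite(s)
            n = int(m.sum())
            for cov in covariates.columns:
                c = covariates[cov].to_numpy(dtype=float)
                row = {
                    "aridity_lo": aridity_edges[a],
                    "aridity_hi": aridity_edges[a + 1],
                    "temperature_lo": temperature_edges[t],
                    "temperature_hi": temperature_edges[t + 1],
                    "covariate": cov,
                    "n_cells": n,
                    "n_significant_cells": int((m & sig).sum()),
                    "suppressed": n < min_cells,
                    "partial_rho": np.nan,
                    "p_raw": np.nan,
                }
                if n >= min_cells:
                    rho, p = partial_spearman(
                        c[m], s[m], controls=np.column_stack([ar[m], te[m]])
                    )
                    row["partial_rho"] = rho
                    row["p_raw"] = p
                rows.append(row)
    out = pd.DataFrame(rows)
    out["significant_raw"] = out["p_raw"] < alpha
    reject, adj = benjamini_hochberg(out["p_raw"].to_numpy(), q=q)
    out["p_adjusted"] = adj
    out["significant_bh"] = reject
    return out
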