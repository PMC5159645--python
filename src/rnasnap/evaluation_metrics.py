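"""Evaluation statistics: pooled / stratified Pearson r and per-base summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

BASES = "ACGU"


@dataclass
class PairedSeries:
    """Predicted vs actual values with optional per-entry base and chain labels."""

    predicted: np.ndarray
    actual: np.ndarray
    bases: list[str] | None = None
    chains: list[str] | None = None

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.actual = np.asarray(self.actual, dtype=float)
        if self.predicted.shape != self.actual.shape:
            raise ValueError("predicted and actual must have equal length")
        for labels, what in ((self.bases, "bases"), (self.chains, "chains")):
            if labels is not None and len(labels) != len(self.predicted):
                raise ValueError(f"{what} labels must match series length")


def pearson(x, y) -> float:
    """Product-moment correlation; errors on length < 2 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def per_base_pcc(series: PairedSeries) -> dict[str, tuple[float, int]]:
    """Pearson r stratified by base: {base: (r, n)}; empty strata absent."""
    if series.bases is None:
        raise ValueError("series carries no base labels")
    labels = np.asarray(series.bases)
    out: dict[str, tuple[float, int]] = {}
    for b in BASES:
        sel = labels == b
        n = int(sel.sum())
        if n < 2:
            continue
        out[b] = (pearson(series.predicted[sel], series.actual[sel]), n)
    return out


def per_chain_pcc(series: PairedSeries) -> dict[str, tuple[float, int]]:
    """Pearson r per chain id (chains with < 2 points or zero variance skipped)."""
    if series.chains is None:
        raise ValueError("series carries no chain labels")
    labels = np.asarray(series.chains)
    out: dict[str, tuple[float, int]] = {}
    for cid in dict.fromkeys(series.chains):  # preserve first-seen order
        sel = labels == cid
        n = int(sel.sum())
        p, a = series.predicted[sel], series.actual[sel]
        if n < 2 or np.ptp(p) == 0 or np.ptp(a) == 0:
            continue
        out[cid] = (pearson(p, a), n)
    return out


def base_asa_summary(values, bases) -> dict[str, tuple[float, float, int]]:
    """Sample mean and sd (n−1) of values per base: {base: (mean, sd, n)}.

    A single-value stratum reports sd 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(bases))
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and base labels must have equal length")
    out: dict[str, tuple[float, float, int]] = {}
    for b in BASES:
        v = values[labels == b]
        if v.size == 0:
            continue
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        out[b] = (float(np.mean(v)), sd, int(v.size))
    return out


def density_plot_export(
    series: PairedSeries, n_bins: int = 40, extent: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D binned counts over (predicted, actual) for density-plot rendering.

    Returns (counts[n_bins, n_bins], pred_edges, actual_edges); bin totals
    sum to the series length.  Values on the upper edge fall in the last bin.
    """
    p, a = series.predicted, series.actual
    if p.size == 0:
        raise ValueError("empty series")
    if extent is None:
        lo = min(p.min(), a.min())
        hi = max(p.max(), a.max())
        if hi == lo:
            hi = lo + 1.0
    else:
        lo, hi = extent
    edges = np.linspace(lo, hi, n_bins + 1)
    ip = np.clip(np.digitize(p, edges) - 1, 0, n_bins - 1)
    ia = np.clip(np.digitize(a, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(ip * n_bins + ia, minlength=n_bins * n_bins)
    return counts.reshape(n_bins, n_bins), edges, edges.copy()
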