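"""Xenograft radiotherapy-response classification and association testing.

Each patient-derived xenograft (PDX) model contributes the ratio of median
survival under radiotherapy to median survival under placebo. The ratio
distribution across models is bimodal; the changing point of its kernel
density curve (default 1.52, the deepest valley between the two main modes)
separates responders (ratio >= cutoff) from non-responders. Association
between responsiveness and predicted p53 status is tested with Fisher's
exact test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CUTOFF = 1.52


def survival_ratio(rt_median: float, placebo_median: float) -> float:
    """Ratio of median survival: radiotherapy arm over placebo arm."""
    if rt_median <= 0 or placebo_median <= 0:
        raise ValueError("median survival must be > 0 in both arms")
    return rt_median / placebo_median


def find_cutoff(ratios, default: float = DEFAULT_CUTOFF, grid_size: int = 512) -> float:
    """Changing point of the ratio kernel-density curve.

    Fits a Gaussian KDE (Silverman bandwidth) and returns the location of
    the deepest local minimum between the two highest modes. Degenerate or
    unimodal inputs fall back to ``default`` with a warning.
    """
    ratios = np.asarray(list(ratios), dtype=float)
    if len(ratios) < 5 or np.ptp(ratios) == 0:
        warnings.warn(f"too few or degenerate ratios for a density cutoff; using {default}")
        return default
    kde = stats.gaussian_kde(ratios, bw_method="silverman")
    pad = 3.0 * np.std(ratios) * len(ratios) ** (-1 / 5)
    grid = np.linspace(ratios.min() - pad, ratios.max() + pad, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if len(maxima) < 2:
        warnings.warn(f"ratio density appears unimodal; using default cutoff {default}")
        return default
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = sorted(top2)
    between = np.arange(lo + 1, hi)
    return float(grid[between[np.argmin(dens[between])]])


def classify_responders(ratios, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Responder flag per model: ratio >= cutoff (inclusive)."""
    arr = np.asarray(list(ratios), dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("ratios must be finite")
    return arr >= cutoff


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Sample odds ratio and two-sided exact p for a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) no more likely than the observed one. A zero row or
    column margin yields p = 1.0 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValueError("empty contingency table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin in contingency table; p = 1.0")
        a, b, c, d = t.ravel()
        oddsratio = (a * d / (b * c)) if b * c > 0 else float("nan")
        return oddsratio, 1.0
    a, b, c, d = t.ravel()
    oddsratio = (a * d / (b * c)) if b * c > 0 else float("inf")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(oddsratio), float(p)


def fisher_association(responder_flags, status_labels) -> dict:
    """Association between RT responsiveness and predicted p53 status.

    ``status_labels`` are 'pRF'/'pN' (or any binary coding); the table is
    oriented so the odds ratio > 1 means responders are over-represented in
    the pRF group.
    """
    flags = pd.Series(responder_flags).astype(bool)
    status = pd.Series(status_labels)
    if len(flags) != len(status):
        raise ValueError("flags and statuses must have equal length")
    is_prf = status.astype(str).isin(("pRF", "1", "True", "true"))
    a = int((flags & is_prf.to_numpy()).sum())
    b = int((~flags & is_prf.to_numpy()).sum())
    c = int((flags & ~is_prf.to_numpy()).sum())
    d = int((~flags & ~is_prf.to_numpy()).sum())
    oddsratio, p = fisher_exact_2x2([[a, b], [c, d]])
    return {
        "table": [[a, b], [c, d]],
        "odds_ratio": oddsratio,
        "pvalue": p,
    }


def build_pdx_table(records: pd.DataFrame, cutoff: float | None = None) -> tuple[pd.DataFrame, float]:
    """Add ratio and responder columns to a PDX survival table.

    ``records`` needs rt_median and placebo_median columns; when ``cutoff``
    is None it is estimated from the ratio density.
    """
    need = {"rt_median", "placebo_median"}
    if not need <= set(records.columns):
        raise ValueError(f"PDX table needs columns {sorted(need)}")
    out = records.copy()
    out["ratio"] = [
        survival_ratio(r.rt_median, r.placebo_median) for r in records.itertuples()
    ]
    if cutoff is None:
        cutoff = find_cutoff(out["ratio"])
    out["responder"] = classify_responders(out["ratio"], cutoff)
    return out, float(cutoff)
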