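"""Composite expression scores (CES) for p53-target gene sets.

Four single-sample scoring algorithms summarize the joint expression of a
gene set into one scalar per sample:

- combined Z-score: per-gene standardization across samples, then the sum
  of the set genes' z-scores divided by sqrt(k),
- ssGSEA: weighted Kolmogorov-Smirnov-style running sum over each sample's
  expression ranking (weight exponent ``alpha``), integrated over the
  ranking and rescaled by the cross-sample score range,
- GSVA: per-gene kernel CDF estimate across samples, symmetric rank
  statistic per sample, and the difference between the extreme positive and
  negative running-sum deviations (``tau`` weight, Gaussian kernel with
  bandwidth sd/4 by default, empirical-CDF option for exact small-fixture
  oracles),
- PC1: projection onto the principal axis of the gene-standardized matrix,
  sign-oriented so normal-tissue reference samples score higher than
  TP53-truncated reference samples.

GSVA/ssGSEA/Z-score are computed separately for the DR and UR sets and PC1
on their union, giving the seven per-sample features consumed by the
classifier. Every scorer accepts a ``ref`` matrix so that all cross-sample
statistics (standardization, kernel CDFs, rescaling ranges, the PCA axis)
can be fitted on training samples only and applied to held-out samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .cohort import ExpressionCohort
from .feature_selection import GeneSetPair

#: fixed column order of the CES feature table
CES_COLUMNS = ("gsva_dr", "gsva_ur", "ssgsea_dr", "ssgsea_ur", "zscore_dr", "zscore_ur", "pc1")


def _as_matrix(expr) -> pd.DataFrame:
    return expr.matrix if isinstance(expr, ExpressionCohort) else expr


def _resolve_set(matrix: pd.DataFrame, geneset) -> list[str]:
    genes = list(dict.fromkeys(geneset))
    if not genes:
        raise ValueError("empty gene set")
    present = [g for g in genes if g in matrix.index]
    if len(present) < len(genes):
        missing = sorted(set(genes) - set(present))
        warnings.warn(f"{len(missing)} set genes absent from matrix, skipped: {missing[:5]}")
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    return present


def combined_zscore(expr, geneset, ref=None) -> pd.Series:
    """Combined Z-score: Z_gamma = sum_i z_i / sqrt(k) over the set genes.

    Per gene, z = (x - mu) / sigma with mu and sigma taken across the
    reference samples (sample standard deviation). Zero-variance genes are
    dropped with a warning; an empty effective set is an error.
    """
    matrix = _as_matrix(expr)
    ref_m = _as_matrix(ref) if ref is not None else matrix
    genes = _resolve_set(matrix, geneset)
    mu = ref_m.loc[genes].mean(axis=1)
    sigma = ref_m.loc[genes].std(axis=1, ddof=1)
    keep = sigma > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes from Z-score")
    genes = [g for g, k in zip(genes, keep) if k]
    if not genes:
        raise ValueError("all set genes have zero variance; combined Z-score undefined")
    z = matrix.loc[genes].sub(mu[genes], axis=0).div(sigma[genes], axis=0)
    return z.sum(axis=0) / np.sqrt(len(genes))


def _ssgsea_raw(matrix: pd.DataFrame, in_set: np.ndarray, alpha: float) -> np.ndarray:
    """Integrated running-sum statistic per sample (columns of ``matrix``)."""
    arr = matrix.to_numpy(dtype=float)
    p, n = arr.shape
    k = int(in_set.sum())
    out_dec = 1.0 / (p - k)
    scores = np.empty(n)
    gene_idx = np.arange(p)
    for j in range(n):
        ranks = rankdata(arr[:, j], method="average")
        # traverse by decreasing rank; ties broken by gene position (stable)
        order = np.lexsort((gene_idx, -ranks))
        mask = in_set[order]
        w = np.where(mask, ranks[order] ** alpha, 0.0)
        inc = np.cumsum(w) / w.sum()
        dec = np.cumsum(np.where(mask, 0.0, out_dec))
        scores[j] = np.sum(inc - dec)
    return scores


def ssgsea_score(expr, geneset, alpha: float = 0.25, ref=None, rescale: bool = True) -> pd.Series:
    """Single-sample GSEA score per sample.

    Within each sample, genes are ranked by expression (average ranks on
    ties) and traversed from the highest rank down; in-set steps add
    rank**alpha (normalized over the set), out-of-set steps subtract
    1/(p - k). The raw score is the sum of the running difference, then all
    samples are rescaled by the (max - min) raw-score range of the reference
    samples.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    matrix = _as_matrix(expr)
    genes = _resolve_set(matrix, geneset)
    if len(genes) >= matrix.shape[0]:
        raise ValueError("gene set covers the whole matrix; no out-of-set genes remain")
    in_set = matrix.index.isin(genes)
    raw = _ssgsea_raw(matrix, in_set, alpha)
    if rescale:
        if ref is not None:
            ref_m = _as_matrix(ref)
            ref_raw = _ssgsea_raw(ref_m, ref_m.index.isin(genes), alpha)
        else:
            ref_raw = raw
        span = float(ref_raw.max() - ref_raw.min())
        if span > 0:
            raw = raw / span
        else:
            warnings.warn("degenerate reference score range; ssGSEA left unscaled")
    return pd.Series(raw, index=matrix.columns)


def _kcdf(matrix: pd.DataFrame, ref_m: pd.DataFrame, kcdf: str) -> np.ndarray:
    """Per-gene cross-sample CDF estimate of each expression value."""
    x = matrix.to_numpy(dtype=float)
    r = ref_m.to_numpy(dtype=float)
    p, n = x.shape
    out = np.empty_like(x)
    if kcdf == "ecdf":
        for start in range(0, p, 256):
            stop = min(start + 256, p)
            out[start:stop] = (r[start:stop, None, :] <= x[start:stop, :, None]).mean(axis=2)
        return out
    if kcdf != "gaussian":
        raise ValueError(f"unknown kcdf {kcdf!r}")
    sd = r.std(axis=1, ddof=1) if r.shape[1] > 1 else np.zeros(p)
    h = sd / 4.0
    flat = h <= 0
    # chunk over genes to bound the (genes x samples x ref-samples) temporary
    chunk = max(1, int(4.0e6 // max(1, n * r.shape[1])))
    for start in range(0, p, chunk):
        stop = min(start + chunk, p)
        hs = h[start:stop]
        with np.errstate(divide="ignore", invalid="ignore"):
            zdiff = (x[start:stop, :, None] - r[start:stop, None, :]) / hs[:, None, None]
        out[start:stop] = ndtr(zdiff).mean(axis=2)
        # genes with zero spread degrade to the empirical CDF with ties at 1/2
        for i in np.nonzero(flat[start:stop])[0]:
            gi = start + i
            out[gi] = (r[gi, None, :] < x[gi, :, None]).mean(axis=1) + 0.5 * (
                r[gi, None, :] == x[gi, :, None]
            ).mean(axis=1)
    return out


def _gsva_walk(z: np.ndarray, in_set: np.ndarray, tau: float) -> np.ndarray:
    """GSVA enrichment per sample from the gene-level statistics ``z``."""
    p, n = z.shape
    k = int(in_set.sum())
    out_dec = 1.0 / (p - k)
    gene_idx = np.arange(p)
    half = p / 2.0
    scores = np.empty(n)
    for j in range(n):
        order = np.lexsort((gene_idx, -z[:, j]))
        # symmetric rank statistic: position t (1-based) gets |p - t + 1 - p/2|
        rstat = np.abs(np.arange(p, 0, -1) - half)
        mask = in_set[order]
        w = np.where(mask, rstat**tau, 0.0)
        walk = np.cumsum(w) / w.sum() - np.cumsum(np.where(mask, 0.0, out_dec))
        scores[j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
    return scores


def gsva_score(expr, geneset, kcdf: str = "gaussian", tau: float = 1.0, ref=None) -> pd.Series:
    """Gene set variation analysis score per sample.

    Stage 1 estimates, per gene, where each sample's expression sits in the
    cross-sample distribution (Gaussian-kernel CDF with bandwidth sd/4, or
    the empirical CDF with ``kcdf='ecdf'``). Stage 2 ranks genes within each
    sample by that statistic, applies the symmetric rank weight |r - p/2|,
    and walks the ranking: the score is the sum of the largest positive and
    largest negative running-sum deviations.
    """
    matrix = _as_matrix(expr)
    ref_m = _as_matrix(ref) if ref is not None else matrix
    if ref_m.shape[1] < 3:
        raise ValueError("GSVA needs at least 3 reference samples for the density estimate")
    genes = _resolve_set(matrix, geneset)
    if len(genes) >= matrix.shape[0]:
        raise ValueError("gene set covers the whole matrix; no out-of-set genes remain")
    ref_m = ref_m.loc[matrix.index]
    z = _kcdf(matrix, ref_m, kcdf)
    return pd.Series(_gsva_walk(z, matrix.index.isin(genes), tau), index=matrix.columns)


def pc1_score(expr, genes, nt_ref: list[str], tm_ref: list[str], ref=None) -> pd.Series:
    """Projection onto the first principal axis of the gene-standardized matrix.

    The axis and per-gene standardization are fitted on the reference
    samples; the sign is oriented so that the NT reference mean exceeds the
    TM reference mean.
    """
    matrix = _as_matrix(expr)
    ref_m = _as_matrix(ref) if ref is not None else matrix
    nt_ref, tm_ref = list(nt_ref), list(tm_ref)
    if not nt_ref or not tm_ref:
        raise ValueError("both NT and TM orientation references are required")
    if matrix.shape[1] < 2 or len(_resolve_set(matrix, genes)) < 2:
        raise ValueError("PC1 needs at least 2 samples and 2 genes")
    genes = _resolve_set(matrix, genes)
    ref_sub = ref_m.loc[genes]
    mu = ref_sub.mean(axis=1)
    sigma = ref_sub.std(axis=1, ddof=1)
    keep = sigma > 0
    genes = [g for g, k in zip(genes, keep) if k]
    if len(genes) < 2:
        raise ValueError("degenerate input: fewer than 2 genes with nonzero variance")
    std_ref = ref_m.loc[genes].sub(mu[genes], axis=0).div(sigma[genes], axis=0)
    # principal axis of the samples-by-genes standardized training matrix
    _, s, vt = np.linalg.svd(std_ref.to_numpy().T, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate input: all samples identical")
    axis = vt[0]
    std_all = matrix.loc[genes].sub(mu[genes], axis=0).div(sigma[genes], axis=0)
    proj = pd.Series(std_all.to_numpy().T @ axis, index=matrix.columns)
    ref_proj = pd.Series(std_ref.to_numpy().T @ axis, index=ref_m.columns)
    if ref_proj[nt_ref].mean() < ref_proj[tm_ref].mean():
        proj = -proj
    return proj


@dataclass
class CESModel:
    """Fitted CES parameters: reference matrix, gene sets, scoring options.

    ``fit`` stores the training expression (the source of every cross-sample
    statistic) and the DR/UR pair; ``transform`` scores any matrix over the
    same gene universe, so held-out samples never influence the parameters.
    """

    pair: GeneSetPair = None  # type: ignore[assignment]
    nt_ref: list[str] = field(default_factory=list)
    tm_ref: list[str] = field(default_factory=list)
    alpha: float = 0.25
    kcdf: str = "gaussian"
    tau: float = 1.0
    _ref: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]

    def fit(self, expr, pair: GeneSetPair, nt_ref, tm_ref) -> "CESModel":
        matrix = _as_matrix(expr)
        for sid in list(nt_ref) + list(tm_ref):
            if sid not in matrix.columns:
                raise ValueError(f"orientation reference sample {sid!r} not in training matrix")
        self._ref = matrix
        self.pair = pair
        self.nt_ref = list(nt_ref)
        self.tm_ref = list(tm_ref)
        return self

    def transform(self, expr) -> pd.DataFrame:
        if self._ref is None:
            raise ValueError("CESModel is not fitted")
        matrix = _as_matrix(expr)
        cols = {}
        for name, geneset in (("dr", self.pair.dr), ("ur", self.pair.ur)):
            try:
                cols[f"gsva_{name}"] = gsva_score(
                    matrix, geneset, kcdf=self.kcdf, tau=self.tau, ref=self._ref
                )
                cols[f"ssgsea_{name}"] = ssgsea_score(
                    matrix, geneset, alpha=self.alpha, ref=self._ref
                )
                cols[f"zscore_{name}"] = combined_zscore(matrix, geneset, ref=self._ref)
            except ValueError as exc:
                raise ValueError(f"CES failed for the {name.upper()} set: {exc}") from exc
        try:
            cols["pc1"] = pc1_score(
                matrix, self.pair.all_genes, self.nt_ref, self.tm_ref, ref=self._ref
            )
        except ValueError as exc:
            raise ValueError(f"CES failed for pc1: {exc}") from exc
        table = pd.DataFrame(cols, index=matrix.columns)[list(CES_COLUMNS)]
        if table.isna().any().any():
            raise ValueError("CES table contains missing values")
        return table


def build_ces_table(expr, pair: GeneSetPair, nt_ref, tm_ref, **options) -> pd.DataFrame:
    """Fit-and-score convenience: the seven CES per sample of ``expr``."""
    model = CESModel(**options).fit(expr, pair, nt_ref, tm_ref)
    return model.transform(expr)
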