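"""Cohort-specific selection of p53tru-DR / p53tru-UR gene sets.

Starting from a candidate list of experimentally supported p53 target genes
(direct activated targets and indirectly repressed genes), the stage runs a
two-group differential-expression comparison between adjacent normal tissue
(NT) and TP53-truncated tumors (TM) and keeps candidates passing an
adjusted-P and fold-change threshold. Genes down-regulated in TM form the
DR set; genes up-regulated in TM form the UR set.

The differential-expression engine is deliberately compact: median-of-ratios
library-size normalization, Welch's t-test on log2(normalized count + 1) and
Benjamini-Hochberg adjustment across the tested candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionCohort

#: pseudo-count added before the log2 transform so zero counts stay finite
PSEUDOCOUNT = 1.0


@dataclass
class GeneSetPair:
    """The cohort-specific DR (down in TM) and UR (up in TM) gene sets."""

    dr: tuple[str, ...]
    ur: tuple[str, ...]
    cohort: str = "cohort"
    adj_p_max: float = 0.05
    min_abs_fc: float = 2.0

    def __post_init__(self) -> None:
        self.dr = tuple(self.dr)
        self.ur = tuple(self.ur)
        if set(self.dr) & set(self.ur):
            raise ValueError("DR and UR gene sets must be disjoint")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.dr + self.ur

    def as_gmt(self) -> dict[str, list[str]]:
        return {
            f"{self.cohort}_p53tru_DR": list(self.dr),
            f"{self.cohort}_p53tru_UR": list(self.ur),
        }


def read_candidates(path) -> pd.DataFrame:
    """Read a two-column candidate TSV (gene, class in activated/repressed)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "gene_class"} <= set(df.columns):
        raise ValueError("candidate list needs 'gene' and 'gene_class' columns")
    return validate_candidates(df)


def validate_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    if candidates.empty:
        raise ValueError("candidate gene list is empty")
    if candidates["gene"].duplicated().any():
        dup = candidates.loc[candidates["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate candidate gene {dup!r}")
    bad = set(candidates["gene_class"]) - {"activated", "repressed", "background"}
    if bad:
        raise ValueError(f"unknown candidate classes: {sorted(bad)}")
    return candidates.reset_index(drop=True)


def filter_expressed(
    tpm: ExpressionCohort, candidates: pd.DataFrame, min_median_tpm: float = 1.0
) -> pd.DataFrame:
    """Keep candidates whose median TPM strictly exceeds ``min_median_tpm``.

    Candidates absent from the matrix are skipped with a warning rather than
    raising, since public candidate lists routinely contain symbols missing
    from a given quantification.
    """
    if tpm.layer != "tpm":
        raise ValueError(f"expected the tpm layer, got {tpm.layer!r}")
    candidates = validate_candidates(candidates)
    present = candidates["gene"].isin(tpm.genes)
    if (~present).any():
        missing = candidates.loc[~present, "gene"].tolist()
        warnings.warn(f"{len(missing)} candidate genes absent from matrix, skipped: {missing[:5]}")
    kept = candidates[present]
    medians = tpm.matrix.loc[kept["gene"]].median(axis=1)
    return kept[medians.to_numpy() > min_median_tpm].reset_index(drop=True)


def size_factors(counts: ExpressionCohort | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors (geometric-mean reference).

    Only genes with nonzero counts in every sample enter the reference; if no
    such gene exists the factors fall back to relative library totals, with a
    warning. An all-zero matrix is an error.
    """
    mat = counts.matrix if isinstance(counts, ExpressionCohort) else counts
    arr = mat.to_numpy(dtype=float)
    if arr.sum() == 0:
        raise ValueError("all-zero count matrix")
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        warnings.warn("no gene expressed in every sample; using library-total size factors")
        tot = arr.sum(axis=0)
        return pd.Series(tot / np.exp(np.mean(np.log(tot))), index=mat.columns)
    ref = arr[allpos]
    log_geo = np.mean(np.log(ref), axis=1)
    factors = np.median(np.exp(np.log(ref) - log_geo[:, None]), axis=0)
    return pd.Series(factors, index=mat.columns)


def differential_expression(
    counts: ExpressionCohort,
    group_a: list[str],
    group_b: list[str],
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group DE on candidate genes: log2FC (B vs A), Welch's t, BH.

    ``group_a`` is the reference (NT); ``group_b`` the comparison (TM), so
    genes down in TM get negative log2 fold changes. Returns one row per
    tested gene with columns ``log2fc``, ``pvalue``, ``padj``, ``mean_a``,
    ``mean_b`` and a ``flag`` for degenerate (all-zero group) genes.
    """
    if counts.layer != "counts":
        raise ValueError(f"expected the counts layer, got {counts.layer!r}")
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")

    cohort_ab = counts.subset_samples(group_a + group_b)
    factors = size_factors(cohort_ab)
    norm = cohort_ab.matrix / factors
    if genes is not None:
        missing = [g for g in genes if g not in norm.index]
        if missing:
            warnings.warn(f"{len(missing)} requested genes absent from matrix, skipped")
        genes = [g for g in genes if g in norm.index]
        if not genes:
            raise ValueError("no requested genes present in the count matrix")
        norm = norm.loc[genes]

    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    log_a = np.log2(a + PSEUDOCOUNT)
    log_b = np.log2(b + PSEUDOCOUNT)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2(mean_b + PSEUDOCOUNT) - np.log2(mean_a + PSEUDOCOUNT)

    with np.errstate(divide="ignore", invalid="ignore"):
        tres = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    pvalue = np.asarray(tres.pvalue, dtype=float)
    flag = np.where(
        (a.sum(axis=1) == 0) | (b.sum(axis=1) == 0), "all_zero_group", ""
    )
    # zero variance in both groups -> undefined t; treat as no evidence
    pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)
    padj = multipletests(pvalue, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene": norm.index,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "flag": flag,
        }
    ).set_index("gene")


def select_gene_sets(
    de: pd.DataFrame,
    adj_p_max: float = 0.05,
    min_abs_fc: float = 2.0,
    cohort: str = "cohort",
    fallback_top_n: int | None = None,
) -> GeneSetPair:
    """Threshold DE results into the DR / UR pair.

    DR = significant genes with fold change <= 1/min_abs_fc (down in TM);
    UR = significant genes with fold change >= min_abs_fc. Thresholds are
    inclusive. If either set comes out empty the call fails — unless
    ``fallback_top_n`` is given, in which case the empty side is filled with
    the top-N genes by raw P value having the required fold-change sign
    (used during hold-out validation, where a feature set must always
    exist).
    """
    if adj_p_max <= 0 or min_abs_fc <= 0:
        raise ValueError("thresholds must be positive")
    min_lfc = np.log2(min_abs_fc)
    sig = de["padj"] <= adj_p_max
    dr = sorted(de.index[sig & (de["log2fc"] <= -min_lfc)])
    ur = sorted(de.index[sig & (de["log2fc"] >= min_lfc)])

    if (not dr or not ur) and fallback_top_n is not None:
        if not dr:
            cand = de[de["log2fc"] < 0].sort_values("pvalue")
            dr = sorted(cand.index[:fallback_top_n])
            warnings.warn(f"no DR gene passed thresholds; using top {len(dr)} by P value")
        if not ur:
            cand = de[de["log2fc"] >= 0].sort_values("pvalue")
            ur = sorted(cand.index[:fallback_top_n])
            warnings.warn(f"no UR gene passed thresholds; using top {len(ur)} by P value")
    if not dr or not ur:
        raise ValueError(
            "empty gene set after thresholding "
            f"(DR: {len(dr)}, UR: {len(ur)}; adj_p_max={adj_p_max}, min_abs_fc={min_abs_fc}); "
            "composite scoring needs both sets"
        )
    return GeneSetPair(tuple(dr), tuple(ur), cohort, adj_p_max, min_abs_fc)
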