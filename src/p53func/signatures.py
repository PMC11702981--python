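"""Therapy-sensitivity signature scoring and group comparisons.

Two published signatures are scored per sample from the TPM layer:

- RPS (recombination proficiency score), a chemosensitivity indicator over
  four DNA-repair genes (RIF1, PARI/F2R, RAD51, Ku80/XRCC5), represented
  here as the *negative* GSVA score of the 4-gene set,
- RSS (radiation sensitivity signature), a 51-gene panel split into
  "positive" and "negative" subsets by the sign of each gene's correlation
  with radiation sensitivity; each subset is GSVA-scored independently.

The RSS membership is not shipped (the panel belongs to its original
publication); callers supply it as a GMT with two sets. Only the 4-gene RPS
set is packaged. Group contrasts use the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ces import _as_matrix, gsva_score

#: the four DNA-repair genes of the RPS chemosensitivity signature
RPS_GENES = ("RIF1", "F2R", "RAD51", "XRCC5")


@dataclass
class SignatureSet:
    """A named gene signature with a polarity tag."""

    name: str
    genes: tuple[str, ...]
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


def load_rss_sets(gmt_sets: dict[str, list[str]]) -> tuple[SignatureSet, SignatureSet]:
    """Build the positive/negative RSS subsets from a two-set GMT mapping.

    Set names must contain 'positive' / 'negative'; a gene present in both
    subsets is a validation error.
    """
    pos_name = [n for n in gmt_sets if "positive" in n.lower()]
    neg_name = [n for n in gmt_sets if "negative" in n.lower()]
    if len(pos_name) != 1 or len(neg_name) != 1:
        raise ValueError("RSS GMT must contain exactly one 'positive' and one 'negative' set")
    pos = gmt_sets[pos_name[0]]
    neg = gmt_sets[neg_name[0]]
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"genes present in both RSS subsets: {sorted(overlap)}")
    return (
        SignatureSet(pos_name[0], tuple(pos), "positive"),
        SignatureSet(neg_name[0], tuple(neg), "negative"),
    )


def _log_tpm(tpm) -> pd.DataFrame:
    # GSVA's Gaussian kernel behaves poorly on raw TPM's heavy tail
    return np.log2(_as_matrix(tpm) + 1.0)


def rps_score(tpm, exclude: list[str] | None = None, **gsva_options) -> pd.Series:
    """RPS per sample: the negated GSVA score of the 4-gene repair set."""
    genes = [g for g in RPS_GENES if exclude is None or g not in exclude]
    if not genes:
        raise ValueError("no RPS genes left after exclusion")
    return -1.0 * gsva_score(_log_tpm(tpm), genes, **gsva_options)


def rss_scores(
    tpm,
    positive_set: SignatureSet,
    negative_set: SignatureSet,
    exclude: list[str] | None = None,
    **gsva_options,
) -> pd.DataFrame:
    """GSVA scores of the positive and negative RSS subsets, per sample."""
    overlap = set(positive_set.genes) & set(negative_set.genes)
    if overlap:
        raise ValueError(f"genes present in both RSS subsets: {sorted(overlap)}")
    log_tpm = _log_tpm(tpm)
    out = {}
    for key, sig in (("rss_positive", positive_set), ("rss_negative", negative_set)):
        genes = [g for g in sig.genes if exclude is None or g not in exclude]
        if not genes:
            raise ValueError(f"signature {sig.name!r} empty after exclusion")
        out[key] = gsva_score(log_tpm, genes, **gsva_options)
    return pd.DataFrame(out)


def compare_groups(values: pd.Series, groups: pd.Series) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of exactly two groups.

    Uses the exact null distribution when the combined sample is small
    (<= 20) and tie-free, the tie-corrected normal approximation otherwise.
    Returns the p-value and per-group medians.
    """
    values = pd.Series(values)
    groups = pd.Series(groups).loc[values.index]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly two groups, got {list(names)}")
    x = values[groups == names[0]].to_numpy(dtype=float)
    y = values[groups == names[1]].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return {
        "pvalue": float(min(res.pvalue, 1.0)),
        "method": method,
        "medians": {names[0]: float(np.median(x)), names[1]: float(np.median(y))},
    }
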