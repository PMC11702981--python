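"""Re-genotyping of reported variant sites from RNA-seq allele counts.

Tumors predicted to have reduced p53 function despite a wild-type exome
call are re-examined at their reported TP53 variant sites using RNA-seq
read counts. A site is excluded below 10 mapped reads; it is called mutant
when the mutant allele fraction reaches 0.1 AND at least five high-quality
reads (base and mapping quality > 30) support the mutant allele; otherwise
it stays wild type. Both thresholds are inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass
class GenotypeFilters:
    min_depth: int = 10
    maf_cutoff: float = 0.1
    min_hq_reads: int = 5


@dataclass
class GenotypeCall:
    status: str  # excluded | wildtype | mutant
    maf: float | None  # undefined when excluded


def maf(alt: int, depth: int) -> float:
    """Mutant allele fraction alt/depth."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0 <= alt <= depth:
        raise ValueError("alt count must lie in [0, depth]")
    return alt / depth


def maf_percent(alt: int, depth: int) -> int:
    """MAF reported as a whole percent, rounding half-up (44/98 -> 45)."""
    return int(math.floor(maf(alt, depth) * 100.0 + 0.5))


def genotype_site(
    depth: int, alt: int, hq_alt: int, filters: GenotypeFilters | None = None
) -> GenotypeCall:
    """Call one site: excluded (low depth), mutant, or wildtype."""
    filters = filters or GenotypeFilters()
    if not 0 <= hq_alt <= alt <= depth:
        raise ValueError(f"malformed counts: need 0 <= hq_alt <= alt <= depth, got {hq_alt}/{alt}/{depth}")
    if depth < filters.min_depth:
        return GenotypeCall("excluded", None)
    frac = maf(alt, depth)
    if frac >= filters.maf_cutoff and hq_alt >= filters.min_hq_reads:
        return GenotypeCall("mutant", frac)
    return GenotypeCall("wildtype", frac)


def genotype_table(records: pd.DataFrame, filters: GenotypeFilters | None = None) -> pd.DataFrame:
    """Vector form of :func:`genotype_site` over a depth/alt/hq_alt table."""
    need = {"depth", "alt", "hq_alt"}
    if not need <= set(records.columns):
        raise ValueError(f"allele-count table needs columns {sorted(need)}")
    calls = [
        genotype_site(int(r.depth), int(r.alt), int(r.hq_alt), filters)
        for r in records.itertuples()
    ]
    out = records.copy()
    out["status"] = [c.status for c in calls]
    out["maf"] = [c.maf for c in calls]
    return out


def rescue_summary(calls: pd.Series, amplified: pd.Series) -> dict[str, float]:
    """Fractions of predicted-pRF samples explained by each mechanism.

    ``calls`` maps sample id -> genotype status ('mutant' means an RNA-seq
    rescued mutation); ``amplified`` maps the same samples to an MDM2/MDM4
    amplification flag. Categories may overlap; 'either' uses the union.
    """
    calls = pd.Series(calls)
    amplified = pd.Series(amplified).astype(bool)
    if set(calls.index) != set(amplified.index):
        raise ValueError("calls and amplification flags must cover the same samples")
    amplified = amplified.loc[calls.index]
    n = len(calls)
    if n == 0:
        raise ValueError("no samples to summarize")
    rescued = calls == "mutant"
    either = rescued | amplified
    return {
        "n": n,
        "rescued_mutation": float(rescued.sum() / n),
        "amplification": float(amplified.sum() / n),
        "either": float(either.sum() / n),
        "neither": float((~either).sum() / n),
    }


def allele_counts_from_bam(bam_path, sites: pd.DataFrame, min_quality: int = 30) -> pd.DataFrame:
    """Optional adapter: pile up allele counts at 1-based VCF-style sites.

    ``sites`` needs columns chrom, pos (1-based), ref, alt. Requires pysam;
    the rest of the module operates on plain count tables so this is never
    imported implicitly.
    """
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("BAM ingestion requires pysam") from exc
    need = {"chrom", "pos", "ref", "alt"}
    if not need <= set(sites.columns):
        raise ValueError(f"site table needs columns {sorted(need)}")
    rows = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for site in sites.itertuples():
            depth = alt_n = hq_alt = 0
            for col in bam.pileup(
                site.chrom, site.pos - 1, site.pos, truncate=True, min_base_quality=0
            ):
                for read in col.pileups:
                    if read.is_del or read.is_refskip or read.query_position is None:
                        continue
                    depth += 1
                    base = read.alignment.query_sequence[read.query_position]
                    if base != site.alt:
                        continue
                    alt_n += 1
                    bq = read.alignment.query_qualities[read.query_position]
                    if bq > min_quality and read.alignment.mapping_quality > min_quality:
                        hq_alt += 1
            rows.append(
                {"chrom": site.chrom, "pos": site.pos, "depth": depth, "alt": alt_n, "hq_alt": hq_alt}
            )
    if not rows:
        warnings.warn("no sites piled up")
    return pd.DataFrame(rows)
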