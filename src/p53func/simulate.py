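"""Synthetic cohorts with the statistical structure the analysis assumes.

Three generators cover the pipeline's input space:

- :func:`generate_cohort` — multi-group expression cohorts (NT/WT/MM/TM)
  in which a latent per-sample p53 activity drives down-regulation of
  p53-activated target genes and up-regulation of p53-repressed genes,
- :func:`generate_allele_counts` — per-site RNA-seq allele-count tables
  with known genotypes, for the re-genotyping stage,
- :func:`generate_pdx` — xenograft survival ratios with a bimodal
  responder structure, for the radiotherapy-association stage.

Counts follow a negative-binomial model with gene-specific log-normal
baselines and log-normal library sizes. A single global seed fans out to
independent child streams so each generator is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort

#: per-gene transcript "length" used for the FPKM/TPM layers (kb); with a
#: constant length the two layers coincide, which is all the rank-based
#: scoring stages need.
_GENE_LENGTH_KB = 1.0


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic multi-group cohort.

    ``delta`` is the log2 effect of p53 loss on target genes: in samples
    with reduced latent activity, activated-class genes have their mean
    multiplied by ``2**-delta`` and repressed-class genes by ``2**+delta``.
    ``phi_wt_rf`` / ``phi_mm_rf`` are the fractions of WT / MM samples that
    carry the latent reduced-function state.
    """

    n_nt: int = 60
    n_wt: int = 100
    n_mm: int = 50
    n_tm: int = 60
    n_background: int = 853
    n_activated: int = 116
    n_repressed: int = 31
    delta: float = 1.5
    phi_wt_rf: float = 0.9
    phi_mm_rf: float = 0.99
    dispersion: float = 0.1
    libsize_sigma: float = 0.2
    baseline_log_mean: float = float(np.log(300.0))
    baseline_log_sd: float = 1.0
    #: ids given to the first activated-class genes, so signature scoring
    #: (the 4 DNA-repair RPS genes) has p53-responsive targets to find
    named_activated: tuple[str, ...] = ("RIF1", "F2R", "RAD51", "XRCC5")
    cohort: str = "SYN"
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_nt=self.n_nt, n_wt=self.n_wt, n_mm=self.n_mm, n_tm=self.n_tm,
            n_background=self.n_background, n_activated=self.n_activated,
            n_repressed=self.n_repressed,
        )
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_nt < 1 or self.n_tm < 1:
            raise ValueError("need at least one NT and one TM sample")
        if self.n_nt + self.n_wt + self.n_mm + self.n_tm < 4:
            raise ValueError("need at least 4 samples in total")
        if self.n_background + self.n_activated + self.n_repressed < 2:
            raise ValueError("need at least 2 genes in total")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        for name, phi in (("phi_wt_rf", self.phi_wt_rf), ("phi_mm_rf", self.phi_mm_rf)):
            if not 0.0 <= phi <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {phi}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")


@dataclass
class TruthTable:
    """Latent ground truth: per-gene class/effect and per-sample activity.

    ``genes`` has columns ``gene_class`` (activated/repressed/background) and
    ``true_log2_effect``; ``samples`` has column ``activity`` with 1 = normal
    p53 activity and 0 = reduced.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame


@dataclass
class AlleleSimConfig:
    """Parameters for simulated allele-count tables.

    ``true_maf`` is either a scalar applied to every site or a sequence of
    per-site mutant-allele fractions; ``hq_fraction`` is the probability that
    an alt-supporting read passes the base/mapping quality > 30 filter.
    """

    n_sites: int = 100
    mean_depth: float = 100.0
    true_maf: float | list[float] = 0.45
    hq_fraction: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.hq_fraction <= 1.0:
            raise ValueError("hq_fraction must lie in [0, 1]")
        mafs = np.atleast_1d(np.asarray(self.true_maf, dtype=float))
        if ((mafs < 0) | (mafs > 1)).any():
            raise ValueError("true_maf values must lie in [0, 1]")
        if mafs.size not in (1, self.n_sites):
            raise ValueError("true_maf must be scalar or of length n_sites")


@dataclass
class PDXSimConfig:
    """Parameters of the bimodal xenograft survival-ratio mixture.

    Non-responding models cluster around a ratio of ~1 (radiotherapy does
    not extend survival); responders around ``responder_mode``. The latent
    predicted-status label (pRF/pN) is correlated with responder membership
    at ``status_odds_ratio``.
    """

    n_models: int = 35
    responder_fraction: float = 0.4
    nonresponder_mode: float = 1.0
    responder_mode: float = 2.0
    nonresponder_spread: float = 0.1
    responder_spread: float = 0.1
    status_odds_ratio: float = 25.0
    nonresponder_prf_rate: float = 0.2
    placebo_days: tuple[float, float] = (30.0, 60.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.nonresponder_mode <= 0 or self.responder_mode <= 0:
            raise ValueError("both ratio modes must be > 0")
        if self.nonresponder_spread < 0 or self.responder_spread < 0:
            raise ValueError("spreads must be >= 0")
        if self.status_odds_ratio <= 0:
            raise ValueError("status_odds_ratio must be > 0")
        if not 0.0 < self.nonresponder_prf_rate < 1.0:
            raise ValueError("nonresponder_prf_rate must lie in (0, 1)")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionCohort, ExpressionCohort, ExpressionCohort, TruthTable]:
    """Simulate counts / log2fpkm / tpm layers plus the latent truth table.

    Counts are negative binomial around ``baseline * libsize * effect``;
    the FPKM/TPM layers are per-sample normalizations of the same sampled
    counts (constant 1-kb gene length), so within-group biological and
    sampling variability propagates into every layer.
    """
    config.validate()
    rng_genes, rng_act, rng_counts = _child_rngs(config.seed, 3)

    gene_classes = (
        ["activated"] * config.n_activated
        + ["repressed"] * config.n_repressed
        + ["background"] * config.n_background
    )
    named = list(config.named_activated[: config.n_activated])
    genes = (
        named
        + [f"ACT{i + 1:04d}" for i in range(len(named), config.n_activated)]
        + [f"REP{i + 1:04d}" for i in range(config.n_repressed)]
        + [f"BG{i + 1:04d}" for i in range(config.n_background)]
    )
    n_genes = len(genes)

    groups = (
        ["NT"] * config.n_nt + ["WT"] * config.n_wt
        + ["MM"] * config.n_mm + ["TM"] * config.n_tm
    )
    sample_ids = []
    counters = {g: 0 for g in ("NT", "WT", "MM", "TM")}
    for g in groups:
        counters[g] += 1
        sample_ids.append(f"{g}{counters[g]:03d}")
    n_samples = len(sample_ids)

    # latent activity: NT always normal, TM always reduced, tumors mixed
    activity = np.ones(n_samples, dtype=int)
    for i, g in enumerate(groups):
        if g == "TM":
            activity[i] = 0
        elif g == "WT":
            activity[i] = 0 if rng_act.random() < config.phi_wt_rf else 1
        elif g == "MM":
            activity[i] = 0 if rng_act.random() < config.phi_mm_rf else 1

    baseline = rng_genes.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    libsize = rng_counts.lognormal(0.0, config.libsize_sigma, n_samples)

    effect = np.zeros(n_genes)
    effect[: config.n_activated] = -config.delta
    effect[config.n_activated: config.n_activated + config.n_repressed] = config.delta

    log2_shift = np.outer(effect, 1 - activity)  # applies only where activity == 0
    mu = baseline[:, None] * libsize[None, :] * np.exp2(log2_shift)

    r = 1.0 / config.dispersion
    p = r / (r + mu)
    counts = rng_counts.negative_binomial(r, p).astype(np.int64)

    col_tot = counts.sum(axis=0).astype(float)
    col_tot[col_tot == 0] = 1.0
    fpkm = counts / (col_tot[None, :] * _GENE_LENGTH_KB) * 1.0e6

    sheet = pd.DataFrame({"group": groups, "cohort": config.cohort}, index=pd.Index(sample_ids, name="sample"))
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    fpkm_df = pd.DataFrame(fpkm, index=genes, columns=sample_ids)

    truth = TruthTable(
        genes=pd.DataFrame(
            {"gene_class": gene_classes, "true_log2_effect": effect},
            index=pd.Index(genes, name="gene"),
        ),
        samples=pd.DataFrame(
            {"group": groups, "activity": activity},
            index=pd.Index(sample_ids, name="sample"),
        ),
    )
    return (
        ExpressionCohort(counts_df, "counts", sheet),
        ExpressionCohort(np.log2(fpkm_df + 1.0), "log2fpkm", sheet),
        ExpressionCohort(fpkm_df.copy(), "tpm", sheet),
        truth,
    )


def generate_allele_counts(config: AlleleSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-site allele-count records plus the truth genotypes.

    Depth is Poisson around ``mean_depth``; alt reads are binomial at the
    site's true MAF; high-quality alt reads are a binomial thinning of the
    alt reads at ``hq_fraction``.
    """
    config.validate()
    (rng,) = _child_rngs(config.seed, 1)
    mafs = np.broadcast_to(
        np.atleast_1d(np.asarray(config.true_maf, dtype=float)), (config.n_sites,)
    )
    depth = rng.poisson(config.mean_depth, config.n_sites)
    alt = rng.binomial(depth, mafs)
    hq_alt = rng.binomial(alt, config.hq_fraction)
    sites = [f"site{i + 1:04d}" for i in range(config.n_sites)]
    table = pd.DataFrame(
        {
            "sample": [f"S{i + 1:04d}" for i in range(config.n_sites)],
            "site": sites,
            "depth": depth,
            "alt": alt,
            "hq_alt": hq_alt,
        }
    )
    truth = pd.DataFrame(
        {
            "site": sites,
            "true_maf": mafs,
            "true_genotype": np.where(mafs > 0, "mutant", "wildtype"),
        }
    )
    return table, truth


def generate_pdx(config: PDXSimConfig) -> pd.DataFrame:
    """Simulate xenograft survival records with truth labels.

    Returns one row per model with placebo / radiotherapy median survival
    (days), the survival ratio, the true responder flag (mixture-mode
    membership) and a correlated true pRF/pN status label.
    """
    config.validate()
    (rng,) = _child_rngs(config.seed, 1)
    responder = rng.random(config.n_models) < config.responder_fraction
    mode = np.where(responder, config.responder_mode, config.nonresponder_mode)
    spread = np.where(responder, config.responder_spread, config.nonresponder_spread)
    ratio = np.maximum(rng.normal(mode, spread), 0.05)

    # pRF probability by responder status, from the configured odds ratio
    p0 = config.nonresponder_prf_rate
    odds1 = config.status_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    p_prf = np.where(responder, p1, p0)
    status = np.where(rng.random(config.n_models) < p_prf, "pRF", "pN")

    lo, hi = config.placebo_days
    placebo = rng.uniform(lo, hi, config.n_models)
    rt = placebo * ratio
    return pd.DataFrame(
        {
            "model": [f"PDX{i + 1:03d}" for i in range(config.n_models)],
            "rt_median": rt,
            "placebo_median": placebo,
            "ratio": ratio,
            "true_responder": responder,
            "true_status": status,
        }
    )
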