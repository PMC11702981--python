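"""End-to-end orchestration: gene selection -> CES -> classifier -> extras.

``run_pipeline`` executes the analytic workflow on a loaded cohort:
candidate filtering, NT-vs-TM differential expression, DR/UR selection, the
seven composite scores, hold-out validation, a production model fitted on
all NT and TM samples, pN/pRF prediction for WT/MM tumors, and the optional
signature / re-genotyping / PDX stages when their inputs are present. Every
artifact is written under the output directory and listed, with a checksum,
in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ces import CESModel
from .classifier import cluster_predict, holdout_validate, predict, train
from .cohort import ExpressionCohort
from .feature_selection import (
    differential_expression,
    filter_expressed,
    select_gene_sets,
    validate_candidates,
)
from .io import read_expression, read_gmt, read_sample_sheet, write_gmt
from .rt_response import build_pdx_table, fisher_association
from .signatures import load_rss_sets, rps_score, rss_scores
from .simulate import AlleleSimConfig, CohortConfig, PDXSimConfig, generate_allele_counts, generate_cohort, generate_pdx
from .variant_rescue import GenotypeFilters, genotype_table

log = logging.getLogger("p53func")


@dataclass
class RunConfig:
    """Paths, thresholds and the seed of one pipeline run."""

    counts: str | None = None
    log2fpkm: str | None = None
    tpm: str | None = None
    sample_sheet: str | None = None
    candidates: str | None = None
    rss_gmt: str | None = None
    allele_counts: str | None = None
    pdx_table: str | None = None
    outdir: str = "p53func_run"
    cohort: str = "cohort"
    adj_p_max: float = 0.05
    min_abs_fc: float = 2.0
    tpm_median_min: float = 1.0
    apply_tpm_filter: bool = False
    ssgsea_alpha: float = 0.25
    gsva_kcdf: str = "gaussian"
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    split: float = 0.75
    repeats: int = 10
    min_depth: int = 10
    maf_cutoff: float = 0.1
    min_hq_reads: int = 5
    rt_cutoff: float | None = None
    cluster_fallback: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.split < 1:
            raise ValueError("split must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.adj_p_max <= 0 or self.min_abs_fc <= 0:
            raise ValueError("DE thresholds must be positive")
        for name in ("counts", "log2fpkm", "tpm", "sample_sheet", "candidates",
                     "rss_gmt", "allele_counts", "pdx_table"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.c_grid, list):
            cfg.c_grid = tuple(cfg.c_grid)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Structured per-stage logging: name, shapes, elapsed time."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            log.error("stage=%s status=failed elapsed=%.2fs error=%s", self.name, dt, exc)
            return False
        log.info("stage=%s status=ok elapsed=%.2fs", self.name, dt)
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the artifact manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save_tsv(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        artifacts[name] = path

    with _Stage("load"):
        if not (config.counts and config.log2fpkm and config.sample_sheet and config.candidates):
            raise ValueError("counts, log2fpkm, sample_sheet and candidates paths are required")
        sheet = read_sample_sheet(config.sample_sheet)
        counts = read_expression(config.counts, "counts", sheet)
        log2fpkm = read_expression(config.log2fpkm, "log2fpkm", sheet)
        tpm = read_expression(config.tpm, "tpm", sheet) if config.tpm else None
        candidates = validate_candidates(pd.read_csv(config.candidates, sep="\t"))

    nt = counts.group_samples("NT")
    tm = counts.group_samples("TM")
    wt = counts.group_samples("WT")
    mm = counts.group_samples("MM")
    if (len(nt) < 2 or len(tm) < 2) and not config.cluster_fallback:
        raise ValueError(
            "classifier stage needs >= 2 NT and >= 2 TM samples; "
            "enable cluster_fallback for reference-free prediction"
        )

    with _Stage("filter_expressed"):
        if config.apply_tpm_filter:
            if tpm is None:
                raise ValueError("tpm layer required for the median-TPM candidate filter")
            candidates = filter_expressed(tpm, candidates, config.tpm_median_min)
        save_tsv(candidates, "candidates_used.tsv", index=False)

    with _Stage("differential_expression"):
        de = differential_expression(counts, nt, tm, genes=list(candidates["gene"]))
        save_tsv(de, "de_results.tsv")
        pair = select_gene_sets(de, config.adj_p_max, config.min_abs_fc, cohort=config.cohort)
        write_gmt(pair.as_gmt(), outdir / "gene_sets.gmt")
        artifacts["gene_sets.gmt"] = outdir / "gene_sets.gmt"

    with _Stage("ces"):
        ces_model = CESModel(alpha=config.ssgsea_alpha, kcdf=config.gsva_kcdf).fit(
            log2fpkm.matrix[nt + tm], pair, nt, tm
        )
        ces_all = ces_model.transform(log2fpkm.matrix)
        save_tsv(ces_all, "ces_table.tsv", index_label="sample")

    with _Stage("validate"):
        report = holdout_validate(
            counts, log2fpkm, candidates,
            split=config.split, repeats=config.repeats, seed=config.seed,
            C_grid=config.c_grid, adj_p_max=config.adj_p_max, min_abs_fc=config.min_abs_fc,
        )
        save_tsv(report.per_repeat, "validation_report.tsv")
        (outdir / "validation_summary.json").write_text(
            json.dumps({"means": report.means, "gene_sets": report.gene_sets}, indent=2)
        )
        artifacts["validation_summary.json"] = outdir / "validation_summary.json"

    with _Stage("train"):
        labels = pd.Series([0] * len(nt) + [1] * len(tm), index=nt + tm)
        model = train(ces_all.loc[nt + tm], labels, C_grid=config.c_grid, seed=config.seed)
        model.to_json(outdir / "model.json")
        artifacts["model.json"] = outdir / "model.json"

    with _Stage("predict"):
        targets = wt + mm
        predictions = predict(model, ces_all.loc[targets], sheet["group"])
        save_tsv(predictions, "predictions.tsv", index_label="sample")
        if config.cluster_fallback:
            cluster = cluster_predict(ces_all, nt, tm)
            save_tsv(cluster, "cluster_predictions.tsv", index_label="sample")

    with _Stage("signatures"):
        if tpm is not None:
            from .signatures import RPS_GENES

            if set(RPS_GENES) & set(tpm.genes):
                sig = pd.DataFrame({"rps": rps_score(tpm)})
                if config.rss_gmt:
                    pos, neg = load_rss_sets(read_gmt(config.rss_gmt))
                    sig = sig.join(rss_scores(tpm, pos, neg))
                save_tsv(sig, "signature_scores.tsv", index_label="sample")
            else:
                log.info("stage=signatures skipped: no RPS gene in the matrix")

    with _Stage("rescue"):
        if config.allele_counts:
            records = pd.read_csv(config.allele_counts, sep="\t")
            calls = genotype_table(
                records,
                GenotypeFilters(config.min_depth, config.maf_cutoff, config.min_hq_reads),
            )
            save_tsv(calls, "genotype_calls.tsv", index=False)

    with _Stage("rt_response"):
        if config.pdx_table:
            pdx = pd.read_csv(config.pdx_table, sep="\t")
            pdx, cutoff = build_pdx_table(pdx, config.rt_cutoff)
            save_tsv(pdx, "pdx_response.tsv", index=False)
            if "predicted_status" in pdx.columns:
                assoc = fisher_association(pdx["responder"], pdx["predicted_status"])
                assoc["cutoff"] = cutoff
                (outdir / "rt_association.json").write_text(json.dumps(assoc, indent=2))
                artifacts["rt_association.json"] = outdir / "rt_association.json"

    with _Stage("manifest"):
        cfg_text = json.dumps(asdict(config), sort_keys=True, default=str)
        manifest = {
            "package": "p53func",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "config": json.loads(cfg_text),
            "files": {name: _sha256(path) for name, path in sorted(artifacts.items())},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def verify_manifest(outdir) -> bool:
    """Recompute artifact checksums and compare with the stored manifest."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    return all(_sha256(outdir / name) == digest for name, digest in manifest["files"].items())


def write_simulated_inputs(outdir, cohort_config: CohortConfig | None = None,
                           allele_config: AlleleSimConfig | None = None,
                           pdx_config: PDXSimConfig | None = None, seed: int = 0) -> RunConfig:
    """Simulate a full input set on disk and return a ready RunConfig."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_config = cohort_config or CohortConfig(seed=seed)
    allele_config = allele_config or AlleleSimConfig(seed=seed + 1)
    pdx_config = pdx_config or PDXSimConfig(seed=seed + 2)

    counts, log2fpkm, tpm, truth = generate_cohort(cohort_config)
    for cohort_obj, name in ((counts, "counts"), (log2fpkm, "log2fpkm"), (tpm, "tpm")):
        cohort_obj.matrix.to_csv(outdir / f"{name}.tsv", sep="\t", index_label="gene")
    counts.samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    truth.samples.to_csv(outdir / "truth_samples.tsv", sep="\t")
    truth.genes.reset_index().rename(columns={"index": "gene"})[["gene", "gene_class"]].query(
        "gene_class != 'background'"
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    allele, allele_truth = generate_allele_counts(allele_config)
    allele.to_csv(outdir / "allele_counts.tsv", sep="\t", index=False)
    allele_truth.to_csv(outdir / "allele_truth.tsv", sep="\t", index=False)

    pdx = generate_pdx(pdx_config)
    pdx_io = pdx.rename(columns={"true_status": "predicted_status"})
    pdx_io[["model", "rt_median", "placebo_median", "predicted_status"]].to_csv(
        outdir / "pdx.tsv", sep="\t", index=False
    )
    pdx.to_csv(outdir / "pdx_truth.tsv", sep="\t", index=False)

    (outdir / "cohort_config.yaml").write_text(yaml.safe_dump(asdict(cohort_config)))
    return RunConfig(
        counts=str(outdir / "counts.tsv"),
        log2fpkm=str(outdir / "log2fpkm.tsv"),
        tpm=str(outdir / "tpm.tsv"),
        sample_sheet=str(outdir / "samples.tsv"),
        candidates=str(outdir / "candidates.tsv"),
        allele_counts=str(outdir / "allele_counts.tsv"),
        pdx_table=str(outdir / "pdx.tsv"),
        outdir=str(outdir / "run"),
        cohort=cohort_config.cohort,
        seed=seed,
    )


def demo(outdir, seed: int = 7, repeats: int = 10,
         cohort_config: CohortConfig | None = None) -> dict:
    """Full pipeline on freshly simulated inputs; returns the manifest."""
    if cohort_config is None:
        cohort_config = CohortConfig(seed=seed)
    cfg = write_simulated_inputs(outdir, cohort_config=cohort_config, seed=seed)
    cfg.repeats = repeats
    cfg.cluster_fallback = True
    return run_pipeline(cfg)
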