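import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from p53func.ces import CESModel
from p53func.feature_selection import differential_expression, select_gene_sets
from p53func.simulate import CohortConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def candidates_from_truth(truth) -> pd.DataFrame:
    """Candidate list = the true activated/repressed genes of a cohort."""
    df = truth.genes.reset_index()
    return df[df["gene_class"] != "background"][["gene", "gene_class"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default study conditions (60 NT / 60 TM, delta 1.5)."""
    counts, log2fpkm, tpm, truth = generate_cohort(CohortConfig(seed=1))
    return {"counts": counts, "log2fpkm": log2fpkm, "tpm": tpm, "truth": truth}


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for fast unit tests of downstream stages."""
    cfg = CohortConfig(
        n_nt=20, n_wt=20, n_mm=10, n_tm=20,
        n_background=150, n_activated=30, n_repressed=10, seed=5,
    )
    counts, log2fpkm, tpm, truth = generate_cohort(cfg)
    return {"config": cfg, "counts": counts, "log2fpkm": log2fpkm, "tpm": tpm, "truth": truth}


@pytest.fixture(scope="session")
def small_pair(small_cohort):
    counts = small_cohort["counts"]
    de = differential_expression(
        counts,
        counts.group_samples("NT"),
        counts.group_samples("TM"),
        genes=list(candidates_from_truth(small_cohort["truth"])["gene"]),
    )
    return select_gene_sets(de, cohort="SMALL")


@pytest.fixture(scope="session")
def small_ces(small_cohort, small_pair):
    """Fitted CES model (on NT+TM) and the full small-cohort CES table."""
    counts = small_cohort["counts"]
    nt, tm = counts.group_samples("NT"), counts.group_samples("TM")
    model = CESModel().fit(small_cohort["log2fpkm"].matrix[nt + tm], small_pair, nt, tm)
    return {"model": model, "table": model.transform(small_cohort["log2fpkm"].matrix)}
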