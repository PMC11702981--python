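"""Packaged desk-scale fixtures: worked examples, oracle matrices, presets.

Every fixture is a small plain-text payload bundled with the package plus
its expected outputs, so the scoring and genotyping arithmetic can be
checked without any external data. The candidate-list template documents
the expected schema only; real candidate gene lists come from the
literature and are supplied by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .simulate import CohortConfig


@dataclass
class Fixture:
    """A named payload with its expected outputs and a provenance note."""

    name: str
    description: str
    provenance: str  # worked-example | oracle | preset | template
    payload: object
    expected: dict = field(default_factory=dict)


def _data_path(name: str):
    return resources.files("p53func.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t", index_col=0)


def rps_gmt_path():
    """Filesystem path of the packaged 4-gene RPS signature GMT."""
    return _data_path("rps.gmt")


def list_fixtures() -> dict[str, Fixture]:
    """Catalog of all packaged fixtures, loaded and ready to use."""
    from .io import read_gmt

    with resources.as_file(rps_gmt_path()) as path:
        rps_sets = read_gmt(path)
    with resources.as_file(_data_path("cohort_default.yaml")) as path:
        preset = yaml.safe_load(path.read_text())

    catalog = {
        "maf_worked_examples": Fixture(
            name="maf_worked_examples",
            description=(
                "mutant-allele-fraction reporting convention: alt/depth rounded "
                "half-up to whole percent"
            ),
            provenance="worked-example",
            payload=pd.DataFrame({"alt": [44, 35, 0], "depth": [98, 100, 50]}),
            expected={"percent": [45, 35, 0]},
        ),
        "rps_signature": Fixture(
            name="rps_signature",
            description="4-gene DNA-repair chemosensitivity signature (RPS)",
            provenance="worked-example",
            payload=rps_sets,
            expected={"n_genes": 4, "genes": rps_sets["RPS"]},
        ),
        "ssgsea_oracle_matrix": Fixture(
            name="ssgsea_oracle_matrix",
            description="6-gene x 2-sample matrix for brute-force running-sum checks",
            provenance="oracle",
            payload=_read_tsv("ssgsea_oracle.tsv"),
            expected={"geneset": ["g2", "g4"]},
        ),
        "gsva_oracle_matrix": Fixture(
            name="gsva_oracle_matrix",
            description="8-gene x 4-sample matrix for step-by-step GSVA (ecdf) checks",
            provenance="oracle",
            payload=_read_tsv("gsva_oracle.tsv"),
            expected={"geneset": ["g1", "g5", "g7"]},
        ),
        "cohort_default_config": Fixture(
            name="cohort_default_config",
            description="default synthetic-cohort study conditions",
            provenance="preset",
            payload=CohortConfig(**preset),
            expected={"n_candidates": preset["n_activated"] + preset["n_repressed"]},
        ),
        "candidate_template": Fixture(
            name="candidate_template",
            description="schema template for user-supplied candidate gene lists",
            provenance="template",
            payload=_read_tsv("candidate_template.tsv").reset_index(),
            expected={"columns": ["gene", "gene_class"]},
        ),
    }
    return catalog
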