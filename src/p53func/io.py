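"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices and sample sheets travel as TSV/CSV (gzip accepted
transparently), gene sets as GMT, models and manifests as JSON.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .cohort import ExpressionCohort


def _sep_for(path: Path) -> str:
    name = path.name
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_expression(path, layer: str, samples: pd.DataFrame | None = None) -> ExpressionCohort:
    """Read a gene-by-sample matrix (gene id in the first column).

    Duplicate gene ids and non-numeric cells are rejected; gzip compression
    is detected from the file name.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in expression matrix ({exc})") from exc
    return ExpressionCohort(df, layer, samples)


def write_expression(cohort: ExpressionCohort, path) -> None:
    path = Path(path)
    cohort.matrix.to_csv(path, sep=_sep_for(path), index_label="gene")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns ``sample``, ``group``[, ``cohort``]."""
    path = Path(path)
    sheet = pd.read_csv(path, sep=_sep_for(path))
    if "sample" not in sheet.columns or "group" not in sheet.columns:
        raise ValueError(f"{path}: sample sheet needs 'sample' and 'group' columns")
    return sheet.set_index("sample")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(Path(path), sep="\t", index_label="sample")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, tab-separated members).

    Strict dialect: every line must have a name, a description field and at
    least one member. Repeated members are deduplicated with a warning;
    duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 member"
            )
        name, _desc, *members = parts
        members = [m for m in members if m != ""]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in sets:
            raise ValueError(f"{path}: duplicate gene-set name {name!r}")
        unique = list(dict.fromkeys(members))
        if len(unique) < len(members):
            warnings.warn(f"{path}: duplicated members in set {name!r} were removed")
        sets[name] = unique
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "p53func") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
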