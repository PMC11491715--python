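"""Gene-disease association (GDA) filtering and heatmap-matrix export.

DisGeNET-style records carry a gene symbol, a disease name, a disease
type and an association score in [0, 1].  The analysis keeps records
with score strictly above 0.3 and drops whole disease types (by default
``phenotype``), then pivots the survivors into a gene x disease score
matrix for heatmap rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GDARecord",
    "DiseaseMatrix",
    "read_gda",
    "filter_gda",
    "pivot_matrix",
    "DEFAULT_MIN_SCORE",
    "DEFAULT_EXCLUDED_TYPES",
]

DEFAULT_MIN_SCORE = 0.3
DEFAULT_EXCLUDED_TYPES = frozenset({"phenotype"})


@dataclass(frozen=True)
class GDARecord:
    gene: str
    disease_name: str
    disease_type: str
    score: float

    def __post_init__(self) -> None:
        if not self.gene or not self.disease_name:
            raise ValueError("gene and disease_name must be non-empty")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(
                f"GDA score {self.score} outside [0, 1] "
                f"({self.gene} / {self.disease_name})"
            )


@dataclass
class DiseaseMatrix:
    """Gene x disease score matrix; absent associations are 0."""

    genes: list[str]
    diseases: list[str]
    values: pd.DataFrame  # index = genes, columns = diseases

    def to_frame(self) -> pd.DataFrame:
        return self.values


def read_gda(
    path,
    gene_col: str = "gene",
    disease_col: str = "disease_name",
    type_col: str = "disease_type",
    score_col: str = "score",
) -> list[GDARecord]:
    """Read a GDA table from TSV with configurable column names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (gene_col, disease_col, type_col, score_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        GDARecord(row[gene_col], row[disease_col], row[type_col],
                  float(row[score_col]))
        for _, row in df.iterrows()
    ]


def filter_gda(
    records: Iterable[GDARecord],
    min_score_exclusive: float = DEFAULT_MIN_SCORE,
    excluded_types: Iterable[str] = DEFAULT_EXCLUDED_TYPES,
) -> list[GDARecord]:
    """Keep records with score strictly above the cutoff and a disease
    type outside the excluded set (type comparison case-insensitive)."""
    excl = {t.casefold() for t in excluded_types}
    return [
        r for r in records
        if r.score > min_score_exclusive and r.disease_type.casefold() not in excl
    ]


def pivot_matrix(records: Sequence[GDARecord]) -> DiseaseMatrix:
    """Pivot filtered records into a gene x disease matrix.

    Genes and diseases are sorted lexicographically; duplicate
    (gene, disease) records collapse keeping the maximum score; empty
    cells hold 0.
    """
    if not records:
        return DiseaseMatrix([], [], pd.DataFrame())
    df = pd.DataFrame(
        {"gene": [r.gene for r in records],
         "disease": [r.disease_name for r in records],
         "score": [r.score for r in records]}
    )
    wide = (
        df.pivot_table(index="gene", columns="disease", values="score",
                       aggfunc="max", fill_value=0.0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    wide.index.name = None
    wide.columns.name = None
    return DiseaseMatrix(list(wide.index), list(wide.columns), wide)
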