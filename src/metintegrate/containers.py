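"""Core in-memory containers shared across the pipeline.

Expression values are always log2-scale, genes as rows and samples as
columns.  Gene and sample identity is by exact (case-sensitive) string;
no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

#: canonical tissue class labels
CLASS_NORMAL = "normal"
CLASS_PRIMARY = "primary"
CLASS_METASTASIS = "metastasis"


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix with per-sample class and cohort labels.

    Parameters
    ----------
    values
        genes x samples DataFrame of finite floats; the index holds gene
        ids, the columns sample ids, both unique.
    sample_class
        per-sample label, e.g. ``normal`` / ``primary`` / ``metastasis``
        for tissues, or an origin label for cell lines.
    cohort
        per-sample source tag (which dataset a sample came from).
    """

    values: pd.DataFrame
    sample_class: pd.Series
    cohort: pd.Series = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InvalidInputError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise InvalidInputError(f"duplicate sample id: {dup!r}")
        if self.cohort is None:
            self.cohort = pd.Series("cohort1", index=self.values.columns)
        self.sample_class = pd.Series(self.sample_class).reindex(self.values.columns)
        self.cohort = pd.Series(self.cohort).reindex(self.values.columns)
        if self.sample_class.isna().any():
            missing = self.sample_class.index[self.sample_class.isna()][0]
            raise InvalidInputError(f"sample {missing!r} has no class label")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise InvalidInputError("expression values must be finite (no NaN/Inf)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_samples(self, label: str) -> list[str]:
        """Sample ids carrying the given class label."""
        return list(self.sample_class.index[self.sample_class == label])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise InvalidInputError(f"unknown sample ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            values=self.values[ids].copy(),
            sample_class=self.sample_class[ids].copy(),
            cohort=self.cohort[ids].copy(),
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.sample_class.equals(other.sample_class)
            and self.cohort.equals(other.cohort)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT-compatible).

    ``sets`` maps set id -> (description, member tuple).  Members are
    deduplicated preserving first occurrence and never empty.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def add(self, set_id: str, description: str, members) -> None:
        seen: dict[str, None] = {}
        for m in members:
            seen.setdefault(m, None)
        if not seen:
            raise InvalidInputError(f"gene set {set_id!r} has no members")
        self.sets[set_id] = (description, tuple(seen))

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __iter__(self):
        return iter(self.sets)


@dataclass
class DependencyMatrix:
    """Per-gene, per-cell-line knockout dependency probabilities.

    Values lie in [0, 1]: 1 means the line depends on the gene for
    viability (essential), 0 means knockout has no effect.  NaN cells are
    allowed (a line may not have been screened for a gene) and are
    excluded from aggregation.
    """

    values: pd.DataFrame  # genes x cell lines
    origin: pd.Series  # per-line label: primary / metastasis
    lineage: pd.Series  # per-line tissue tag

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise InvalidInputError("duplicate gene or cell-line ids")
        self.origin = pd.Series(self.origin).reindex(self.values.columns)
        self.lineage = pd.Series(self.lineage).reindex(self.values.columns)
        if self.origin.isna().any():
            raise InvalidInputError("every cell line needs an origin label")
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | ((arr >= 0.0) & (arr <= 1.0))
        if not ok.all():
            raise InvalidInputError("dependency values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cellline_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SimulationTruth:
    """Ground truth recorded by the synthetic generators.

    Every id listed here exists in the emitted matrices, so recovery of
    planted structure can be scored exactly.
    """

    planted_de_genes: list[tuple[str, float]] = field(default_factory=list)
    planted_enriched_sets: list[tuple[str, str]] = field(default_factory=list)
    planted_essential_genes: list[str] = field(default_factory=list)
    planted_response_signature: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def de_gene_ids(self) -> list[str]:
        return [g for g, _ in self.planted_de_genes]


@dataclass
class AnnotationTables:
    """Surfaceome / secretome / drug-target annotation tables.

    surfaceome : DataFrame[gene, uniprot_id, category]   category in {1,2,3}
    secretome  : DataFrame[gene, metaz_tag, hpa_location]
    drug_targets : DataFrame[gene, inhibitor, approved]  (long format,
        one row per gene-inhibitor pair, input order preserved)
    """

    surfaceome: pd.DataFrame
    secretome: pd.DataFrame
    drug_targets: pd.DataFrame


@dataclass
class ResponseStrata:
    """Drug-response stratification of cell lines.

    ``responsive`` (group A), ``non_responsive`` (group B) and
    ``excluded`` partition the lines carrying response data.
    """

    responsive: list[str]
    non_responsive: list[str]
    excluded: list[str]
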