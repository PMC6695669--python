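"""Core containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file or container contents."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (already log-scale, normalized) expression.

    Values are unitless log-intensities; rows are genes, columns samples.
    Identifiers must be unique and all values finite — missing values are a
    hard error rather than silently imputed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = pd.Index(self.sample_ids)[pd.Index(self.sample_ids).duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite or missing values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


@dataclass
class SampleGroups:
    """Case/control label per sample."""

    labels: dict[str, str]

    CASE = "case"
    CONTROL = "control"

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {self.CASE, self.CONTROL}
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}; expected case/control")

    def validate_against(self, matrix: ExpressionMatrix, require_both: bool = True) -> None:
        unlabeled = [s for s in matrix.sample_ids if s not in self.labels]
        if unlabeled:
            raise FormatError(f"samples without group label: {unlabeled[:5]}")
        if require_both:
            groups = {self.labels[s] for s in matrix.sample_ids}
            if groups != {self.CASE, self.CONTROL}:
                raise FormatError("differential expression requires both case and control samples")

    def mask(self, matrix: ExpressionMatrix, group: str) -> np.ndarray:
        return np.array([self.labels[s] == group for s in matrix.sample_ids])


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT-style annotation)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty after deduplication")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)
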