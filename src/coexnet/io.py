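"""Readers and writers for the pipeline's tabular artifacts.

All outputs are TSV with '.' as the decimal separator regardless of
locale; round trips are lossless at 12 decimals.  Expression input is
assumed already log-transformed and normalized — this package refuses to
guess a normalization for raw data — and missing values are an error, not
imputed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, FormatError, GeneSetCollection, SampleGroups
from .inference import ConsensusNetwork, MethodScoreMatrix

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples table (first column gene ids, header samples)."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"missing value in gene {bad!r}; imputation is not performed")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as err:
        raise FormatError(f"non-numeric expression value: {err}") from err
    return ExpressionMatrix(list(map(str, df.index)), list(map(str, df.columns)), values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    # %.17g: shortest representation that round-trips IEEE doubles bit-exactly
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g", index_label="gene_id")


def read_sample_groups(path: str | Path) -> SampleGroups:
    """Two-column TSV: sample_id, group (case/control)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise FormatError("sample-group table needs columns: sample_id, group")
    return SampleGroups(dict(zip(df["sample_id"], df["group"])))


def write_sample_groups(groups: SampleGroups, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.labels), "group": list(groups.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read GMT (name TAB description TAB member...); members deduplicated."""
    sets: dict[str, tuple[str, list[str]]] = {}
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()]
    if not any(ln.strip() for ln in lines):
        logger.warning("GMT file %s is empty", path)
        return GeneSetCollection({})
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3")
        name, desc, *members = fields
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        seen: set[str] = set()
        deduped = [m for m in members if m and not (m in seen or seen.add(m))]
        sets[name] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_edge_table(
    network: ConsensusNetwork,
    path: str | Path,
    method_scores: dict[str, MethodScoreMatrix] | None = None,
) -> None:
    """Write one row per unordered gene pair: per-method scores + consensus.

    Pairs are emitted with gene_a < gene_b lexicographically and sorted by
    descending consensus, ties broken by (gene_a, gene_b).
    """
    genes = network.gene_ids
    p = len(genes)
    iu, ju = np.triu_indices(p, k=1)
    rows = []
    for i, j in zip(iu, ju):
        a, b = sorted((genes[i], genes[j]))
        row = {"gene_a": a, "gene_b": b}
        if method_scores:
            for m, sm in method_scores.items():
                row[m] = sm.scores[i, j]
        row["consensus"] = network.consensus[i, j]
        row["n_methods"] = int(network.n_contributing[i, j])
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["consensus", "gene_a", "gene_b"], ascending=[False, True, True])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
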