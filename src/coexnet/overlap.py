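"""Curated-list harmonization and intersection.

Published GWAS summary tables and miRNA-study tables print gene loci and
miRNA names in heterogeneous shorthand: fused locus pairs ("GBA-SYT11"),
en-dash ranges, annotation words, continuation shorthand ("miR-9, -29a,
-29b"), and occasional typography that must be preserved verbatim so that
counts remain auditable.  This module turns such raw printed strings into
normalized tokens under explicit, data-driven rules and intersects the
resulting lists.

Normalization contracts:

* gene loci — uppercase symbols; split on "/", ",", en-dash and whitespace;
  split on hyphen-minus unless a packaged exception file protects the
  hyphen (family prefixes such as HLA-, antisense "-AS1" suffixes, listed
  official hyphenated symbols); annotation words ("region") are dropped.
* miRNAs — lowercase; the "hsa-" species prefix is stripped; continuation
  shorthand is expanded against the most recent family prefix ("miR-9,
  -29a" -> mir-9, mir-29a); arm suffixes (-5p/-3p) are kept exactly as
  printed and never collapsed; typography is never repaired, so e.g.
  "miR-27a3p" and "miR-27a-3p" remain distinct tokens.

Matching is exact on normalized tokens.  Every token retains provenance
(source table/citation and the raw printed string it came from).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NamedEntityList",
    "OverlapResult",
    "TokenizationError",
    "tokenize_locus",
    "normalize_mirna_cell",
    "intersect_lists",
    "intersect_tam_lists",
    "load_gwas_list",
    "load_mirna_list",
    "load_de_entrez",
]


class TokenizationError(ValueError):
    """Raised when a raw printed string cannot be reduced to any token."""


def _data_text(name: str) -> str:
    return resources.files("coexnet.data").joinpath(name).read_text(encoding="utf-8")


def _load_exceptions() -> dict:
    return json.loads(_data_text("gene_token_exceptions.json"))


@dataclass(frozen=True)
class Entry:
    """One normalized token with its provenance."""

    token: str
    raw: str
    source: str


@dataclass
class NamedEntityList:
    """A curated list of gene loci or miRNAs with per-token provenance."""

    kind: str  # "gene_locus" | "mirna"
    entries: list[Entry] = field(default_factory=list)

    def tokens(self) -> set[str]:
        return {e.token for e in self.entries}

    def provenance(self, token: str) -> list[Entry]:
        return [e for e in self.entries if e.token == token]

    def __len__(self) -> int:  # number of distinct tokens
        return len(self.tokens())


@dataclass
class OverlapResult:
    """Sorted intersection of two curated lists, with dual provenance."""

    kind: str
    intersection: list[str]
    provenance_a: dict[str, list[Entry]]
    provenance_b: dict[str, list[Entry]]

    @property
    def size(self) -> int:
        return len(self.intersection)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "size": self.size,
            "intersection": list(self.intersection),
            "provenance": {
                t: {
                    "a": [e.source for e in self.provenance_a[t]],
                    "b": [e.source for e in self.provenance_b[t]],
                }
                for t in self.intersection
            },
        }


# ---------------------------------------------------------------------------
# gene locus tokenization

_ANNOTATION_WORDS = {"REGION", "LOCUS", "GENE"}
_EN_DASH = "–"


def tokenize_locus(raw: str, exceptions: dict | None = None) -> list[str]:
    """Split a printed locus string into individual gene symbols.

    Separators are "/", ",", the en-dash and whitespace.  A hyphen-minus
    separates fused symbols ("GBA-SYT11") unless the exception rules keep
    it: protected family prefixes (HLA-DRB5), protected suffix patterns
    (antisense -AS1), or tokens listed verbatim as official hyphenated
    symbols.  Annotation words such as "region" are discarded.  Raises
    :class:`TokenizationError` if nothing remains.
    """
    if not raw or not raw.strip():
        raise TokenizationError("empty locus string")
    exc = exceptions if exceptions is not None else _load_exceptions()
    prefixes = {p.upper() for p in exc.get("protected_prefixes", [])}
    suffix_res = [re.compile(p, re.IGNORECASE) for p in exc.get("protected_suffix_patterns", [])]
    whole = {s.upper() for s in exc.get("hyphenated_symbols", [])}

    text = raw.replace(_EN_DASH, " ")
    pieces = re.split(r"[/,\s]+", text)
    out: list[str] = []
    for piece in pieces:
        piece = piece.strip().upper()
        if not piece or piece in _ANNOTATION_WORDS:
            continue
        if "-" not in piece or piece in whole:
            out.append(piece)
            continue
        parts = [p for p in piece.split("-")]
        # re-join protected hyphens left to right
        merged: list[str] = []
        i = 0
        while i < len(parts):
            cur = parts[i]
            while i + 1 < len(parts) and cur and parts[i + 1] and (
                cur.split("-")[0] in prefixes
                or any(r.fullmatch(parts[i + 1]) for r in suffix_res)
            ):
                cur = cur + "-" + parts[i + 1]
                i += 1
            if cur:
                merged.append(cur)
            i += 1
        out.extend(merged)
    out = [t for t in out if t]
    if not out:
        raise TokenizationError(f"locus string reduced to no tokens: {raw!r}")
    # dedupe preserving first occurrence
    seen: set[str] = set()
    return [t for t in out if not (t in seen or seen.add(t))]


# ---------------------------------------------------------------------------
# miRNA normalization

# a token that (re)establishes a family prefix: "mir-9", "let-7d-5p",
# "hmir-26a-5p" (typos keep their printed prefix), optionally "mir36"
_FAMILY_RE = re.compile(r"^([a-z]*mir|let)(?=$|-|\d)")


def normalize_mirna_cell(raw: str) -> list[str]:
    """Normalize one printed cell of miRNA names into tokens.

    Lowercases, strips the "hsa-" species prefix, and expands the
    continuation shorthand used throughout published tables: after
    "miR-9", the fragments "-29a" or "29a" denote mir-29a.  Arm suffixes
    are kept exactly as printed.  Fragments that carry no digit (prose
    such as "and"/"novel") are logged and skipped without resetting the
    active family prefix; fragments appearing before any family prefix
    are logged and excluded.
    """
    if not raw or not raw.strip():
        raise TokenizationError("empty miRNA string")
    text = raw.lower()
    out: list[str] = []
    prefix: str | None = None
    for frag in re.split(r"[,\s.]+", text):
        frag = frag.strip()
        if not frag:
            continue
        if frag.startswith("hsa-"):
            frag = frag[len("hsa-"):]
        if not any(c.isdigit() for c in frag):
            logger.debug("skipping non-miRNA fragment %r in %r", frag, raw)
            continue
        m = _FAMILY_RE.match(frag)
        if m:
            prefix = m.group(1)
            out.append(frag)
            continue
        # continuation shorthand: "-29a" / "29a" / "19a-3p"
        if prefix is None:
            logger.warning("unparseable miRNA fragment %r in %r (no active prefix); excluded", frag, raw)
            continue
        out.append(f"{prefix}-{frag.lstrip('-')}")
    if not out:
        raise TokenizationError(f"miRNA string reduced to no tokens: {raw!r}")
    seen: set[str] = set()
    return [t for t in out if not (t in seen or seen.add(t))]


def normalize_mirna(raw: str) -> str:
    """Normalize a single printed miRNA name (no continuation context)."""
    tokens = normalize_mirna_cell(raw)
    if len(tokens) != 1:
        raise TokenizationError(f"expected a single miRNA name, got {tokens!r} from {raw!r}")
    return tokens[0]


# ---------------------------------------------------------------------------
# list construction from packaged fixtures

_GWAS_FILES = {"AD": "gwas_ad_loci.tsv", "PD": "gwas_pd_loci.tsv"}
_MIRNA_FILES = {"AD": "mirna_ad.tsv", "PD": "mirna_pd.tsv"}


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("coexnet.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def _build_list(df: pd.DataFrame, raw_col: str, kind: str, tokenizer) -> NamedEntityList:
    lst = NamedEntityList(kind=kind)
    for _, row in df.iterrows():
        source = f"table {row['table']}, study {row['study']}"
        for tok in tokenizer(row[raw_col]):
            lst.entries.append(Entry(token=tok, raw=row[raw_col], source=source))
    return lst


def load_gwas_list(disease: str) -> NamedEntityList:
    """Load the packaged GWAS locus list ("AD" or "PD") as curated tokens."""
    df = _read_fixture(_GWAS_FILES[disease.upper()])
    return _build_list(df, "raw_locus", "gene_locus", tokenize_locus)


def load_mirna_list(disease: str) -> NamedEntityList:
    """Load the packaged disease-associated miRNA list ("AD" or "PD")."""
    df = _read_fixture(_MIRNA_FILES[disease.upper()])
    return _build_list(df, "raw_mirnas", "mirna", normalize_mirna_cell)


def load_fixture_frame(disease: str, kind: str) -> pd.DataFrame:
    """Raw packaged fixture table (raw strings plus checked-in tokens)."""
    files = _GWAS_FILES if kind == "gene_locus" else _MIRNA_FILES
    return _read_fixture(files[disease.upper()])


def load_de_entrez() -> dict[str, list[int]]:
    """Packaged Entrez IDs of reported DE genes per disease cohort."""
    data = json.loads(_data_text("de_entrez.json"))
    return {"AD": list(data["AD"]), "PD": list(data["PD"])}


def list_from_strings(kind: str, raws: Iterable[str], source: str = "user") -> NamedEntityList:
    """Build a curated list from raw strings (one printed entry per item)."""
    tokenizer = tokenize_locus if kind == "gene_locus" else normalize_mirna_cell
    lst = NamedEntityList(kind=kind)
    for raw in raws:
        for tok in tokenizer(raw):
            lst.entries.append(Entry(token=tok, raw=raw, source=source))
    return lst


# ---------------------------------------------------------------------------
# intersections

def intersect_lists(a: NamedEntityList, b: NamedEntityList) -> OverlapResult:
    """Exact-token intersection of two curated lists of the same kind."""
    if a.kind != b.kind:
        raise ValueError(f"entity kind mismatch: {a.kind!r} vs {b.kind!r}")
    common = sorted(a.tokens() & b.tokens())
    return OverlapResult(
        kind=a.kind,
        intersection=common,
        provenance_a={t: a.provenance(t) for t in common},
        provenance_b={t: b.provenance(t) for t in common},
    )


def intersect_tam_lists() -> OverlapResult:
    """Intersect the packaged per-disease upregulated-miRNA lists."""
    data = json.loads(_data_text("tam_mirnas.json"))
    a = list_from_strings("mirna", data["AD"], source="upregulated in AD")
    b = list_from_strings("mirna", data["PD"], source="upregulated in PD")
    return intersect_lists(a, b)
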