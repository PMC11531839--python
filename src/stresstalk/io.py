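"""Readers, writers and validated containers for DE tables, gene lists and
gene->term maps.

DE result tables are tab-separated text with a header row; the semantic
columns are ``gene_id``, ``log2fc`` and ``adj_p``, remappable through a
*dialect* so that e.g. DESeq2-style headers (``log2FoldChange``, ``padj``)
load without editing the file. Adjusted p-values may be missing (the DESeq2
independent-filtering convention): such rows are kept, flagged, and never
pass a DEG threshold downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DETable",
    "GeneUniverse",
    "TermMap",
    "DEFAULT_DIALECT",
    "load_de_table",
    "write_de_table",
    "load_gene_list",
    "load_term_map",
]

#: semantic column -> file column name used when no dialect is given
DEFAULT_DIALECT: dict[str, str] = {
    "gene_id": "gene_id",
    "log2fc": "log2fc",
    "adj_p": "adj_p",
}

_COLUMNS = ("gene_id", "log2fc", "adj_p")


@dataclass
class DETable:
    """One contrast's differential-expression results.

    Parameters
    ----------
    contrast_label
        Free-text label for the contrast, e.g. ``"HF_vs_NM"``.
    data
        DataFrame with columns ``gene_id`` (str), ``log2fc`` (float, finite)
        and ``adj_p`` (float in [0, 1], NaN = missing). Gene identifiers are
        stripped of surrounding whitespace and must be unique.
    """

    contrast_label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"DETable missing columns: {missing}")
        df["gene_id"] = df["gene_id"].astype(str).str.strip()
        if (df["gene_id"] == "").any():
            raise ValueError("empty gene_id")
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id: {sorted(set(dup))[:5]}")
        df["log2fc"] = pd.to_numeric(df["log2fc"], errors="raise")
        if not np.isfinite(df["log2fc"]).all():
            raise ValueError("log2fc must be finite")
        df["adj_p"] = pd.to_numeric(df["adj_p"], errors="coerce")
        pv = df["adj_p"].dropna()
        if ((pv < 0) | (pv > 1)).any():
            raise ValueError("adj_p outside [0, 1]")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.data["gene_id"])

    @property
    def missing_p(self) -> set[str]:
        """Genes whose adjusted p-value is missing (never callable as DEGs)."""
        return set(self.data.loc[self.data["adj_p"].isna(), "gene_id"])

    def log2fc_of(self, gene_ids: Iterable[str]) -> pd.Series:
        """log2 fold-changes for ``gene_ids``; raises if any gene is absent."""
        s = self.data.set_index("gene_id")["log2fc"]
        wanted = list(gene_ids)
        absent = [g for g in wanted if g not in s.index]
        if absent:
            raise KeyError(
                f"genes absent from table {self.contrast_label!r}: {absent[:5]}"
            )
        return s.loc[wanted]


@dataclass(frozen=True)
class GeneUniverse:
    """Background gene collection for overlap and enrichment tests."""

    gene_ids: frozenset[str]
    source_label: str = "universe"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene universe is empty")
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids

    @classmethod
    def from_tables(cls, tables: Iterable[DETable]) -> "GeneUniverse":
        """Default universe: union of all genes in the supplied DE tables."""
        ids: set[str] = set()
        labels = []
        for t in tables:
            ids |= t.gene_ids
            labels.append(t.contrast_label)
        return cls(frozenset(ids), source_label="union(" + ",".join(labels) + ")")


@dataclass
class TermMap:
    """term_id -> (term_name, member gene set), GMT-style."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (name, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term_id!r} has no members")
            if any(not g for g in members):
                raise ValueError(f"term {term_id!r} has an empty member id")

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def items(self):
        return self.terms.items()


def _resolve_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(_COLUMNS)
        if unknown:
            raise ValueError(f"unknown dialect keys: {sorted(unknown)}")
        d.update(dialect)
    return d


def load_de_table(
    path: str | os.PathLike,
    dialect: Mapping[str, str] | None = None,
    contrast_label: str | None = None,
    sep: str = "\t",
) -> DETable:
    """Load a delimited DE result table into a validated :class:`DETable`.

    ``dialect`` maps semantic names (``gene_id``, ``log2fc``, ``adj_p``) to
    the column headers actually present in the file. Non-numeric adjusted
    p-values ("NA", "", ...) become missing; non-numeric fold-changes are an
    error. Duplicate gene identifiers are an error.
    """
    d = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep=sep)
    absent = [col for col in d.values() if col not in df.columns]
    if absent:
        raise ValueError(f"{path}: missing mapped column(s) {absent}")
    out = pd.DataFrame(
        {sem: df[col] for sem, col in d.items()}
    )
    label = contrast_label or os.path.splitext(os.path.basename(str(path)))[0]
    return DETable(contrast_label=label, data=out)


def write_de_table(table: DETable, path: str | os.PathLike, sep: str = "\t") -> None:
    """Write a DETable as delimited text; missing adj_p serialises as NA."""
    table.data.to_csv(path, sep=sep, index=False, na_rep="NA")


def load_gene_list(path: str | os.PathLike) -> set[str]:
    """One gene identifier per line; blank lines and '#' comments skipped."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.add(g)
    return out


def load_term_map(path: str | os.PathLike) -> TermMap:
    """Parse a GMT file: ``term_id TAB description TAB gene1 TAB gene2 ...``.

    Members are de-duplicated per term. A line with fewer than three fields
    is a parse error naming the line number.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT record needs term_id, "
                    f"description and at least one member (got {len(fields)} fields)"
                )
            term_id, description = fields[0].strip(), fields[1].strip()
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not members:
                raise ValueError(f"{path}: line {lineno}: term has no members")
            terms[term_id] = (description, members)
    return TermMap(terms)
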