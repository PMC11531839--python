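"""Multi-set overlap machinery.

Venn partitions decompose two or three labeled gene sets into their disjoint
membership regions, either from explicit member lists or — when only summary
totals and overlaps are printed in a publication — by inclusion–exclusion on
counts. Pairwise overlap counts are taken to INCLUDE the triple overlap,
which is the reading under which published totals decompose into
non-negative regions.

Also here: directionality concordance between two signed DEG sets, mean
fold-change amplitude of a gene panel across contrasts, and
transcriptome–proteome fold-change quadrant classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from stresstalk.degsets import SignedDEGSet
from stresstalk.io import DETable

__all__ = [
    "VennPartition",
    "ConcordanceReport",
    "venn_from_sets",
    "venn3_from_overlap_counts",
    "combined_only_count",
    "directionality_concordance",
    "mean_amplitude",
    "omic_fc_concordance",
]

Region = frozenset  # a region is keyed by the subset of labels containing it


@dataclass
class VennPartition:
    """Disjoint region decomposition of 2–3 labeled sets.

    ``counts`` maps each non-empty subset of ``labels`` (frozenset key) to
    the number of genes belonging to exactly those sets. ``members`` carries
    the gene identifiers per region when the partition was built from member
    lists; it is ``None`` in count-only mode.
    """

    labels: tuple[str, ...]
    counts: dict[Region, int]
    members: dict[Region, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if not 2 <= len(self.labels) <= 3:
            raise ValueError("VennPartition supports 2 or 3 sets")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        expected = self._regions(self.labels)
        if set(self.counts) != set(expected):
            raise ValueError("counts must cover every non-empty label subset")
        for reg, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"negative/non-integer region count for {set(reg)}")
        if self.members is not None:
            for reg in expected:
                if len(self.members.get(reg, frozenset())) != self.counts[reg]:
                    raise ValueError("member lists inconsistent with counts")

    @staticmethod
    def _regions(labels: Sequence[str]) -> list[Region]:
        out = []
        n = len(labels)
        for mask in range(1, 2**n):
            out.append(frozenset(l for i, l in enumerate(labels) if mask >> i & 1))
        return out

    def count(self, *labels: str) -> int:
        """Count of the region belonging to exactly ``labels``."""
        return self.counts[frozenset(labels)]

    def members_of(self, *labels: str) -> frozenset[str]:
        if self.members is None:
            raise ValueError("count-only partition has no member lists")
        return self.members[frozenset(labels)]

    def set_total(self, label: str) -> int:
        """|S| for input set ``label``: sum of regions containing it."""
        return sum(c for reg, c in self.counts.items() if label in reg)

    def union_total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        """JSON-serialisable report (region keys joined with '&')."""
        key = lambda reg: "&".join(l for l in self.labels if l in reg)
        out = {
            "labels": list(self.labels),
            "counts": {key(r): c for r, c in sorted(self.counts.items(), key=lambda x: key(x[0]))},
        }
        if self.members is not None:
            out["members"] = {
                key(r): sorted(m) for r, m in self.members.items()
            }
        return out


def venn_from_sets(sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Exhaustive disjoint partition of 2–3 labeled gene sets, with members.

    Each gene in the union is assigned to the single region given by its
    exact membership pattern, so regions are disjoint and the per-set
    marginals reproduce the input cardinalities.
    """
    labels = tuple(sets)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if not 2 <= len(labels) <= 3:
        raise ValueError("venn_from_sets supports 2 or 3 sets")
    as_sets = {l: frozenset(s) for l, s in sets.items()}
    members: dict[Region, set[str]] = {r: set() for r in VennPartition._regions(labels)}
    for gene in frozenset.union(*as_sets.values()) if as_sets else frozenset():
        pattern = frozenset(l for l in labels if gene in as_sets[l])
        members[pattern].add(gene)
    frozen = {r: frozenset(m) for r, m in members.items()}
    counts = {r: len(m) for r, m in frozen.items()}
    return VennPartition(labels=labels, counts=counts, members=frozen)


def combined_only_count(
    total: int, overlap_with_a: int, overlap_with_b: int, triple: int
) -> int:
    """Genes unique to one set of three, by inclusion–exclusion on counts.

    ``total`` is that set's cardinality and the two pairwise overlaps are
    counted inclusive of the ``triple`` overlap:
    unique = total − overlap_a − overlap_b + triple.
    """
    unique = total - overlap_with_a - overlap_with_b + triple
    if min(total, overlap_with_a, overlap_with_b, triple) < 0:
        raise ValueError("counts must be non-negative")
    if unique < 0:
        raise ValueError(f"inconsistent counts: unique region would be {unique}")
    return unique


def venn3_from_overlap_counts(
    labels: tuple[str, str, str],
    totals: tuple[int, int, int],
    pairwise: tuple[int, int, int],
    triple: int,
) -> VennPartition:
    """Count-only 3-set Venn partition from totals and (triple-inclusive)
    pairwise overlap counts.

    ``pairwise`` is ordered (|A∩B|, |A∩C|, |B∩C|) for labels (A, B, C).
    Raises if any implied region count is negative (inconsistent inputs).
    """
    a, b, c = labels
    ta, tb, tc = totals
    pab, pac, pbc = pairwise
    if min(ta, tb, tc, pab, pac, pbc, triple) < 0:
        raise ValueError("counts must be non-negative")
    counts = {
        frozenset({a}): ta - pab - pac + triple,
        frozenset({b}): tb - pab - pbc + triple,
        frozenset({c}): tc - pac - pbc + triple,
        frozenset({a, b}): pab - triple,
        frozenset({a, c}): pac - triple,
        frozenset({b, c}): pbc - triple,
        frozenset({a, b, c}): triple,
    }
    bad = {tuple(sorted(r)): v for r, v in counts.items() if v < 0}
    if bad:
        raise ValueError(f"inconsistent overlap counts; negative regions: {bad}")
    return VennPartition(labels=labels, counts=counts, members=None)


@dataclass
class ConcordanceReport:
    """Direction agreement between two signed DEG sets on their common genes."""

    n_common: int
    n_same_direction: int
    per_gene: pd.DataFrame = field(repr=False)  # gene_id, sign_a, sign_b, same

    @property
    def fraction_same(self) -> float | None:
        """None (undefined) when there are no common genes."""
        if self.n_common == 0:
            return None
        return self.n_same_direction / self.n_common


def directionality_concordance(
    a: SignedDEGSet,
    b: SignedDEGSet,
    restrict_to: Iterable[str] | None = None,
) -> ConcordanceReport:
    """Fraction of genes DE in both conditions that move the same way.

    Common genes are ``a.all ∩ b.all`` (optionally intersected with
    ``restrict_to``, which must be contained in that intersection); a gene is
    concordant when it is up in both or down in both.
    """
    common = a.all & b.all
    if restrict_to is not None:
        restrict = frozenset(restrict_to)
        if not restrict <= common:
            raise ValueError("restrict_to must be a subset of the common DEGs")
        common = restrict
    rows = []
    for g in sorted(common):
        sa = 1 if g in a.up else -1
        sb = 1 if g in b.up else -1
        rows.append((g, sa, sb, sa == sb))
    df = pd.DataFrame(rows, columns=["gene_id", "sign_a", "sign_b", "same"])
    n_same = int(df["same"].sum()) if len(df) else 0
    return ConcordanceReport(n_common=len(common), n_same_direction=n_same, per_gene=df)


def mean_amplitude(gene_ids: Iterable[str], tables: Sequence[DETable]) -> pd.DataFrame:
    """Mean and SD of log2 fold-change of a gene panel in each contrast.

    Every gene must be present in every table (a gene panel common to all
    contrasts, e.g. the DEGs shared by all three stress datasets). SD is the
    population-style sample standard deviation (ddof=1; 0 for a single gene).
    """
    genes = sorted(set(gene_ids))
    if not genes:
        raise ValueError("empty gene panel")
    rows = []
    for t in tables:
        fc = t.log2fc_of(genes)
        sd = float(fc.std(ddof=1)) if len(genes) > 1 else 0.0
        rows.append((t.contrast_label, len(genes), float(fc.mean()), sd))
    return pd.DataFrame(rows, columns=["contrast", "n_genes", "mean_log2fc", "sd_log2fc"])


_QUADRANTS = {
    (1, 1): "both-up",
    (-1, -1): "both-down",
    (1, -1): "mRNA-up/protein-down",
    (-1, 1): "mRNA-down/protein-up",
}


def omic_fc_concordance(
    mrna: DETable, protein_log2fc: Mapping[str, float]
) -> tuple[pd.DataFrame, float]:
    """Quadrant classification and rank correlation of mRNA vs protein
    fold-changes on the shared genes.

    Returns a per-gene DataFrame (gene_id, mrna_log2fc, protein_log2fc,
    quadrant) and the Spearman rank correlation of the paired fold-changes.
    Genes with a zero fold-change on either axis are classed by the sign of
    the other axis being zero-inclusive ("both-up" requires strictly
    positive on both; zeros fall in the discordant-free 'unchanged' class).
    """
    shared = sorted(mrna.gene_ids & set(protein_log2fc))
    if not shared:
        raise ValueError("no shared gene identifiers between mRNA and protein data")
    m = mrna.log2fc_of(shared).to_numpy(dtype=float)
    p = np.asarray([protein_log2fc[g] for g in shared], dtype=float)
    quad = []
    for mv, pv in zip(m, p):
        if mv == 0 or pv == 0:
            quad.append("unchanged")
        else:
            quad.append(_QUADRANTS[(int(np.sign(mv)), int(np.sign(pv)))])
    df = pd.DataFrame(
        {"gene_id": shared, "mrna_log2fc": m, "protein_log2fc": p, "quadrant": quad}
    )
    if len(shared) > 1:
        rho = float(sps.spearmanr(m, p).statistic)
    else:
        rho = float("nan")
    return df, rho
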