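"""Overlap significance and term enrichment.

Overlap between two gene sets drawn from a common universe is tested with a
Pearson chi-square on the 2x2 membership contingency table (no continuity
correction by default). Term enrichment uses the one-sided
(over-representation) hypergeometric tail with Benjamini–Hochberg control
across the tested terms — a generic stand-in for ontology-based enrichment
tools, without graph propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from stresstalk.io import GeneUniverse, TermMap

__all__ = [
    "OverlapTest",
    "overlap_chisq",
    "hypergeom_pvalue",
    "enrich_terms",
    "qpcr_relative_expression",
]


@dataclass
class OverlapTest:
    """Chi-square test of association between membership in two gene sets."""

    table: tuple[tuple[int, int], tuple[int, int]]  # [[both, A only], [B only, neither]]
    chi2_stat: float
    p_value: float
    universe_size: int

    @property
    def overlap(self) -> int:
        return self.table[0][0]

    @property
    def expected_overlap(self) -> float:
        n_a = self.table[0][0] + self.table[0][1]
        n_b = self.table[0][0] + self.table[1][0]
        return n_a * n_b / self.universe_size


def overlap_chisq(
    set_a: set, set_b: set, universe: GeneUniverse, correction: bool = False
) -> OverlapTest:
    """Pearson chi-square (1 df) for the overlap of two gene sets.

    Builds the 2x2 table of (in A) x (in B) indicator counts over the
    universe. Yates continuity correction is off by default. Both sets must
    be contained in the universe.
    """
    a, b = frozenset(set_a), frozenset(set_b)
    u = universe.gene_ids
    if not a <= u:
        raise ValueError("set A is not contained in the universe")
    if not b <= u:
        raise ValueError("set B is not contained in the universe")
    both = len(a & b)
    a_only = len(a) - both
    b_only = len(b) - both
    neither = len(u) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]])
    res = sps.chi2_contingency(table, correction=correction)
    return OverlapTest(
        table=((both, a_only), (b_only, neither)),
        chi2_stat=float(res.statistic),
        p_value=float(res.pvalue),
        universe_size=len(u),
    )


def hypergeom_pvalue(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for k successes in a query of
    size n, term of size K, universe of size N."""
    return float(sps.hypergeom.sf(k - 1, big_n, big_k, n))


def enrich_terms(
    query: set,
    universe: GeneUniverse,
    terms: TermMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``query`` in each term.

    Term members are clipped to the universe before counting. P-values are
    Benjamini–Hochberg adjusted across all tested terms; the result is
    sorted by adjusted then raw p-value. ``significant`` flags
    adjusted_p < alpha.
    """
    q = frozenset(query)
    if not q:
        raise ValueError("empty query set")
    if len(terms) == 0:
        raise ValueError("empty term map")
    u = universe.gene_ids
    if not q <= u:
        raise ValueError("query is not contained in the universe")
    big_n, n = len(u), len(q)
    rows = []
    for term_id, (name, members) in terms.items():
        in_universe = members & u
        k = len(q & in_universe)
        big_k = len(in_universe)
        p = hypergeom_pvalue(k, big_k, n, big_n) if big_k else 1.0
        rows.append((term_id, name, k, big_k, n, big_n, p))
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    )
    rej, adj, _, _ = multipletests(df["p_value"].to_numpy(), alpha=alpha, method="fdr_bh")
    df["adjusted_p"] = adj
    df["significant"] = rej
    return df.sort_values(["adjusted_p", "p_value"], kind="stable").reset_index(drop=True)


def qpcr_relative_expression(cp_reference: float, cp_gene: float) -> float:
    """Relative expression from qPCR crossing points, 2**(Cp_ref − Cp_gene),
    assuming a PCR efficiency of 2."""
    return float(2.0 ** (cp_reference - cp_gene))
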