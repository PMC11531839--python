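"""Crosstalk metrics for combined-stress transcriptional responses.

Given the DEG sets A and B of two single stresses and the DEG set AB of the
combined treatment, three scores characterise the interaction:

similarity(A, B) = |A ∩ B| / |A ∪ B|
    Jaccard index of the two single-stress programs; 1 iff identical
    non-empty programs, 0 iff disjoint.

suppression(A, B, AB) = |B ∩ AB| / |B| − |A ∩ AB| / |A|
    Difference in retention of the two single-stress programs in the
    combined response. With the convention A = dominating (abiotic) stress
    and B = suppressed (biotic) stress, a NEGATIVE score means A's program
    is retained at the expense of B's — A suppresses B. Antisymmetric in
    (A, B); range [−1, 1].

novel_interaction(A, B, AB) = |AB \\ (A ∪ B)| / |AB|
    Fraction of the combined-stress program seen in neither single stress;
    1 iff the combined treatment elicits an entirely new program.

Each score is computed per direction (up with up, down with down) and on the
direction-blind union by :func:`crosstalk_report`. Alternative formulas can
be swapped in via the ``formulas`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

from stresstalk.degsets import SignedDEGSet

__all__ = [
    "CrosstalkScores",
    "similarity_score",
    "suppression_score",
    "suppression_score_from_counts",
    "novel_interaction_score",
    "novel_interaction_from_counts",
    "crosstalk_report",
    "DEFAULT_FORMULAS",
]

GeneSet = frozenset


def similarity_score(a: set, b: set) -> float:
    """Jaccard similarity of two single-stress DEG sets; undefined (error)
    when both are empty."""
    a, b = frozenset(a), frozenset(b)
    union = a | b
    if not union:
        raise ValueError("similarity undefined: both sets empty")
    return len(a & b) / len(union)


def suppression_score(a: set, b: set, ab: set) -> float:
    """Retention-difference suppression score r_B − r_A, r_X = |X∩AB|/|X|.

    Negative values mean the A-stress program dominates the combined
    response (A suppresses B). Both single-stress sets must be non-empty.
    """
    a, b, ab = frozenset(a), frozenset(b), frozenset(ab)
    if not a or not b:
        raise ValueError("suppression undefined: empty single-stress set")
    return len(b & ab) / len(b) - len(a & ab) / len(a)


def suppression_score_from_counts(
    n_a: int, n_b: int, a_in_ab: int, b_in_ab: int
) -> float:
    """Suppression from published summary counts: b_in_ab/n_b − a_in_ab/n_a."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("single-stress set sizes must be positive")
    if not (0 <= a_in_ab <= n_a and 0 <= b_in_ab <= n_b):
        raise ValueError("overlap counts exceed set sizes")
    return b_in_ab / n_b - a_in_ab / n_a


def novel_interaction_score(a: set, b: set, ab: set) -> float:
    """Fraction of the combined-stress DEG set outside A ∪ B; AB non-empty."""
    a, b, ab = frozenset(a), frozenset(b), frozenset(ab)
    if not ab:
        raise ValueError("novel interaction undefined: empty combined set")
    return len(ab - (a | b)) / len(ab)


def novel_interaction_from_counts(novel: int, n_ab: int) -> float:
    """Novel-interaction score from summary counts: novel / |AB|."""
    if n_ab <= 0:
        raise ValueError("combined set size must be positive")
    if not 0 <= novel <= n_ab:
        raise ValueError("novel count outside [0, |AB|]")
    return novel / n_ab


#: score name -> callable; swap entries to use alternative definitions
DEFAULT_FORMULAS: dict[str, Callable] = {
    "similarity": similarity_score,
    "suppression": suppression_score,
    "novel_interaction": novel_interaction_score,
}


@dataclass
class CrosstalkScores:
    """Scores for one direction, with the Venn region counts behind them."""

    direction: str  # up | down | all
    similarity: float | None
    suppression: float | None
    novel_interaction: float | None
    component_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "similarity": self.similarity,
            "suppression": self.suppression,
            "novel_interaction": self.novel_interaction,
            "component_counts": dict(self.component_counts),
        }


def _scores_for(
    a: GeneSet, b: GeneSet, ab: GeneSet, direction: str, formulas: Mapping[str, Callable]
) -> CrosstalkScores:
    counts = {
        "n_a": len(a),
        "n_b": len(b),
        "n_ab": len(ab),
        "a_and_b": len(a & b),
        "a_in_ab": len(a & ab),
        "b_in_ab": len(b & ab),
        "novel": len(ab - (a | b)),
    }
    sim = formulas["similarity"](a, b) if (a | b) else None
    sup = formulas["suppression"](a, b, ab) if (a and b) else None
    nov = formulas["novel_interaction"](a, b, ab) if ab else None
    return CrosstalkScores(
        direction=direction,
        similarity=sim,
        suppression=sup,
        novel_interaction=nov,
        component_counts=counts,
    )


def crosstalk_report(
    a: SignedDEGSet,
    b: SignedDEGSet,
    ab: SignedDEGSet,
    formulas: Mapping[str, Callable] | None = None,
) -> dict[str, CrosstalkScores]:
    """All three crosstalk scores for each of up / down / all.

    ``a`` is the dominating (abiotic, e.g. hypoxia) single stress, ``b`` the
    potentially suppressed (biotic, e.g. flg22) one, ``ab`` the combined
    treatment. Per-direction scores compare same-direction sets only; 'all'
    is direction-blind. Degenerate inputs (empty sets where a score is
    undefined) yield ``None`` for that score rather than an exception.
    """
    labels = {a.condition_label, b.condition_label, ab.condition_label}
    if len(labels) != 3:
        raise ValueError("condition labels must be distinct")
    formulas = dict(DEFAULT_FORMULAS) | dict(formulas or {})
    return {
        d: _scores_for(a.direction(d), b.direction(d), ab.direction(d), d, formulas)
        for d in ("up", "down", "all")
    }
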