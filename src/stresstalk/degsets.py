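"""Signed DEG calling.

A gene is called differentially expressed when its adjusted p-value is
strictly below the p threshold and |log2 fold-change| strictly exceeds the
fold-change threshold. The defaults (adjusted p < 0.05, |log2FC| > 0.585)
are the cutoffs used throughout the hypoxia/flg22 analysis; the 1.0
fold-change variant matches the stricter cutoff applied to external hypoxia
time-course data. Both inequalities are strict, so a gene sitting exactly on
a threshold is excluded. Genes with a missing adjusted p-value are never
called.
"""

from __future__ import annotations

from dataclasses import dataclass

from stresstalk.io import DETable

__all__ = ["SignedDEGSet", "call_degs", "hypoxia_style_degs", "DEFAULT_FC", "DEFAULT_P"]

DEFAULT_FC = 0.585
DEFAULT_P = 0.05


@dataclass(frozen=True)
class SignedDEGSet:
    """A condition's DEG identifiers split by direction of change."""

    condition_label: str
    up: frozenset[str]
    down: frozenset[str]
    fc_threshold: float = DEFAULT_FC
    p_threshold: float = DEFAULT_P

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if self.up & self.down:
            raise ValueError("up and down DEG sets must be disjoint")

    @property
    def all(self) -> frozenset[str]:
        return self.up | self.down

    def direction(self, which: str) -> frozenset[str]:
        if which == "up":
            return self.up
        if which == "down":
            return self.down
        if which == "all":
            return self.all
        raise ValueError(f"direction must be up/down/all, got {which!r}")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def call_degs(
    table: DETable,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_P,
) -> SignedDEGSet:
    """Call signed DEGs from a DE table at strict thresholds.

    up:   log2fc >  fc_threshold  and adj_p < p_threshold
    down: log2fc < −fc_threshold  and adj_p < p_threshold
    """
    if not (fc_threshold > 0 and p_threshold > 0):
        raise ValueError("thresholds must be positive")
    df = table.data
    sig = df["adj_p"] < p_threshold  # NaN compares False: missing p never calls
    up = frozenset(df.loc[sig & (df["log2fc"] > fc_threshold), "gene_id"])
    down = frozenset(df.loc[sig & (df["log2fc"] < -fc_threshold), "gene_id"])
    return SignedDEGSet(
        condition_label=table.contrast_label,
        up=up,
        down=down,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
    )


def hypoxia_style_degs(table: DETable) -> SignedDEGSet:
    """DEG calling at |log2FC| > 1.0 and adjusted p (FDR) < 0.05."""
    return call_degs(table, fc_threshold=1.0, p_threshold=DEFAULT_P)
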