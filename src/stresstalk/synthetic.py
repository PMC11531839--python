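"""Synthetic single- and combined-stress DE tables with known crosstalk
structure.

The generator emits three DE tables over a shared gene universe — stress A
(hypoxia-like), stress B (flg22-like) and the combined treatment AB —
together with the ground-truth class of every gene. DEGs receive effect
sizes strictly beyond the calling thresholds and adjusted p-values strictly
below them; null genes sit strictly inside, so DEG calling recovers the
ground truth exactly (unless the noisy-boundary flag is set).

Construction, given a spec:

1. ``n_shared = round(similarity_overlap * n_deg_b)`` genes are shared
   between the A and B programs (same direction in both); the remaining
   A-only / B-only genes are disjoint draws from the universe.
2. Each single-stress DEG is retained in the combined program by an
   independent Bernoulli draw (``retention_a`` / ``retention_b``); a shared
   gene is retained if either of its two draws succeeds.
3. Novel genes are drawn from the null pool so that the novel fraction of
   the combined program matches ``novelty`` up to integer rounding:
   ``n_novel = round(novelty/(1-novelty) * n_retained)``.
4. Directions are up with probability ``prop_up`` and preserved for
   retained genes; novel genes draw directions from the same law.

Default parameters mirror the realized rates of a short combined
hypoxia/flg22 treatment: a small (~3%) overlap between single-stress
programs, high retention of both programs in the combined response
(0.90 / 0.84), a ~0.36 novel fraction, and ~73% upregulated DEGs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from stresstalk.crosstalk import crosstalk_report
from stresstalk.degsets import DEFAULT_FC, DEFAULT_P, call_degs
from stresstalk.io import DETable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_experiment",
    "expected_scores",
    "sweep",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic combined-stress experiment.

    All proportions are in [0, 1]; effect sizes are on the log2 scale.
    """

    n_genes: int = 5000
    n_deg_a: int = 1000
    n_deg_b: int = 1000
    similarity_overlap: float = 0.03  # fraction of B's DEGs shared with A
    retention_a: float = 0.90  # P(an A DEG stays significant in AB)
    retention_b: float = 0.84
    novelty: float = 0.36  # target fraction of AB that is AB-only
    prop_up: float = 0.73
    effect_size_mean: float = 2.0
    effect_size_sd: float = 0.75
    fc_threshold: float = DEFAULT_FC
    p_threshold: float = DEFAULT_P
    noisy_boundary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("similarity_overlap", "retention_a", "retention_b", "novelty", "prop_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_genes, self.n_deg_a, self.n_deg_b) <= 0:
            raise ValueError("n_genes and program sizes must be positive")
        if self.effect_size_sd < 0:
            raise ValueError("effect_size_sd must be non-negative")
        if not (self.fc_threshold > 0 and 0 < self.p_threshold <= 1):
            raise ValueError("invalid calling thresholds")
        if self.n_shared > min(self.n_deg_a, self.n_deg_b):
            raise ValueError("similarity_overlap demands more shared genes than the programs hold")
        if self.n_deg_a + self.n_deg_b - self.n_shared > self.n_genes:
            raise ValueError("DEG programs exceed the gene universe")

    @property
    def n_shared(self) -> int:
        return round(self.similarity_overlap * self.n_deg_b)


@dataclass
class GroundTruth:
    """True gene classes and realized region counts of one experiment.

    ``per_gene`` columns: gene_id, label in {A-only, B-only, shared,
    AB-novel, null}, direction in {up, down, none}, in_combined (bool).
    """

    per_gene: pd.DataFrame = field(repr=False)
    region_counts: dict[str, int] = field(default_factory=dict)

    def genes(self, label: str) -> frozenset[str]:
        df = self.per_gene
        return frozenset(df.loc[df["label"] == label, "gene_id"])


def _de_values(
    rng: np.random.Generator,
    n_genes: int,
    deg_idx: np.ndarray,
    deg_sign: np.ndarray,
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """log2fc and adj_p arrays for one table: crisp DEGs, crisp nulls."""
    fc = rng.uniform(-0.9, 0.9, size=n_genes) * spec.fc_threshold
    adj_p = rng.uniform(spec.p_threshold, 1.0, size=n_genes)
    mag = np.abs(rng.normal(spec.effect_size_mean, spec.effect_size_sd, size=len(deg_idx)))
    mag = np.maximum(mag, spec.fc_threshold + 0.05)
    fc[deg_idx] = deg_sign * mag
    adj_p[deg_idx] = rng.uniform(1e-12, spec.p_threshold * (1 - 1e-9), size=len(deg_idx))
    if spec.noisy_boundary:
        # a few null genes wander near the cutoffs; ground-truth recovery
        # is then no longer exact (robustness testing only)
        null_mask = np.ones(n_genes, bool)
        null_mask[deg_idx] = False
        null_idx = np.flatnonzero(null_mask)
        n_noisy = max(1, len(null_idx) // 50)
        noisy = rng.choice(null_idx, size=n_noisy, replace=False)
        fc[noisy] = rng.choice([-1.0, 1.0], n_noisy) * rng.uniform(
            0.9 * spec.fc_threshold, 1.1 * spec.fc_threshold, n_noisy
        )
        adj_p[noisy] = rng.uniform(0.8 * spec.p_threshold, 1.2 * spec.p_threshold, n_noisy)
    return fc, np.clip(adj_p, 1e-300, 1.0)


def generate_experiment(
    spec: SyntheticSpec,
) -> tuple[DETable, DETable, DETable, GroundTruth]:
    """Generate (table_A, table_B, table_AB, ground_truth), deterministically
    for a given seed.

    Raises if the spec is infeasible, e.g. the requested novelty needs more
    novel genes than the null pool holds.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_structure, rng_a, rng_b, rng_ab = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    perm = rng_structure.permutation(spec.n_genes)

    n_sh = spec.n_shared
    n_ao = spec.n_deg_a - n_sh
    n_bo = spec.n_deg_b - n_sh
    shared_idx = perm[:n_sh]
    a_only_idx = perm[n_sh : n_sh + n_ao]
    b_only_idx = perm[n_sh + n_ao : n_sh + n_ao + n_bo]
    pool_idx = perm[n_sh + n_ao + n_bo :]  # null pool, source of novel genes

    a_idx = np.concatenate([shared_idx, a_only_idx])
    b_idx = np.concatenate([shared_idx, b_only_idx])

    # one direction per DEG gene, shared between programs and preserved in AB
    direction = np.full(spec.n_genes, 0, dtype=int)  # +1 up, -1 down, 0 null
    union_idx = perm[: n_sh + n_ao + n_bo]
    direction[union_idx] = np.where(
        rng_structure.random(len(union_idx)) < spec.prop_up, 1, -1
    )

    # Bernoulli retention; a shared gene survives if either draw succeeds
    keep_a = rng_structure.random(len(a_idx)) < spec.retention_a
    keep_b = rng_structure.random(len(b_idx)) < spec.retention_b
    retained = set(a_idx[keep_a]) | set(b_idx[keep_b])
    n_ret = len(retained)

    if spec.novelty >= 1.0:
        if n_ret:
            raise ValueError(
                "novelty = 1 is infeasible with non-zero retention: the "
                "combined program would have to exclude retained genes"
            )
        n_novel = spec.n_deg_b
    else:
        n_novel = round(spec.novelty / (1.0 - spec.novelty) * n_ret)
    if n_novel > len(pool_idx):
        raise ValueError(
            f"novelty {spec.novelty} demands {n_novel} novel genes but the "
            f"null pool holds only {len(pool_idx)}"
        )
    novel_idx = rng_structure.choice(pool_idx, size=n_novel, replace=False)
    direction[novel_idx] = np.where(
        rng_structure.random(n_novel) < spec.prop_up, 1, -1
    )
    ab_idx = np.concatenate([np.fromiter(retained, dtype=int, count=n_ret), novel_idx])
    ab_idx = np.sort(ab_idx.astype(int))

    def make_table(label: str, rng: np.random.Generator, deg_idx: np.ndarray) -> DETable:
        deg_idx = np.sort(deg_idx.astype(int))
        fc, p = _de_values(rng, spec.n_genes, deg_idx, direction[deg_idx], spec)
        return DETable(
            contrast_label=label,
            data=pd.DataFrame({"gene_id": genes, "log2fc": fc, "adj_p": p}),
        )

    table_a = make_table("A", rng_a, a_idx)
    table_b = make_table("B", rng_b, b_idx)
    table_ab = make_table("AB", rng_ab, ab_idx)

    label_col = np.full(spec.n_genes, "null", dtype=object)
    label_col[shared_idx] = "shared"
    label_col[a_only_idx] = "A-only"
    label_col[b_only_idx] = "B-only"
    label_col[novel_idx] = "AB-novel"
    in_ab = np.zeros(spec.n_genes, bool)
    in_ab[ab_idx] = True
    per_gene = pd.DataFrame(
        {
            "gene_id": genes,
            "label": label_col,
            "direction": np.where(direction > 0, "up", np.where(direction < 0, "down", "none")),
            "in_combined": in_ab,
        }
    )
    up = direction > 0
    region_counts = {
        "n_a": len(a_idx),
        "n_b": len(b_idx),
        "n_shared": n_sh,
        "n_ab": len(ab_idx),
        "n_retained_a": int(keep_a.sum()),
        "n_retained_b": int(keep_b.sum()),
        "n_retained": n_ret,
        "n_novel": n_novel,
        "n_ab_up": int(up[ab_idx].sum()),
        "n_ab_down": int(len(ab_idx) - up[ab_idx].sum()),
    }
    return table_a, table_b, table_ab, GroundTruth(per_gene=per_gene, region_counts=region_counts)


def expected_scores(spec: SyntheticSpec) -> dict[str, float]:
    """Analytic expectations of the direction-blind crosstalk estimates.

    With shared fraction s_X = n_shared / n_deg_X and or-of-two-draws
    retention of shared genes, the expected program retention is
    E[r_X] = retention_X + s_X (1 − retention_X) retention_Y, so the
    expected suppression estimate is E[r_B] − E[r_A] — equal to
    (1 − s)(retention_b − retention_a) for equal-size programs. The novel
    fraction is ``novelty`` by construction (up to integer rounding).
    """
    s_a = spec.n_shared / spec.n_deg_a
    s_b = spec.n_shared / spec.n_deg_b
    r_a = spec.retention_a + s_a * (1 - spec.retention_a) * spec.retention_b
    r_b = spec.retention_b + s_b * (1 - spec.retention_b) * spec.retention_a
    union = spec.n_deg_a + spec.n_deg_b - spec.n_shared
    return {
        "similarity": spec.n_shared / union,
        "suppression": r_b - r_a,
        "novel_interaction": spec.novelty,
        "retention_a": r_a,
        "retention_b": r_b,
    }


def _derived_seed(seed: int, cell: int, rep: int) -> int:
    # deterministic per-replicate child seed, kept below 2**31
    return (seed * 1_000_003 + cell * 9_973 + rep) % (2**31 - 1)


def sweep(
    spec_grid: Sequence[SyntheticSpec] | Iterable[SyntheticSpec],
    replicates: int = 10,
    summarize: bool = True,
) -> pd.DataFrame:
    """Estimated crosstalk scores across a grid of generator specs.

    Each grid cell is run ``replicates`` times with distinct derived seeds;
    the three DE tables are thresholded with the spec's own cutoffs and
    scored with :func:`crosstalk_report` on the direction-blind sets.
    Returns one row per (cell, replicate), or per cell with mean/std columns
    when ``summarize`` is true.
    """
    specs = list(spec_grid)
    if not specs:
        raise ValueError("empty spec grid")
    if replicates <= 0:
        raise ValueError("replicates must be positive")
    params = [
        "n_genes", "n_deg_a", "n_deg_b", "similarity_overlap",
        "retention_a", "retention_b", "novelty", "prop_up",
    ]
    rows = []
    for ci, spec in enumerate(specs):
        for rep in range(replicates):
            rspec = dataclasses.replace(spec, seed=_derived_seed(spec.seed, ci, rep))
            ta, tb, tab, _ = generate_experiment(rspec)
            degs = {
                lbl: call_degs(t, rspec.fc_threshold, rspec.p_threshold)
                for lbl, t in (("A", ta), ("B", tb), ("AB", tab))
            }
            scores = crosstalk_report(degs["A"], degs["B"], degs["AB"])["all"]
            row = {p: getattr(spec, p) for p in params}
            row.update(
                cell=ci,
                replicate=rep,
                similarity=scores.similarity,
                suppression=scores.suppression,
                novel_interaction=scores.novel_interaction,
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    if not summarize:
        return df
    agg = df.groupby(["cell"] + params, as_index=False).agg(
        n_replicates=("replicate", "size"),
        similarity_mean=("similarity", "mean"),
        similarity_sd=("similarity", "std"),
        suppression_mean=("suppression", "mean"),
        suppression_sd=("suppression", "std"),
        novel_mean=("novel_interaction", "mean"),
        novel_sd=("novel_interaction", "std"),
    )
    return agg
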