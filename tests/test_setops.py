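from itertools import chain, combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stresstalk.degsets import SignedDEGSet
from stresstalk.setops import (
    combined_only_count,
    directionality_concordance,
    mean_amplitude,
    omic_fc_concordance,
    venn3_from_overlap_counts,
    venn_from_sets,
)

from conftest import make_table


def brute_force_regions(sets):
    """Oracle: tally each gene's exact membership pattern."""
    labels = list(sets)
    out = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            out[frozenset(combo)] = set()
    for g in set().union(*sets.values()):
        pattern = frozenset(l for l in labels if g in sets[l])
        out[pattern].add(g)
    return out


gene_sets = st.sets(st.integers(0, 49).map(lambda i: f"g{i}"), max_size=50)


class TestVennFromSets:
    def test_hand_enumerable(self):
        part = venn_from_sets({"A": {"a", "b"}, "B": {"b", "c"}, "AB": {"b", "c", "d"}})
        assert part.members_of("A") == {"a"}
        assert part.members_of("B") == frozenset()
        assert part.members_of("AB") == {"d"}
        assert part.members_of("A", "B") == frozenset()
        assert part.members_of("B", "AB") == {"c"}
        assert part.members_of("A", "B", "AB") == {"b"}

    def test_identical_sets_only_triple(self):
        s = {"x", "y"}
        part = venn_from_sets({"A": s, "B": s, "C": s})
        assert part.count("A", "B", "C") == 2
        assert part.union_total() == 2

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            venn_from_sets(dict([("A", set())]))  # one set: unsupported arity

    @settings(max_examples=100, derandomize=True)
    @given(a=gene_sets, b=gene_sets, c=gene_sets)
    def test_matches_brute_force_oracle(self, a, b, c):
        sets = {"A": a, "B": b, "C": c}
        part = venn_from_sets(sets)
        oracle = brute_force_regions(sets)
        for reg, members in oracle.items():
            assert part.members[reg] == members
        # marginals reproduce input cardinalities; regions sum to the union
        for l, s in sets.items():
            assert part.set_total(l) == len(s)
        assert part.union_total() == len(a | b | c)

    @settings(max_examples=100, derandomize=True)
    @given(a=gene_sets, b=gene_sets, c=gene_sets)
    def test_equals_count_reconstruction(self, a, b, c):
        """Count-only inclusion–exclusion agrees with the member partition
        applied to its own marginal counts."""
        part = venn_from_sets({"A": a, "B": b, "C": c})
        rebuilt = venn3_from_overlap_counts(
            ("A", "B", "C"),
            (len(a), len(b), len(c)),
            (len(a & b), len(a & c), len(b & c)),
            len(a & b & c),
        )
        assert rebuilt.counts == part.counts


class TestVennFromCounts:
    def test_identical_set_limit(self):
        part = venn3_from_overlap_counts(("A", "B", "C"), (5, 5, 5), (5, 5, 5), 5)
        assert part.count("A", "B", "C") == 5
        assert part.union_total() == 5

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            venn3_from_overlap_counts(("A", "B", "C"), (10, 10, 10), (9, 9, 0), 0)

    def test_combined_only_helper_consistency(self):
        assert combined_only_count(100, 30, 40, 10) == 40
        with pytest.raises(ValueError):
            combined_only_count(10, 9, 9, 0)


class TestDirectionalityConcordance:
    def test_hand_enumerable(self):
        a = SignedDEGSet("a", up=frozenset({"g1", "g2"}), down=frozenset({"g3"}))
        b = SignedDEGSet("b", up=frozenset({"g1"}), down=frozenset({"g2", "g3"}))
        rep = directionality_concordance(a, b)
        assert (rep.n_common, rep.n_same_direction) == (3, 2)
        assert rep.fraction_same == pytest.approx(2 / 3)

    def test_identity_and_symmetry(self):
        a = SignedDEGSet("a", up=frozenset({"g1"}), down=frozenset({"g2", "g3"}))
        assert directionality_concordance(a, a).fraction_same == 1.0
        b = SignedDEGSet("b", up=frozenset({"g2"}), down=frozenset({"g1"}))
        assert (
            directionality_concordance(a, b).fraction_same
            == directionality_concordance(b, a).fraction_same
        )

    def test_empty_intersection_undefined(self):
        a = SignedDEGSet("a", up=frozenset({"g1"}), down=frozenset())
        b = SignedDEGSet("b", up=frozenset({"g9"}), down=frozenset())
        rep = directionality_concordance(a, b)
        assert rep.n_common == 0 and rep.fraction_same is None

    def test_restriction_must_be_subset(self):
        a = SignedDEGSet("a", up=frozenset({"g1"}), down=frozenset())
        b = SignedDEGSet("b", up=frozenset({"g1"}), down=frozenset())
        with pytest.raises(ValueError):
            directionality_concordance(a, b, restrict_to={"g2"})


class TestMeanAmplitude:
    def test_hand_values_and_single_gene(self):
        t = make_table("c1", [("a", 1.0, 0.01), ("b", 3.0, 0.01)])
        df = mean_amplitude({"a", "b"}, [t])
        assert df.loc[0, "mean_log2fc"] == pytest.approx(2.0)
        single = mean_amplitude({"a"}, [t])
        assert single.loc[0, "mean_log2fc"] == pytest.approx(1.0)
        assert single.loc[0, "sd_log2fc"] == 0.0

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(20)]
        tables = []
        fcs = {}
        for k in range(3):
            vals = rng.normal(0, 2, 20)
            fcs[k] = vals
            tables.append(make_table(f"t{k}", list(zip(genes, vals, [0.01] * 20))))
        df = mean_amplitude(genes, tables)
        for k in range(3):
            assert df.loc[k, "mean_log2fc"] == pytest.approx(fcs[k].mean())
            assert df.loc[k, "sd_log2fc"] == pytest.approx(fcs[k].std(ddof=1))

    def test_absent_gene_is_error(self):
        t = make_table("c1", [("a", 1.0, 0.01)])
        with pytest.raises(KeyError):
            mean_amplitude({"a", "zz"}, [t])


class TestOmicConcordance:
    def test_quadrant_signs(self):
        t = make_table("m", [("g1", -1.0, 0.01), ("g2", 2.0, 0.01)])
        df, _ = omic_fc_concordance(t, {"g1": 1.0, "g2": 0.5})
        assert df.set_index("gene_id").loc["g1", "quadrant"] == "mRNA-down/protein-up"
        assert df.set_index("gene_id").loc["g2", "quadrant"] == "both-up"

    def test_identical_vectors_rank_correlation_one(self):
        genes = [f"g{i}" for i in range(10)]
        vals = np.linspace(-2, 2, 10)
        t = make_table("m", list(zip(genes, vals, [0.01] * 10)))
        _, rho = omic_fc_concordance(t, dict(zip(genes, vals)))
        assert rho == pytest.approx(1.0)

    def test_correlation_matches_oracle(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(50)]
        m = rng.normal(0, 1, 50)
        p = 0.5 * m + rng.normal(0, 1, 50)
        t = make_table("m", list(zip(genes, m, [0.01] * 50)))
        df, rho = omic_fc_concordance(t, dict(zip(genes, p)))
        # oracle on the aligned pairs exactly as returned
        assert rho == pytest.approx(
            spearmanr(df["mrna_log2fc"], df["protein_log2fc"]).statistic
        )

    def test_empty_intersection_error(self):
        t = make_table("m", [("g1", 1.0, 0.01)])
        with pytest.raises(ValueError):
            omic_fc_concordance(t, {"zz": 1.0})
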