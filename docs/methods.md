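# Methods

## Problem setting

A factorial stress experiment yields per-contrast differential-expression
tables: single stress A vs control, single stress B vs control, and the
combined treatment AB vs control. The package quantifies how the combined
transcriptional program relates to the two single-stress programs, treating
the DE tables (gene, log₂ fold-change, adjusted p) as the primary data.
Upstream read processing and DE model fitting are out of scope: the
analysis consumes whatever table the user's DE tool produced.

## DEG calling

A gene is a DEG when adjusted *p* < `p_threshold` and |log₂FC| >
`fc_threshold`, both strict. Defaults are 0.05 and 0.585; the 0.585 value
is used as a literal constant (≈ log₂ 1.5, but not recomputed) so that a
published cutoff is reproduced digit for digit. A second preset
(`hypoxia_style_degs`) applies the stricter 1.0 cutoff used for external
hypoxia time-course data. Genes whose adjusted p is missing (the DESeq2
independent-filtering convention) are retained in the table — they count
toward the gene universe — but can never be called; this keeps universe
accounting stable across contrasts. Boundary genes (a fold-change exactly
at the threshold) are excluded by the strict inequality; this is tested
explicitly. Identifiers are compared case-sensitively after whitespace
stripping, matching the canonical uppercase AGI locus format.

## Venn partitions

`venn_from_sets` assigns every gene in the union of 2–3 labeled sets to the
single region given by its exact membership pattern; regions are disjoint
by construction and per-set marginals equal the input cardinalities.
`venn3_from_overlap_counts` reconstructs the same partition from summary
counts by inclusion–exclusion when only published totals are available.
Pairwise overlap counts are interpreted as *including* the triple overlap:
this is the reading under which published factorial-experiment counts
(145/1906/2612 totals, 1601/131 overlaps, 59 triple) decompose into
non-negative regions with a 939-gene combined-only region. Any negative
implied region raises an error rather than being clipped.

## Crosstalk scores

Working definitions (each swappable through the `formulas` argument of
`crosstalk_report` if an alternative algebra is preferred):

- similarity(A, B) = |A∩B| / |A∪B|; undefined (error) when both sets are
  empty.
- suppression(A, B, AB) = |B∩AB|/|B| − |A∩AB|/|A|; the difference of
  program retention rates. Argument order is fixed as (A = dominating /
  abiotic, B = suppressed / biotic) so that a negative value reads "A
  suppresses B". Antisymmetric under swapping A and B; requires both
  single-stress sets non-empty.
- novel_interaction(A, B, AB) = |AB \ (A∪B)| / |AB|; requires AB non-empty.

These satisfy all the stated range and extreme-case behaviour (identity ⇒
similarity 1; disjoint ⇒ 0; AB = A with disjoint B ⇒ suppression −1;
AB disjoint from A∪B ⇒ novel 1) and reconcile exactly with the published
per-direction novel scores (459/1904 = 0.241 up, 480/708 = 0.678 down,
whose totals sum to the printed 2612 and 939). Per-direction scores compare
up-sets with up-sets and down-sets with down-sets only; a gene that flips
direction between conditions contributes to the direction-blind ("all")
scores but to neither per-direction score. In `crosstalk_report`, a
direction in which a score's preconditions fail (e.g. no downregulated
genes anywhere) yields `None` rather than an exception, so batch sweeps do
not abort on degenerate draws.

## Overlap significance and enrichment

Overlap between two gene sets is tested with a Pearson χ² (1 df) on the
2×2 membership table over a user-supplied universe. No continuity
correction by default (a flag enables Yates), since small-expected-count
tables are better served by the hypergeometric tail, which is provided as
an independent oracle. The default universe is the union of all genes in
the supplied DE tables — the most defensible reproducible choice when the
original background is unstated — and is injectable for sensitivity
analysis. Term enrichment is a one-sided (over-representation)
hypergeometric test per term with Benjamini–Hochberg adjustment across the
tested terms; term members outside the universe are clipped before
counting. No ontology graph propagation is attempted: the enrichment layer
is a generic stand-in, and published GO tables that depend on a specific
annotation snapshot are not reproduction targets.

## Synthetic data generator

The generator emulates the statistical skeleton of a two-stress factorial
experiment at the DE-table level: a gene universe of `n_genes`, programs of
`n_deg_a` / `n_deg_b` genes of which `round(similarity_overlap · n_deg_b)`
are shared (same direction in both), independent Bernoulli retention of
each single-stress DEG in the combined program, and novel genes drawn from
the null pool so the novel fraction of AB matches `novelty` up to integer
rounding. Directions are up with probability `prop_up`, preserved for
retained genes. DEG rows get |log₂FC| = max(|N(effect_size_mean,
effect_size_sd)|, threshold + 0.05) and adjusted p uniform below the p
cutoff; null rows stay strictly inside both cutoffs. Ground-truth recovery
by the calling layer is therefore exact, which is what the recovery tests
assert; an optional `noisy_boundary` flag deliberately places a few null
genes near the cutoffs for robustness testing, at the cost of exactness.

A shared gene is retained in AB if *either* of its two retention draws
succeeds. With shared fraction s per program this inflates both expected
retention rates, and for equal-size programs the expected suppression
estimate becomes (1 − s)(retention_b − retention_a). `expected_scores`
returns these exact expectations and the tests compare against them, so the
small shrinkage is accounted for analytically, not absorbed into
tolerances.

Defaults mirror the realized rates of a short (1 h) combined hypoxia/flg22
treatment: retention 0.90 / 0.84 (the observed 131/145 and 1601/1906
program retentions), novelty 0.36 (939/2612), prop_up 0.73 (1904/2612),
and a small 3% single-program overlap (60/1906). Universe and program
sizes default to 5000 / 1000 / 1000 — large enough that binomial sampling
error on the scores is ~0.015, small enough that a 200-replicate sweep
runs in seconds. Effect sizes default to mean 2.0, SD 0.75 on the log₂
scale, typical of strong early stress-response fold-changes.

What a green recovery test establishes: the set algebra, thresholding and
score formulas are mutually consistent and unbiased under the generator's
idealised world. What it does not establish: behaviour under realistic
p-value miscalibration, correlated genes, borderline effect sizes, or
count-level noise — the generator operates downstream of the DE model by
design (a count-level mode is an extension point, not core).

Seeding: one master seed per spec; four child streams (structure and one
per table) derived via `numpy.random.SeedSequence.spawn`, so tables are
byte-identical across runs with the same seed. Sweeps derive one child seed
per (cell, replicate) deterministically, kept below 2³¹.

## Numerical and degenerate-input choices

- Concordance with zero common genes reports `fraction_same = None`
  (undefined), never 0 — a fraction is not fabricated.
- Adjusted p-values are validated into [0, 1]; fold-changes must be finite;
  duplicate gene identifiers are an error, not silently deduplicated.
- Spearman correlation is used for transcriptome–proteome concordance
  (robust to the heavy-tailed fold-change distributions); a single shared
  gene yields NaN.
- Venn partitions from counts validate every implied region; sweep summary
  dispersion uses ddof = 1.

## Known limitations

- Suppression/similarity/novel scores are set-level statistics; no per-gene
  interaction-mode taxonomy (prioritized/canceled classes) is attempted.
- The enrichment layer knows nothing of term hierarchies.
- The qPCR helper assumes a PCR efficiency of exactly 2.
- No graphical Venn rendering; the JSON/count output is the contract.
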