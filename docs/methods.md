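# Methods

This note documents the models and procedures implemented in `skimtax`,
the parameter choices that matter, what the synthetic data do and do not
emulate, and the design decisions taken where the procedure admitted more
than one reading.

## Identity distances

`pairwise_distance` implements the identity-model p-distance on aligned
sequences. The default *strict-columns* dialect scores all columns:
a column is identical when both sequences carry the same character, with
gap/gap counting as identical and any ambiguity letter (anything outside
`{A,C,G,T,-}`) treated as `N`, which is never identical to anything —
including another `N`. This is deliberately conservative: crediting
`N == N` as a match would let low-quality sequence pairs look artificially
close. The *pairwise-deletion* dialect excludes columns where either
sequence has a gap or `N` and is the conventional barcoding p-distance; a
pair with zero comparable columns gets an undefined distance (`nan`),
which is reported and excluded from all downstream distributions. On
alignments without ambiguity codes, strict-columns coincides exactly with
classical full-column identity scoring, which the test suite uses as an
independent cross-check.

Length filtering upstream of distances counts *ungapped* positions
(neither `-` nor `N`) against a strict `>` threshold, because padded
barcode compilations have a constant aligned width that says nothing
about the biological read length. End trimming removes a fixed number of
5′ and 3′ alignment columns literally; the new width is always
`old − n5 − n3` and is logged so width expectations from a lab protocol
can be checked against what the arithmetic actually produces.

## Barcode gap and delimitation

The gap is learned on a training/test design: distances among established
*training* species are pooled (across species, matching the usual
single-pair-of-histograms presentation) into intraspecific and
interspecific distributions; any pair involving a focal *test* group is
held out. Each pool is summarised by Tukey's rule with quartiles by
linear interpolation at position `p·(n−1)` on the sorted values — the
common numerical default. Values outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
are flagged as outliers; with fewer than 4 values the fences are
statistically meaningless and the summary switches to a pass-through mode
that flags nothing (and says so in the log). Outlier flagging applies to
the training pools only; test distances are never discarded.

The gap bounds are the non-outlier extrema: `gap_lower` = largest
non-outlier intraspecific distance, `gap_upper` = smallest non-outlier
interspecific distance; the gap exists when `gap_lower < gap_upper`.
Without a gap no verdicts are issued (a `NoGapError`).

Verdicts summarise a test-group pair by the *median* of its cross
distances — robust to the sequence-length heterogeneity typical of
barcode compilations (`min`/`max` variants are exposed). A median
strictly below `gap_lower` is conspecific, strictly above `gap_upper`
heterospecific. Medians inside the closed gap interval are resolved by
distribution membership under the same fences: a value that is a
non-outlier of the interspecific distribution behaves like a
between-species distance even when it undercuts the smallest observed
training distance (with ~30 training species pairs, a fresh species pair
falls below the observed minimum regularly — that alone is not evidence
of anything), and symmetrically for the intraspecific side; neither-or-
both membership stays ambiguous. The delimitation report labels this
verdict rule an interpretation: field practice judges positions relative
to the histograms by eye, and any operational rule is a codification.

Measured behaviour under the default simulation conditions (below): the
gap is detected in effectively 100% of runs, and all between-group
verdicts are heterospecific in roughly 94–100% of 50-seed blocks; the
residual failures are pairs whose median lands slightly below the
interspecific lower fence — the intrinsic borderline of a three-way rule
when test divergence equals training divergence exactly.

## Gene-tree quality control

A taxon is *problematic* when its terminal branch length strictly exceeds
`mean + 2·sd` of the branch-length distribution (one-sided upper by
default — a long terminal branch is the standard mis-orthology /
contamination signal; a two-sided mode exists). The distribution uses all
branches of the tree by default (`--branches terminal` restricts it);
standard deviation is the sample SD (n−1); trees are used as given, with
no re-rooting, and the root edge is not part of the branch set. A gene is
dropped when its problematic fraction strictly exceeds 0.40.

One reading of this filter is internally impossible, and the
implementation takes a position: if the mean and SD come from the same
tree that is being tested, then by the one-sided Chebyshev bound at most
`1/(1+2²) = 20%` of the branch sample can exceed `mean + 2·sd`, and since
an n-taxon binary tree has ~2n branches, the problematic-taxon fraction
can never reach 40% — the drop rule would be dead code. `filter_genes`
therefore defaults to thresholds computed from branch lengths pooled
across the whole gene set (`stats="pooled"`), under which a gene whose
taxa are globally long-branched is correctly caught; `stats="per-tree"`
preserves the single-tree reading for diagnostics, and the per-tree
statistics functions keep their obvious per-tree meaning.

Concatenation matches sequences across genes by taxon id, gap-fills taxa
missing a gene with a block of `-` of that gene's width, and records each
gene's 1-based inclusive column span, exported in RAxML-style
`DNA, gene = start-end` lines. Input gene order defines column order;
fixing the taxon universe fixes row order, making the supermatrix
deterministic under shuffled input.

## Mitogenome extraction and identity

GenBank features of type CDS/tRNA/rRNA are sliced using the GenBank
coordinate convention (1-based, inclusive; `join()` parts concatenated in
annotation order; minus-strand features reverse-complemented after
joining). Names are canonicalised to the 37-gene mitochondrial
vocabulary via a tab-separated synonym table shipped with the package and
meant to be edited; unrecognised names are kept under the raw name with a
warning rather than failing the run, and two features mapping to one
canonical name are an error only when their spans overlap. The control
region is not a gene and is never extracted. Per-gene FASTA files are
unaligned on purpose — alignment is an external step — after which the
concatenator above builds the supermatrix as-is, without per-gene
trimming.

Whole-genome identity is defined on a pairwise alignment: identity =
identical-base columns / columns where both genomes carry a base; SNPs
are the differing both-base columns; indel columns are tallied
separately and never enter the identity denominator. The default aligner
is edlib (deterministic global edit-distance path); mafft is available,
and a precomputed alignment is accepted. The aligner is recorded in the
result because counts at the margins are alignment-dependent: an
edit-distance path may realise a substitution adjacent to a repeat as an
equal-cost indel pair, shifting a SNP or two into indel columns.

## Synthetic data

The generators are pure functions of their spec (which carries the seed)
and define the conditions the pipeline is validated under.

*Barcode alignments* — a uniform-random ancestral sequence; each species
ancestor diverges by independent per-site substitution at `p_inter`
(substitution = jump to a uniformly chosen different base: an
equal-rates, Jukes–Cantor-like step with no rate heterogeneity, no indels
and no codon structure); samples diverge from their ancestor at
`p_intra`. Defaults: 8 training species × 10 samples, 621 columns (the
width of a curated long-barcode subset), `p_intra = 0.005`,
`p_inter = 0.08`, three test groups of 10 at species-level divergence.
Two lineages one substitution pass `p` apart from a common ancestor then
differ per site with probability `2p(1−p) + (2/3)p²`; the tests verify
the simulated means against an independent per-site Markov-chain oracle.
Real COI data additionally carry length heterogeneity, ambiguity codes,
alignment error and rate variation across sites; passing on these
simulations shows the statistical machinery is correct, not that any
particular empirical dataset contains a gap.

*Gene trees* — balanced topologies with branch lengths uniform on
[0.05, 0.15]; rogue taxa have terminal branches scaled ×10; by default 3
of 20 genes carry 50% rogue taxa and the rest none. The truth record
lists the rogues and which genes must be dropped.

*Mock mitogenomes* — 37 gene blocks of typical insect lengths with the
usual minus-strand subset, random 0–20 nt spacers, and a feature table
that deliberately uses a few synonym spellings (`COI`, `tRNA-Phe`,
`16S ribosomal RNA`, ...). Derived taxa carry an exact planted number of
substitutions (default 80, on a ~15 kb genome ≈ 99.5% identity), keeping
feature coordinates valid across taxa.

## Numerical and degenerate-input choices

Quartiles: linear interpolation (`numpy` default). Threshold
comparisons: strict inequalities throughout ("longer than", "more than"),
so boundary values are never flagged/dropped. Fences may be negative;
distances are clamped nowhere. Empty distributions, ragged alignments,
trim overflows, missing branch lengths and out-of-range feature spans are
hard errors; sub-minimum survivor counts after filtering, unknown gene
names and undefined distances degrade with logged warnings and flags.
Problem sizes in the test suite and acceptance script (50-seed blocks,
110-sequence alignments, 20-gene sets, 3-taxon mock genome sets) were
chosen to make the stochastic properties measurable in seconds on one
core.

## Known limitations

- The delimitation verdict is a codified interpretation of a visual
  practice; the report flags it as such.
- The pooled-threshold gene filter presumes gene trees on comparable
  evolutionary scales; mixing markers with very different rates would
  need per-marker pooling.
- Identity/SNP counts inherit the tie-breaking of the chosen aligner
  (reported alongside the numbers).
- The simulators make no attempt at rate heterogeneity, indels,
  selection or sequencing error; they plant exactly the structure the
  analyses are designed to detect.
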