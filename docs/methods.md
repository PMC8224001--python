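# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `keramine`.

## Alignment statistics

The built-in backend is exact Smith–Waterman with affine gaps (BLOSUM62, gap
open 11, extend 1), run through Biopython's C pairwise aligner. Raw scores S
are converted to bit scores with the gapped Karlin–Altschul parameters
λ = 0.267, K = 0.041 — the standard blastp defaults for this scoring scheme —
as S′ = (λS − ln K)/ln 2, and E-values as E = m·n·2^(−S′) with m the query
length and n the subject length (single pair) or the total residue count of
the searched set (all-vs-all and reciprocal-best-hit searches). Percent
identity counts gap columns in the alignment-length denominator, the blastp
convention, so identities from imported 12-column tabular files and from the
built-in engine are comparable. Different gapped aligners can shift identity
by a few tenths of a percentage point; comparisons against externally
reported identities should use a ±0.5 point margin. E-value, never bit
score, is the thresholding statistic at every stage. The engine performs no
heuristic seeding; all-vs-all cost is quadratic in the number of sequences,
which is the intended scale here (hundreds of proteases, not proteome
databases).

## Mining, families, orthogroups

Keyword matching is plain case-insensitive substring search — no stemming or
regular expressions — because the keyword list is designed to hit compound
descriptions ("metallopeptidase" via "peptidase"). The multi-word keyword
"penicillin-binding protein" is matched as a whole phrase; the bare word
"protein" is never a trigger. Single-annotator hits are review-flagged
instead of excluded: automated exclusion would invent criteria that manual
curation does not define.

Family assignment is strict reciprocal best hit: a query takes the family of
reference R only if R is the query's best reference hit at E ≤ 10⁻²⁰ *and*
the query is R's best hit among all queries. Ties break by higher bit score,
then lexicographic reference id, making the assignment deterministic. With a
small reference set, strict reciprocity means at most one query per
reference sequence is assigned — supply several references per family (the
fixture generator writes three) when broader coverage is wanted.

P-orthogroups are connected components of the undirected graph whose edges
are alignment pairs with either directed E-value ≤ 10⁻⁴⁰, keeping components
of at least two members; this is the transparent, testable core of
orthogroup construction rather than a re-implementation of a full published
orthology inference stack (graph construction plus MCL), so exact group-count
parity with such tools is not claimed. Group ids order by decreasing size,
then smallest member id.

## Similarity network

Bidirectional hits collapse to one undirected edge carrying the minimum
E-value; the weight transform w = min(300, −log₁₀E), with E = 0 mapped to
300, is the standard sequence-similarity-network choice and can be switched
to unit weights. Louvain is greedy and order-dependent, so
`detect_communities` runs eight restarts with seeds derived deterministically
from the configured seed and keeps the highest-modularity partition; on
block-structured graphs of ≤ 10 nodes this reproduces the exhaustive-search
modularity optimum (oracle-tested), while a single greedy pass measurably
misses it on a few percent of graphs. "Keratinase-linked" means sharing a
community with a functional keratinase; a stricter direct-edge mode is
available. Panel sequences are nodes but never count toward query statistics.

## Localization features and embedding

The 14 features are the four PSORTb and four CELLO compartment scores
(cytoplasmic, cytoplasmic-membrane, cell wall, extracellular) plus six
SignalP-derived values: the SP(Sec/SPI), TAT(Tat/SPI), LIPO(Sec/SPII) and
OTHER probabilities, a derived signal-peptide possibility = SP + TAT + LIPO,
and a derived intracellular score = 1 − that sum. The two derived features
are not defined by the predictor itself; these formulas are this package's
reading and are stated here so they can be revisited. Proteins missing from
any predictor file are an error — no imputation.

Features are z-scored per column (zero-variance columns dropped with a
warning). PCA is computed on the standardized matrix, so eigenvectors are
those of the correlation structure; loadings are eigenvectors scaled by the
square root of their eigenvalues. t-SNE uses random initialization with the
configured seed, perplexity 30 and 1000 iterations; both coordinate sets are
min-max normalized, t-SNE to [0,1]². DBSCAN (Euclidean, eps 0.05,
min_samples 4) on the normalized plane defines t-SNE groups, renumbered
0..k−1 by decreasing size so labels are input-order invariant.

eps and min_samples have no externally fixed values; 0.05/4 were chosen so
that groups of a few dozen to ~100 points form on embedded sets of several
hundred proteins. Perplexity 30 and eps 0.05 are scale-coupled: on embedded
sets of fewer than ~150 points the perplexity approaches the cluster sizes
and t-SNE spreads large clusters until their internal point spacing
approaches eps, which can split them. Separability properties of the
generator are therefore assessed on a study-scale panel (695 points, 200
extracellular), where the extracellular/intracellular split is recovered at
ARI ≥ 0.99 across seeds; at the minimal end-to-end scenario scale (~90
points) group fragmentation can occur without affecting candidate recovery,
because selection only requires the keratinase-containing group to hold
together.

A t-SNE group is forwarded to phylogenetics when it contains at least one
functional-keratinase panel member. The per-protein extracellular flag in
the report is rule-based — extracellular wins either compartment predictor,
or signal-peptide possibility > 0.5 — and is informational; clade selection
uses group membership, not the flag.

## Phylogenetics and ancestral states

Alignment columns with occupancy (fraction of non-gap rows) below 0.70 are
removed; rows left all-gap are dropped with a warning. When no externally
inferred tree is supplied, a neighbor-joining tree is built on p-distances
of the compact alignment (pairs with no overlapping residue columns get
distance 1; negative NJ branch lengths are clamped to 0). NJ exists so the
pipeline runs self-contained; externally inferred maximum-likelihood trees
are the intended input for real analyses. Trees are midpoint rooted, ties
between equally long tip-to-tip paths breaking toward the lexicographically
smallest tip pair; an all-zero-length tree roots at the first preorder
internal node with a warning.

Ancestral reconstruction uses the k = 4 equal-rates Mk model over
{functional keratinase, keratinase-linked, three-strain, non-keratinase}.
The single rate q is fitted by bounded scalar maximization of the pruning
log-likelihood over log₁₀ q ∈ [−8, 3] with a flat root prior (the canonical
choice under ER symmetry). Marginal posteriors at every node are exact,
via an inside–outside pass with per-node scaling; they match brute-force
enumeration over all ancestral assignments to < 10⁻⁸ on ≤ 6-tip trees. An
optional stochastic-mapping mode draws seeded joint node-state histories
(root from its posterior, children conditionally on parents) and reports
empirical frequencies, which converge to the exact marginals; exact
marginals are the default because they are deterministic.

Clade selection: for every internal node, (1) the posterior probability of
functional-keratinase plus keratinase-linked must strictly exceed 0.5 (an
"either category alone" mode is available), (2) the subtree must contain a
functional-keratinase tip, (3) and a focal-strain tip. Nested selected
clades are subsumed by their maximal ancestor; candidates are the
focal-strain tips of maximal selected clades, deduplicated across groups.

## Synthetic data

`gen_families` plants divergent families: each family is an independent
random root sequence; members carry Poisson(length × divergence)
substitutions (no indels by default, so identity arithmetic stays exact; an
indel mode exercises gap handling). Background between-family identity is
the random expectation (~5%), so family pairs pass E ≤ 10⁻⁴⁰ and non-family
pairs sit orders of magnitude above even 10⁻⁵. The default scenario
("minimal": 12 families × 6 members across three strains, 240 residues,
divergence 0.04, panels of 10 keratinases and 8 non-keratinases, plus
non-protease decoy genes) plants: a keratinase-like family shared between
the panel and the strains (these members become keratinase-linked), an
extracellular localization profile on that family, two decoy families and a
few non-keratinases, and intracellular profiles elsewhere. The expected
candidate set — the focal-strain members of the keratinase-like family — is
recorded in the truth JSON and recovered exactly by the end-to-end run
across seeds. A "paper-shaped" preset scales to ~580 query proteases and
61/50 panels for study-scale experiments. Localization fixtures are drawn
with predictor-realistic peaked scores (e.g. a confident PSORTb call near
8.5–9 of 10) for one clearly extracellular and one clearly intracellular
profile class.

What the fixtures do *not* emulate: realistic protein evolution (no
site-rate heterogeneity, no indel-rich divergence, no selection), annotation
noise (descriptions are clean keyword carriers), correlated predictor errors
or membrane/cell-wall intermediate localization classes, and the long tail
of partial homology that makes real similarity networks messy. Passing the
planted-recovery suite therefore demonstrates the machinery is correct and
deterministic, not that real proteomes will yield equally clean candidate
sets.

## Problem sizes and determinism

Default test and acceptance runs use the minimal scenario (84 query proteins
+ 18 panel sequences; ~4,000 pairwise alignments), a 695-point localization
panel, 50 ASR oracle cases, 30 modularity oracle graphs and 20 rate-recovery
replicates of 200 tips — sizes chosen so the whole acceptance pass completes
in about a minute on one CPU while every check stays at full strength. One
config seed drives every stochastic component (t-SNE initialization, Louvain
restarts, fixture generation); identical inputs and seed reproduce
byte-identical artifacts.

## Known limitations

* Keyword mining inherits annotation quality; proteases annotated only as
  "hypothetical protein" are invisible to the pipeline.
* Strict RBH under-assigns families when the reference set is sparse.
* Connected-component orthogrouping cannot split chimeric components that a
  graph-clustering orthology tool would separate.
* The three-filter selection is rule-based by design; it reports an
  evidence-backed shortlist, not probabilities of keratinolytic function.
* The two real-data checks (identity to a deposited keratinase; community
  counts on the deposited proteomes) need the archived sequences locally and
  are skipped-as-failures until those files are fetched.
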