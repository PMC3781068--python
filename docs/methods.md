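# Methods

## Model and procedure

The association between two gene sets (or a gene set and a term set) is
measured on the abstract level.  Each gene contributes the set of PMIDs
citing it; each free-text term contributes the set of PMIDs whose title+body
match it.  With per-member abstract sets `A_1..A_m` and `B_1..B_n`,

- co-cited abstracts: `C = (∪ A_i) ∩ (∪ B_j)`, `N = |C|`
  (identical to `∪_{i,j} (A_i ∩ B_j)`; the implementation uses the union
  form, the test suite checks the identity against the pairwise form);
- co-citation impact: `CI = log2(N + 1)`.

The log transform compresses the contribution of star genes (heavily
studied genes with thousands of citations) and star papers (single abstracts
citing many query genes); star papers are additionally partitioned out of
the result list when cited by ≥ `star_threshold` (default 10) distinct query
genes.

Significance is by Monte Carlo permutation conditioned on query size:
`n_perm` (default 1000) gene sets of size |A| are drawn uniformly without
replacement from the gene universe of the query species — every gene present
in the citation index, zero-citation genes included — and scored against the
same fixed target sets.  The p-value is the tie-inclusive exceedance
fraction, reported at resolution `1/n_perm` (an exact zero is printed as
`< 1/n_perm`).  The background-adjusted CI is `CI_obs − mean(CI_random)`.
Term-Term comparisons report N and CI only: free text has no enumerable
universe to permute over.

Duplicate query genes are dropped before size matching.  Genes absent from
the index stay in the query with empty citation sets — they contribute
nothing to N but keep the permutation conditioned on the submitted set size.

### Background universe and the target set

In the Gene-Gene analysis the random sets stand in for *candidate query
sets distinct from the target*, so the target set's own genes are excluded
from the background draw (the observed query's genes are not).  A random
set containing a target gene has that gene's full citation set inside the
target union — it measures self-co-citation, not background.  Against a
genome-scale universe the exclusion is numerically irrelevant (drawing a
specific target gene is vanishingly rare); in the small universes used for
testing it is essential, because otherwise every p-value has a floor of
roughly |B|/|universe| per draw.  Homolog pooling, when a table is
supplied, is applied identically to observed and permuted sets, so the null
is not biased by the pooling step.

### Log base

The CI base is a monotone rescaling: p-values, rankings and ROC AUCs are
provably base-invariant (the permutation comparison is done on integer
counts).  Base 2 is the package convention; `base` is exposed on every
entry point and the invariance is asserted by tests rather than assumed.

## Citation index construction

- **gene2pubmed dialect**: tab-separated `tax_id, GeneID, PubMed_ID`, with
  or without a leading `#` header.  Malformed lines are counted and warned
  about; only an entirely invalid file is an error.
- **Expansion**: abstracts containing the exact two-word phrase
  `<SYMBOL> gene` (case-insensitive after tokenization, no insertions — the
  query is a literal phrase, favouring precision) are added per gene, ranked
  by symbol occurrence count descending then PMID ascending, capped at 500.
  Curated citations are never removed and are exempt from the cap; a PMID
  that is both curated and matched keeps curated provenance.
- **Homolog pooling**: citations are pooled across homolog groups restricted
  to human (9606), mouse (10090), fly (7227) and worm (6239), at query time
  for composability.  Queries from other species pass through with a
  warning.

## Text matching

Tokenization lowercases and splits on non-alphanumeric runs; no stemming,
no stop words — exact-token semantics is the reproducibility contract, and
known analyzer subtleties (possessives, acronym handling) are deliberately
out of scope.  A phrase matches when its tokens occur in order with at most
`max_insertions` (default 1) extra tokens inside **each** consecutive gap;
the budget is per gap, read distributively, not shared across the phrase.
Matching is implemented as a reachability sweep over token positions —
greedy earliest-match is incorrect here (term `a b c`, text `a b b x c`,
budget 1: only the second `b` reaches `c`) — and is defined by, and tested
against, the naive exhaustive scan.  Single-word terms reduce to token
membership.  Title and body are concatenated before matching.

## Fisher baseline, BH, ROC

The enrichment baseline is the one-sided hypergeometric tail (over-
representation) on gene overlap, computed with `scipy.stats.hypergeom`; the
default universe is all genes of the species in the index.  BH correction
uses the statsmodels step-up implementation; ROC curves and trapezoidal AUC
use scikit-learn with tied scores sharing a diagonal segment.  All three are
cross-checked in the test suite against hand enumeration, the step-up
formula applied by hand, and the Mann–Whitney rank statistic respectively.
ROC scores default to `1 − p` (size-adjusted); raw CI is available and, by
base invariance, gives the same AUC regardless of logarithm base.

## Synthetic corpora

The generator emulates the statistical structure the analyses assume, not
real English text:

- **Citation counts** per gene follow a truncated discrete power law
  `P(k) ∝ k^-α`, α = 1.8 by default (median 1–2 citations, long tail —
  most genes barely studied, a few stars).  The truncation point is
  `max_citation_frac` (default 0.1) of the corpus rather than the corpus
  size itself: no real citation index has single genes cited by most of the
  literature, and an uncapped tail lets one star gene blanket a small
  corpus and dominate every permutation null.
- **Planted modules**: each module reserves a block of abstracts
  (`module_block_frac`, default 10% of the corpus) representing its topical
  literature.  Within the block every member is cited with probability
  `min(1, ρ · c̄ / n_abstracts)`, where `c̄` is the corpus-average citation
  count — a pathway's literature cites its members symmetrically, so the
  planted rate is a property of the module, not of each member's individual
  fame (multiplying each member's own rate would leave median-count genes
  with no detectable signal at any realistic ρ).  ρ = 1 plants members at
  the average background rate, i.e. no enrichment; the calibration suite
  runs on that setting.  Block text embeds the module's phrase verbatim, so
  term search has recall 1 on module abstracts.
- **Abstract text**: filler tokens from a fixed bundled vocabulary (module
  phrase tokens removed from the filler for that corpus, so phrase matches
  have an exact ground truth), `<symbol> gene` phrases embedded for a random
  subset of citing genes, occasional bare symbol mentions to vary the
  expansion ranking.  Phrases are inserted as unbreakable chunks.
- **Homologs**: a fraction of genes (default 25%) get a second-species
  homolog with 1–3 citations of its own.
- Everything derives from one seeded `numpy` generator; identical spec and
  seed give bit-identical corpora, and the writers emit the same dialects
  the readers parse (round-trip tested).

What passing tests on these corpora do **not** show: robustness to real
Medline text (synonyms, abbreviations, negation), to curation noise in real
gene2pubmed snapshots, or to the much larger and sparser real universes —
the synthetic corpora are dense miniatures tuned for statistical shape, not
linguistic realism.

## Benchmark pair construction

Positive pairs are two random halves of a planted module (in `disjoint`
mode the halves share no genes) plus the module's phrase; negative pairs
are size-matched random background sets with the same phrase attached.  In
`disjoint` mode the negatives are also constructed pairwise-disjoint, so
gene overlap carries no information for either class and the Fisher
baseline sits at AUC 0.5 by construction — isolating exactly the property
under test, association without shared genes.  (Unconstrained negatives in
a 200-gene universe would overlap by chance and push Fisher *below* 0.5, a
small-universe artifact.)

## Problem sizes and defaults

Analyses and calibration run on 200-gene / 2000-abstract corpora: large
enough for heavy-tailed counts and a 10%-of-genes module, small enough that
the full pipeline (including 400×200 permutation draws for calibration and
the 80-pair benchmark at 200 permutations) completes in seconds.  Key
defaults: `n_perm` 1000, α (power law) 1.8, ρ 20 for planted scenarios,
star threshold 10, expansion cap 500, insertion budget 1.

## Known limitations

- The phrase matcher is a simplified analyzer; it does not reproduce
  possessive/acronym handling of production search engines.
- Index expansion scans a local abstract store only; there is no live
  E-utilities client, so expansion recall is bounded by the store.
- The permutation null conditions on set size but not on citation-count
  profile; with very small universes the discrete p-values are conservative.
- Term-Term results are descriptive (no significance), inherent to the
  unbounded term universe.
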