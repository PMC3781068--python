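"""Co-citation statistics between gene sets and term sets.

The association score is the co-citation impact

    CI(A, B) = log2(N + 1),

where ``N`` is the number of abstracts citing at least one member of set A
and at least one member of set B.  The log transform damps the influence of
heavily studied "star" genes and star papers.  Because

    N = | U_{i,j} (A_i ∩ B_j) | = | (U_i A_i) ∩ (U_j B_j) |,

the count is computed from the two set unions (the pairwise form is kept as
a test oracle).  Significance is assessed by Monte Carlo permutation:
size-matched gene sets are drawn uniformly from all genes of the query
species in the index, CI is recomputed against the same fixed target, and
the p-value is the fraction of random sets reaching the observed CI
(inclusive ties, hence conservative).  The background-adjusted CI is the
observed CI minus the mean random CI.

The log base is a monotone rescaling: it cannot change p-values or
rankings, only the scale of CI itself.  It is exposed as ``base`` anyway so
that this invariance is testable.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .corpus import CitationIndex, GeneSet, HomologTable, TermSet, merge_homolog_citations
from .textsearch import term_citations

__all__ = [
    "CoCitationResult",
    "GeneGeneResult",
    "OneToAllEntry",
    "cocitation_count",
    "ci_from_count",
    "permutation_test",
    "gene_gene_analysis",
    "gene_term_analysis",
    "term_term_analysis",
    "one_to_all",
    "split_star_papers",
    "DEFAULT_N_PERMUTATIONS",
    "DEFAULT_STAR_THRESHOLD",
]

DEFAULT_N_PERMUTATIONS = 1000
#: An abstract citing at least this many distinct query genes is a "star paper".
DEFAULT_STAR_THRESHOLD = 10


def cocitation_count(
    citations_a: Sequence[Set[int]], citations_b: Sequence[Set[int]]
) -> Tuple[int, FrozenSet[int]]:
    """Co-cited abstracts between two lists of per-gene/per-term PMID sets.

    Returns ``(N, cocited)`` where ``cocited = (U A_i) ∩ (U B_j)``, which is
    identical to the union of all pairwise intersections.
    """
    if len(citations_a) == 0 or len(citations_b) == 0:
        raise ValueError("citation lists must be nonempty")
    union_a: Set[int] = set().union(*citations_a)
    union_b: Set[int] = set().union(*citations_b)
    cocited = frozenset(union_a & union_b)
    return len(cocited), cocited


def ci_from_count(n: int, base: float = 2.0) -> float:
    """Co-citation impact log_base(N + 1); 0 iff N == 0, strictly increasing."""
    if n < 0:
        raise ValueError(f"abstract count must be nonnegative, got {n}")
    return math.log(n + 1) / math.log(base)


@dataclass(frozen=True)
class CoCitationResult:
    """Observed co-citation statistics plus the permutation background.

    ``p_value``, ``adjusted_ci`` and the random-CI moments are ``None`` for
    Term-Term analyses, where no gene universe exists to permute over.
    """

    n: int
    ci: float
    p_value: Optional[float]
    adjusted_ci: Optional[float]
    cocited_pmids: FrozenSet[int]
    star_pmids: FrozenSet[int]
    n_permutations: int
    random_ci_mean: Optional[float]
    random_ci_sd: Optional[float]
    seed: Optional[int]
    log_base: float = 2.0

    @property
    def p_value_text(self) -> str:
        """p formatted for reports; an exact zero is shown as a bound."""
        if self.p_value is None:
            return "NA"
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.p_value:g}"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "ci": self.ci,
            "p_value": self.p_value,
            "adjusted_ci": self.adjusted_ci,
            "cocited_pmids": sorted(self.cocited_pmids),
            "star_pmids": sorted(self.star_pmids),
            "n_permutations": self.n_permutations,
            "random_ci_mean": self.random_ci_mean,
            "random_ci_sd": self.random_ci_sd,
            "seed": self.seed,
            "log_base": self.log_base,
        }


@dataclass(frozen=True)
class OneToAllEntry:
    """Per-gene co-citation with the whole target set."""

    gene_id: str
    n: int
    ci: float
    rank: int
    cocited_pmids: FrozenSet[int]


@dataclass(frozen=True)
class GeneGeneResult:
    result: CoCitationResult
    one_to_all: Tuple[OneToAllEntry, ...]


def one_to_all(
    a_citations: Mapping[str, Set[int]],
    b_union: Set[int],
    base: float = 2.0,
) -> List[OneToAllEntry]:
    """Each query gene's co-citation with the union of the target set,
    ranked by CI descending (ties by gene identifier ascending)."""
    if not a_citations:
        raise ValueError("query citation map is empty")
    rows = []
    for gene_id in a_citations:
        cocited = frozenset(a_citations[gene_id] & b_union)
        n = len(cocited)
        rows.append((gene_id, n, ci_from_count(n, base), cocited))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return [
        OneToAllEntry(gene_id=g, n=n, ci=ci, rank=i + 1, cocited_pmids=co)
        for i, (g, n, ci, co) in enumerate(rows)
    ]


def split_star_papers(
    cocited: Set[int],
    a_citations: Mapping[str, Set[int]],
    threshold: int = DEFAULT_STAR_THRESHOLD,
) -> Tuple[Set[int], Set[int]]:
    """Partition co-cited abstracts into (regular, star).

    A star paper is cited by at least ``threshold`` distinct query genes;
    such abstracts can dominate raw counts and are listed separately.
    """
    if threshold < 1:
        raise ValueError(f"star threshold must be >= 1, got {threshold}")
    stars: Set[int] = set()
    for pmid in cocited:
        k = sum(1 for pmids in a_citations.values() if pmid in pmids)
        if k >= threshold:
            stars.add(pmid)
    return set(cocited) - stars, stars


def _universe_of(index: CitationIndex, tax_id: int) -> List[str]:
    return index.genes(tax_id)


def permutation_test(
    query: GeneSet,
    target_citations: Sequence[Set[int]],
    index: CitationIndex,
    homologs: Optional[HomologTable] = None,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    base: float = 2.0,
    star_threshold: int = DEFAULT_STAR_THRESHOLD,
    exclude_genes: Optional[Iterable[str]] = None,
) -> CoCitationResult:
    """Monte Carlo permutation significance of the query/target co-citation.

    ``n_perm`` size-matched gene sets are drawn uniformly, without
    replacement within a replicate, from all genes of the query species
    present in the index (zero-citation genes included).  Homolog pooling,
    when a table is given, is applied identically to the observed and the
    permuted sets so the null is unbiased.  The p-value counts random CIs
    reaching or exceeding the observed CI, at resolution ``1 / n_perm``.

    ``exclude_genes`` removes genes from the background universe.  The
    Gene-Gene analysis passes the target set here: a random set that happens
    to contain a target gene measures self-co-citation, not background, and
    while the effect is negligible against a genome-scale universe it
    dominates the null tail in small ones.  The observed query's own genes
    are never excluded.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if len(target_citations) == 0:
        raise ValueError("target citation list is empty")

    merged = merge_homolog_citations(index, homologs, query)
    n_obs, cocited = cocitation_count(list(merged.values()), list(target_citations))
    ci_obs = ci_from_count(n_obs, base)

    universe = _universe_of(index, query.tax_id)
    if exclude_genes is not None:
        dropped = {str(g) for g in exclude_genes}
        universe = [g for g in universe if g not in dropped]
    k = len(query.genes)
    if len(universe) < k:
        raise ValueError(
            f"gene universe for species {query.tax_id} has only "
            f"{len(universe)} genes; cannot draw size-{k} sets"
        )

    target_union: Set[int] = set().union(*target_citations)
    # Per-universe-gene citations restricted to the target union: the random
    # CI of a replicate is the size of the union of these small sets.
    universe_merged = merge_homolog_citations(
        index, homologs, GeneSet(tax_id=query.tax_id, genes=tuple(universe))
    )
    inter = [frozenset(universe_merged[g] & target_union) for g in universe]

    rng = np.random.default_rng(seed)
    n_universe = len(universe)
    rand_n = np.empty(n_perm, dtype=np.int64)
    for r in range(n_perm):
        picks = rng.choice(n_universe, size=k, replace=False)
        rand_n[r] = len(set().union(*(inter[i] for i in picks)))

    rand_ci = np.log(rand_n + 1) / math.log(base)
    # tie-inclusive on counts: CI is strictly monotone in N, so comparing
    # integer counts avoids float-equality pitfalls
    p_value = float(np.count_nonzero(rand_n >= n_obs)) / n_perm
    regular, stars = split_star_papers(cocited, merged, threshold=star_threshold)
    return CoCitationResult(
        n=n_obs,
        ci=ci_obs,
        p_value=p_value,
        adjusted_ci=ci_obs - float(rand_ci.mean()),
        cocited_pmids=frozenset(cocited),
        star_pmids=frozenset(stars),
        n_permutations=n_perm,
        random_ci_mean=float(rand_ci.mean()),
        random_ci_sd=float(rand_ci.std(ddof=1)) if n_perm > 1 else 0.0,
        seed=seed,
        log_base=base,
    )


def gene_gene_analysis(
    a: GeneSet,
    b: GeneSet,
    index: CitationIndex,
    homologs: Optional[HomologTable] = None,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    base: float = 2.0,
    star_threshold: int = DEFAULT_STAR_THRESHOLD,
) -> GeneGeneResult:
    """Gene-Gene association: query set A against target set B.

    B's (homolog-pooled) citation sets are the fixed target; permutation
    randomizes A only, drawing from the gene universe minus B (random sets
    stand in for candidate queries distinct from the target).  Includes the
    one-to-all listing of each A gene against the whole of B.
    """
    b_merged = merge_homolog_citations(index, homologs, b)
    target = list(b_merged.values())
    result = permutation_test(
        a, target, index, homologs=homologs, n_perm=n_perm, seed=seed,
        base=base, star_threshold=star_threshold, exclude_genes=b.genes,
    )
    a_merged = merge_homolog_citations(index, homologs, a)
    b_union: Set[int] = set().union(*target)
    listing = tuple(one_to_all(a_merged, b_union, base=base))
    return GeneGeneResult(result=result, one_to_all=listing)


def gene_term_analysis(
    a: GeneSet,
    terms: TermSet,
    index: CitationIndex,
    store,
    homologs: Optional[HomologTable] = None,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    base: float = 2.0,
    star_threshold: int = DEFAULT_STAR_THRESHOLD,
    species_filter: Optional[Set[int]] = None,
) -> CoCitationResult:
    """Gene-Term association: gene set A against free-text term matches.

    Each term's PMID set comes from a full-text scan of the store; the term
    sets form the fixed target and permutation randomizes the gene set only.
    Terms matching nothing trigger a warning, not an error.
    """
    target = [term_citations(t, store, species=species_filter) for t in terms.terms]
    if all(len(t) == 0 for t in target):
        warnings.warn("no term in the term set matches any abstract; N = 0")
    return permutation_test(
        a, target, index, homologs=homologs, n_perm=n_perm, seed=seed,
        base=base, star_threshold=star_threshold,
    )


def term_term_analysis(
    t1: TermSet,
    t2: TermSet,
    store,
    base: float = 2.0,
    species_filter: Optional[Set[int]] = None,
) -> CoCitationResult:
    """Term-Term co-citation: descriptive only.

    With an unlimited space of free-text terms there is no background
    universe to permute over, so no p-value or adjusted CI is reported.
    """
    if len(store) == 0:
        raise ValueError("abstract store is empty")
    sets1 = [term_citations(t, store, species=species_filter) for t in t1.terms]
    sets2 = [term_citations(t, store, species=species_filter) for t in t2.terms]
    n, cocited = cocitation_count(sets1, sets2)
    return CoCitationResult(
        n=n,
        ci=ci_from_count(n, base),
        p_value=None,
        adjusted_ci=None,
        cocited_pmids=frozenset(cocited),
        star_pmids=frozenset(),
        n_permutations=0,
        random_ci_mean=None,
        random_ci_sd=None,
        seed=None,
        log_base=base,
    )


# ------------------------------------------------------------------ output


def write_result_json(result: CoCitationResult, path, extra: Optional[dict] = None) -> None:
    payload = result.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_summary_tsv(result: CoCitationResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("N\tCI\tp_value\tadjusted_CI\n")
        adj = "NA" if result.adjusted_ci is None else f"{result.adjusted_ci:.4f}"
        fh.write(f"{result.n}\t{result.ci:.4f}\t{result.p_value_text}\t{adj}\n")


def write_paper_list_tsv(result: CoCitationResult, path) -> None:
    """Co-cited PMIDs, one per line; star papers are flagged and listed last."""
    regular = sorted(result.cocited_pmids - result.star_pmids)
    stars = sorted(result.star_pmids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("PMID\tstar\n")
        for pmid in regular:
            fh.write(f"{pmid}\tno\n")
        for pmid in stars:
            fh.write(f"{pmid}\tyes\n")


def write_one_to_all_tsv(entries: Sequence[OneToAllEntry], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tgene_id\tN\tCI\n")
        for e in entries:
            fh.write(f"{e.rank}\t{e.gene_id}\t{e.n}\t{e.ci:.4f}\n")
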