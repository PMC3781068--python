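"""Synthetic corpora with the statistical structure the analyses assume.

Real citation indexes are heavy-tailed: a few star genes are cited by
thousands of abstracts while most genes have only a handful of citations.
The generator draws per-gene citation counts from a truncated discrete power
law P(k) ∝ k^-α (default α = 1.8, giving a median of 1-2 citations and a
long tail), assigns abstracts uniformly at random, and then plants gene
modules: for each module a dedicated block of abstracts is reserved in which
every member gene is cited with its baseline per-abstract rate multiplied by
an enrichment factor ρ, and whose text embeds the module's term phrase
verbatim.  ρ = 1 collapses to the null (the module is indistinguishable
from background), which is what the calibration tests run on.

Abstract bodies are filler tokens from a fixed vocabulary, with
"<SYMBOL> gene" phrases embedded for a random subset of the citing genes
(so index expansion is exercisable) plus occasional bare symbol mentions
(so the occurrence-count ranking has variation).  A random fraction of
genes gets a second-species homolog with a few citations of its own, so
homolog pooling is exercisable too.

Everything is driven by one ``numpy`` generator: identical spec + seed give
an identical corpus, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._vocab import FILLER_WORDS
from .corpus import (
    AbstractRecord,
    AbstractStore,
    CitationIndex,
    GeneSet,
    HomologTable,
    TermSet,
    write_gene2pubmed,
    write_homologene,
)
from .textsearch import tokenize

__all__ = [
    "ModuleSpec",
    "CorpusSpec",
    "SyntheticCorpus",
    "sample_citation_counts",
    "generate_corpus",
    "generate_benchmark_pairs",
    "write_corpus",
]

PMID_BASE = 1_000_000


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene module: members co-cited above baseline in a dedicated
    abstract block whose text carries ``phrase`` verbatim."""

    members: Tuple[str, ...]
    phrase: str
    rho: float = 20.0

    def __post_init__(self):
        if self.rho < 1:
            raise ValueError(f"enrichment factor rho must be >= 1, got {self.rho}")
        if not self.members:
            raise ValueError("module has no members")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus."""

    n_genes: int = 200
    n_abstracts: int = 2000
    tax_id: int = 9606
    alpha: float = 1.8
    modules: Tuple[ModuleSpec, ...] = ()
    seed: int = 0
    #: fraction of abstracts reserved per module as its co-citation block
    module_block_frac: float = 0.1
    #: fraction of genes given a homolog in ``homolog_tax_id``
    homolog_fraction: float = 0.25
    homolog_tax_id: int = 10090
    #: per-citing-gene probability of embedding "<SYMBOL> gene" in the text
    symbol_embed_prob: float = 0.5
    #: per-citing-gene probability of an extra bare symbol mention
    bare_symbol_prob: float = 0.15
    #: cap on one gene's citation count, as a fraction of the corpus.  Real
    #: citation indexes never have a gene cited by most of the literature
    #: (well under 0.1% of genes exceed 500 citations of ~1.6M abstracts);
    #: an uncapped draw would let one star gene blanket a small synthetic
    #: corpus and degenerate the permutation null.
    max_citation_frac: float = 0.1

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.n_abstracts < 10:
            raise ValueError("need at least 10 abstracts")
        gene_ids = {str(i) for i in range(1, self.n_genes + 1)}
        for mod in self.modules:
            extra = set(mod.members) - gene_ids
            if extra:
                raise ValueError(f"module members outside the gene universe: {sorted(extra)}")

    @property
    def gene_ids(self) -> Tuple[str, ...]:
        return tuple(str(i) for i in range(1, self.n_genes + 1))


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its ground truth."""

    spec: CorpusSpec
    index: CitationIndex
    store: AbstractStore
    homologs: HomologTable
    symbols: Dict[str, str]
    truth: dict = field(default_factory=dict)


def sample_citation_counts(
    n_genes: int, alpha: float, k_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-gene citation counts from P(k) ∝ k^-alpha on 1..k_max."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k = np.arange(1, k_max + 1, dtype=float)
    pmf = k**-alpha
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, k_max + 1), size=n_genes, p=pmf)


def power_law_cdf(alpha: float, k_max: int) -> np.ndarray:
    """CDF of the truncated discrete power law, for distribution checks."""
    k = np.arange(1, k_max + 1, dtype=float)
    pmf = k**-alpha
    pmf /= pmf.sum()
    return np.cumsum(pmf)


def _symbol(gene_id: str) -> str:
    return f"gs{gene_id}"


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate (CitationIndex, AbstractStore, HomologTable, truth) per spec."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    n_abs = spec.n_abstracts
    pmids = [PMID_BASE + i for i in range(n_abs)]

    k_max = max(1, round(spec.max_citation_frac * n_abs))
    counts = sample_citation_counts(spec.n_genes, spec.alpha, k_max, rng)
    # baseline: each gene cites `count` abstracts uniformly without replacement
    citing: Dict[int, Set[str]] = {p: set() for p in pmids}  # pmid -> citing genes
    gene_cites: Dict[str, Set[int]] = {g: set() for g in genes}
    for g, c in zip(genes, counts):
        for j in rng.choice(n_abs, size=int(c), replace=False):
            pmid = pmids[j]
            gene_cites[g].add(pmid)
            citing[pmid].add(g)

    # planted modules: reserve disjoint abstract blocks
    block_size = max(10, round(spec.module_block_frac * n_abs))
    available = list(range(n_abs))
    truth_modules = []
    count_of = {g: int(c) for g, c in zip(genes, counts)}
    for mod in spec.modules:
        if block_size > len(available):
            raise ValueError("not enough abstracts left for a module block")
        chosen = rng.choice(len(available), size=block_size, replace=False)
        block_idx = [available[i] for i in sorted(chosen)]
        available = [a for i, a in enumerate(available) if i not in set(chosen)]
        block_pmids = [pmids[i] for i in block_idx]
        # A module's literature cites its members symmetrically: each member
        # appears in a block abstract at rho times the corpus-average
        # per-abstract citation rate, not its own (often tiny) rate.
        mean_rate = float(counts.mean()) / n_abs
        for g in mod.members:
            p_hit = min(1.0, mod.rho * mean_rate)
            hits = rng.random(block_size) < p_hit
            for pmid, h in zip(block_pmids, hits):
                if h:
                    gene_cites[g].add(pmid)
                    citing[pmid].add(g)
        truth_modules.append(
            {
                "members": list(mod.members),
                "phrase": mod.phrase,
                "rho": mod.rho,
                "block_pmids": block_pmids,
            }
        )

    # homologs in a second species, with small citation sets of their own
    n_hom = int(round(spec.homolog_fraction * spec.n_genes))
    hom_idx = rng.choice(spec.n_genes, size=n_hom, replace=False) if n_hom else np.array([], int)
    hom_pairs: List[Tuple[str, str]] = []
    hom_cites: Dict[str, Set[int]] = {}
    mouse_citing: Dict[int, bool] = {}
    for i in sorted(hom_idx):
        g = genes[i]
        mg = str(10_000 + int(g))
        n_extra = int(rng.integers(1, 4))
        extra = {pmids[j] for j in rng.choice(n_abs, size=n_extra, replace=False)}
        hom_pairs.append((g, mg))
        hom_cites[mg] = extra
        for p in extra:
            mouse_citing[p] = True

    # abstract text: filler chunks + planted symbol/gene phrases + module phrase
    phrase_tokens = {t for m in spec.modules for t in tokenize(m.phrase)}
    vocab = tuple(w for w in FILLER_WORDS if w not in phrase_tokens)
    records = []
    module_of_pmid: Dict[int, str] = {}
    for tm in truth_modules:
        for p in tm["block_pmids"]:
            module_of_pmid[p] = tm["phrase"]
    for j, pmid in enumerate(pmids):
        n_fill = int(rng.integers(25, 60))
        chunks: List[Tuple[str, ...]] = [
            (vocab[i],) for i in rng.integers(0, len(vocab), size=n_fill)
        ]
        for g in sorted(citing[pmid]):
            if rng.random() < spec.symbol_embed_prob:
                chunks.append((_symbol(g), "gene"))
            if rng.random() < spec.bare_symbol_prob:
                chunks.append((_symbol(g),))
        phrase = module_of_pmid.get(pmid)
        if phrase is not None:
            chunks.append(tuple(tokenize(phrase)))
        order = rng.permutation(len(chunks))
        body_tokens = [tok for i in order for tok in chunks[i]]
        title_tokens = [vocab[i] for i in rng.integers(0, len(vocab), size=4)]
        tax_ids = {spec.tax_id}
        if mouse_citing.get(pmid):
            tax_ids.add(spec.homolog_tax_id)
        records.append(
            AbstractRecord(
                pmid=pmid,
                title=" ".join(title_tokens),
                body=" ".join(body_tokens),
                tax_ids=frozenset(tax_ids),
            )
        )
    store = AbstractStore(records)

    index = CitationIndex()
    for g in genes:
        index.add(spec.tax_id, g, gene_cites[g], provenance="curated")
    for mg, extra in hom_cites.items():
        index.add(spec.homolog_tax_id, mg, extra, provenance="curated")

    homologs = HomologTable(
        groups={
            f"h{i + 1}": frozenset({(spec.tax_id, g), (spec.homolog_tax_id, mg)})
            for i, (g, mg) in enumerate(hom_pairs)
        }
    )
    symbols = {g: _symbol(g) for g in genes}
    truth = {
        "tax_id": spec.tax_id,
        "genes": list(genes),
        "counts": count_of,
        "modules": truth_modules,
        "homolog_pairs": hom_pairs,
        "seed": spec.seed,
    }
    return SyntheticCorpus(
        spec=spec, index=index, store=store, homologs=homologs, symbols=symbols, truth=truth
    )


def generate_benchmark_pairs(
    corpus: SyntheticCorpus,
    n_pos: int,
    n_neg: int,
    overlap_mode: str = "disjoint",
    seed: int = 0,
):
    """Labeled gene-set pairs for ROC benchmarking.

    Positives: two random halves of one planted module (in ``disjoint`` mode
    the halves never share a gene), plus that module's term phrase.
    Negatives: size-matched random background gene sets (also pairwise
    disjoint in ``disjoint`` mode) with the same term phrase attached, so
    the term itself carries no label information for a random gene set.
    """
    from .benchmark import BenchmarkPair  # local import avoids a cycle

    if overlap_mode not in {"disjoint", "overlapping"}:
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    modules = corpus.truth["modules"]
    if not modules:
        raise ValueError("corpus truth has no planted module")
    rng = np.random.default_rng(seed)
    tax_id = corpus.truth["tax_id"]
    genes = list(corpus.truth["genes"])
    half = len(modules[0]["members"]) // 2
    if half < 1:
        raise ValueError("module too small to split")

    pairs = []
    for i in range(n_pos):
        mod = modules[i % len(modules)]
        members = list(mod["members"])
        if overlap_mode == "disjoint":
            perm = rng.permutation(len(members))
            a = [members[j] for j in perm[:half]]
            b = [members[j] for j in perm[half : 2 * half]]
        else:
            a = [members[j] for j in rng.choice(len(members), size=half, replace=False)]
            b = [members[j] for j in rng.choice(len(members), size=half, replace=False)]
        pairs.append(
            BenchmarkPair(
                pair_id=f"pos{i + 1}",
                label="positive",
                set_a=GeneSet(tax_id=tax_id, genes=tuple(a), label=f"pos{i + 1}a"),
                set_b=GeneSet(tax_id=tax_id, genes=tuple(b), label=f"pos{i + 1}b"),
                terms=TermSet(terms=(mod["phrase"],), label=f"pos{i + 1}t"),
            )
        )
    for i in range(n_neg):
        mod = modules[i % len(modules)]
        if overlap_mode == "disjoint":
            perm = rng.permutation(len(genes))
            a = [genes[j] for j in perm[:half]]
            b = [genes[j] for j in perm[half : 2 * half]]
        else:
            a = [genes[j] for j in rng.choice(len(genes), size=half, replace=False)]
            b = [genes[j] for j in rng.choice(len(genes), size=half, replace=False)]
        pairs.append(
            BenchmarkPair(
                pair_id=f"neg{i + 1}",
                label="negative",
                set_a=GeneSet(tax_id=tax_id, genes=tuple(a), label=f"neg{i + 1}a"),
                set_b=GeneSet(tax_id=tax_id, genes=tuple(b), label=f"neg{i + 1}b"),
                terms=TermSet(terms=(mod["phrase"],), label=f"neg{i + 1}t"),
            )
        )
    return pairs


def write_corpus(corpus: SyntheticCorpus, outdir) -> Dict[str, Path]:
    """Write the corpus in the same dialects the readers consume.

    Produces gene2pubmed.tsv, abstracts.jsonl, homologene.data, symbols.tsv
    and truth.json; returns the path of each.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene2pubmed": outdir / "gene2pubmed.tsv",
        "abstracts": outdir / "abstracts.jsonl",
        "homologene": outdir / "homologene.data",
        "symbols": outdir / "symbols.tsv",
        "truth": outdir / "truth.json",
    }
    write_gene2pubmed(corpus.index, paths["gene2pubmed"])
    corpus.store.to_jsonl(paths["abstracts"])
    write_homologene(corpus.homologs, paths["homologene"])
    with open(paths["symbols"], "w", encoding="utf-8") as fh:
        for g in sorted(corpus.symbols, key=lambda x: int(x)):
            fh.write(f"{g}\t{corpus.symbols[g]}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(corpus.truth, fh, indent=2)
        fh.write("\n")
    for i, mod in enumerate(corpus.truth["modules"]):
        mod_path = outdir / f"module{i + 1}.genes.txt"
        with open(mod_path, "w", encoding="utf-8") as fh:
            fh.write(f"taxid:{corpus.truth['tax_id']}\n")
            for g in mod["members"]:
                fh.write(f"{g}\n")
        paths[f"module{i + 1}"] = mod_path
    return paths
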