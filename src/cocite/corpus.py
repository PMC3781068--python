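"""Gene-to-literature citation index and its supporting resources.

The central object is the :class:`CitationIndex`, a per-species map from a
gene identifier to the set of PubMed abstract identifiers (PMIDs) citing it,
built from NCBI ``gene2pubmed``-style tables.  Around it sit:

* :class:`AbstractStore` — PMID → title/abstract text plus species tags,
  read from JSON-lines or NCBI Medline flat files; the substrate for free
  text search and for index expansion.
* :class:`HomologTable` — NCBI ``homologene.data``-style groups used to pool
  citations across the four heavily studied model organisms (human 9606,
  mouse 10090, fly 7227, worm 6239).
* :func:`expand_index` — supplements curated citations with abstracts that
  literally contain the two-word phrase "<SYMBOL> gene" (e.g. "AKT1 gene"),
  capped at 500 best-matched records per gene.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

from .textsearch import match_phrase, tokenize

__all__ = [
    "AbstractRecord",
    "AbstractStore",
    "CitationIndex",
    "HomologTable",
    "GeneSet",
    "TermSet",
    "DEFAULT_RESTRICTED_SPECIES",
    "read_gene2pubmed",
    "write_gene2pubmed",
    "read_homologene",
    "write_homologene",
    "read_abstracts",
    "expand_index",
    "merge_homolog_citations",
]

#: Human, mouse, fly, worm — the species whose literature is pooled.
DEFAULT_RESTRICTED_SPECIES: FrozenSet[int] = frozenset({9606, 10090, 7227, 6239})


@dataclass(frozen=True)
class AbstractRecord:
    """One searchable abstract: PMID, title, body, species tags."""

    pmid: int
    title: str
    body: str
    tax_ids: FrozenSet[int] = frozenset()


class AbstractStore:
    """In-memory PMID → :class:`AbstractRecord` map with a token cache."""

    def __init__(self, records: Iterable[AbstractRecord] = ()):
        self._records: Dict[int, AbstractRecord] = {}
        self._tokens: Dict[int, List[str]] = {}
        self._token_sets: Dict[int, FrozenSet[str]] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: AbstractRecord) -> None:
        if record.pmid in self._records:
            raise ValueError(f"duplicate PMID {record.pmid}")
        self._records[record.pmid] = record

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, pmid: int) -> bool:
        return pmid in self._records

    def __iter__(self) -> Iterator[AbstractRecord]:
        return iter(self._records.values())

    def get(self, pmid: int) -> Optional[AbstractRecord]:
        return self._records.get(pmid)

    @property
    def pmids(self) -> List[int]:
        return sorted(self._records)

    def tokens(self, pmid: int) -> List[str]:
        """Tokenized title+body of one abstract (cached)."""
        toks = self._tokens.get(pmid)
        if toks is None:
            rec = self._records[pmid]
            toks = tokenize(rec.title + " " + rec.body)
            self._tokens[pmid] = toks
        return toks

    def token_set(self, pmid: int) -> FrozenSet[str]:
        ts = self._token_sets.get(pmid)
        if ts is None:
            ts = frozenset(self.tokens(pmid))
            self._token_sets[pmid] = ts
        return ts

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_jsonl(cls, path) -> "AbstractStore":
        store = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                store.add(
                    AbstractRecord(
                        pmid=int(obj["pmid"]),
                        title=str(obj.get("title", "")),
                        body=str(obj.get("abstract", "")),
                        tax_ids=frozenset(int(t) for t in obj.get("tax_ids", [])),
                    )
                )
        return store

    @classmethod
    def from_medline(cls, path) -> "AbstractStore":
        """Read an NCBI Medline flat file (PMID/TI/AB fields) via Biopython."""
        from Bio import Medline

        store = cls()
        with open(path, encoding="utf-8") as fh:
            for rec in Medline.parse(fh):
                pmid = rec.get("PMID")
                if pmid is None:
                    continue
                store.add(
                    AbstractRecord(
                        pmid=int(pmid),
                        title=rec.get("TI", "") or "",
                        body=rec.get("AB", "") or "",
                    )
                )
        return store

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for pmid in self.pmids:
                rec = self._records[pmid]
                fh.write(
                    json.dumps(
                        {
                            "pmid": rec.pmid,
                            "title": rec.title,
                            "abstract": rec.body,
                            "tax_ids": sorted(rec.tax_ids),
                        }
                    )
                    + "\n"
                )


def read_abstracts(path) -> AbstractStore:
    """Load an abstract store, auto-detecting the dialect by extension.

    ``.jsonl``/``.ndjson``/``.json`` → JSON-lines; anything else is treated
    as an NCBI Medline flat file.
    """
    suffix = Path(path).suffix.lower()
    if suffix in {".jsonl", ".ndjson", ".json"}:
        return AbstractStore.from_jsonl(path)
    return AbstractStore.from_medline(path)


class CitationIndex:
    """Per-species gene → PMID-set map with per-PMID provenance.

    Entries carry "curated" provenance when they come straight from a
    gene2pubmed table and "expanded" when added by :func:`expand_index`.
    Lookups for absent genes return the empty set, never fail.
    """

    def __init__(self):
        self._curated: Dict[Tuple[int, str], Set[int]] = {}
        self._expanded: Dict[Tuple[int, str], Set[int]] = {}
        self.n_malformed: int = 0

    def add(self, tax_id: int, gene_id: str, pmids: Iterable[int], provenance: str = "curated") -> None:
        key = (int(tax_id), str(gene_id))
        if provenance == "curated":
            self._curated.setdefault(key, set()).update(int(p) for p in pmids)
        elif provenance == "expanded":
            self._expanded.setdefault(key, set()).update(int(p) for p in pmids)
        else:
            raise ValueError(f"unknown provenance {provenance!r}")

    def citations(self, tax_id: int, gene_id: str) -> Set[int]:
        key = (int(tax_id), str(gene_id))
        return self._curated.get(key, set()) | self._expanded.get(key, set())

    def curated(self, tax_id: int, gene_id: str) -> Set[int]:
        return set(self._curated.get((int(tax_id), str(gene_id)), set()))

    def expanded(self, tax_id: int, gene_id: str) -> Set[int]:
        return set(self._expanded.get((int(tax_id), str(gene_id)), set()))

    def genes(self, tax_id: int) -> List[str]:
        """All gene identifiers of one species, deterministically ordered."""
        tax_id = int(tax_id)
        seen = {g for t, g in self._curated if t == tax_id}
        seen |= {g for t, g in self._expanded if t == tax_id}
        return sorted(seen)

    def species(self) -> Set[int]:
        return {t for t, _ in self._curated} | {t for t, _ in self._expanded}

    def __len__(self) -> int:
        return len(set(self._curated) | set(self._expanded))

    def copy(self) -> "CitationIndex":
        new = CitationIndex()
        new._curated = {k: set(v) for k, v in self._curated.items()}
        new._expanded = {k: set(v) for k, v in self._expanded.items()}
        new.n_malformed = self.n_malformed
        return new


def read_gene2pubmed(path) -> CitationIndex:
    """Read an NCBI gene2pubmed-style table (tax_id, GeneID, PubMed_ID).

    An optional leading ``#`` header line is accepted.  Malformed lines are
    counted on ``index.n_malformed`` and reported as a warning; the read only
    fails if no line at all is valid.
    """
    index = CitationIndex()
    n_valid = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                tax_id = int(parts[0])
                gene_id = parts[1].strip()
                pmid = int(parts[2])
                if not gene_id:
                    raise ValueError
            except (ValueError, IndexError):
                index.n_malformed += 1
                continue
            index.add(tax_id, gene_id, [pmid], provenance="curated")
            n_valid += 1
    if n_valid == 0:
        raise ValueError(f"no valid gene2pubmed records in {path}")
    if index.n_malformed:
        warnings.warn(f"{index.n_malformed} malformed line(s) skipped in {path}")
    return index


def write_gene2pubmed(index: CitationIndex, path) -> None:
    """Write all entries (curated and expanded pooled) as a gene2pubmed TSV."""
    rows = []
    for tax_id in sorted(index.species()):
        for gene_id in index.genes(tax_id):
            for pmid in sorted(index.citations(tax_id, gene_id)):
                rows.append((tax_id, gene_id, pmid))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#tax_id\tGeneID\tPubMed_ID\n")
        for tax_id, gene_id, pmid in rows:
            fh.write(f"{tax_id}\t{gene_id}\t{pmid}\n")


@dataclass(frozen=True)
class HomologTable:
    """Homolog groups: group id → set of (tax_id, gene_id) members.

    Species outside ``restricted`` (default: human, mouse, fly, worm) stay in
    the table but are ignored when citations are pooled.
    """

    groups: Mapping[str, FrozenSet[Tuple[int, str]]]
    restricted: FrozenSet[int] = DEFAULT_RESTRICTED_SPECIES
    _member_to_group: Dict[Tuple[int, str], str] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self):
        for gid, members in self.groups.items():
            for member in members:
                self._member_to_group.setdefault(member, gid)

    def group_of(self, tax_id: int, gene_id: str) -> Optional[FrozenSet[Tuple[int, str]]]:
        gid = self._member_to_group.get((int(tax_id), str(gene_id)))
        return None if gid is None else self.groups[gid]

    def __len__(self) -> int:
        return len(self.groups)


def read_homologene(path, restricted: Iterable[int] = DEFAULT_RESTRICTED_SPECIES) -> HomologTable:
    """Read a homologene.data-style table; only columns 1-3 are consumed.

    A (tax, gene) pair joining more than one group keeps its first group.
    """
    groups: Dict[str, Set[Tuple[int, str]]] = {}
    assigned: Set[Tuple[int, str]] = set()
    n_valid = 0
    n_malformed = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                hid = parts[0].strip()
                tax_id = int(parts[1])
                gene_id = parts[2].strip()
                if not hid or not gene_id:
                    raise ValueError
            except (ValueError, IndexError):
                n_malformed += 1
                continue
            member = (tax_id, gene_id)
            if member in assigned:
                continue
            assigned.add(member)
            groups.setdefault(hid, set()).add(member)
            n_valid += 1
    if n_valid == 0:
        raise ValueError(f"no valid homologene records in {path}")
    if n_malformed:
        warnings.warn(f"{n_malformed} malformed line(s) skipped in {path}")
    return HomologTable(
        groups={k: frozenset(v) for k, v in groups.items()},
        restricted=frozenset(restricted),
    )


def write_homologene(table: HomologTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for hid in sorted(table.groups):
            for tax_id, gene_id in sorted(table.groups[hid]):
                fh.write(f"{hid}\t{tax_id}\t{gene_id}\t{gene_id}\t0\tNA\n")


@dataclass(frozen=True)
class GeneSet:
    """An ordered, deduplicated list of gene identifiers for one species."""

    tax_id: int
    genes: Tuple[str, ...]
    label: Optional[str] = None

    def __post_init__(self):
        deduped = tuple(dict.fromkeys(str(g) for g in self.genes if str(g).strip()))
        object.__setattr__(self, "genes", deduped)
        if not deduped:
            raise ValueError("gene set is empty after validation")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_file(cls, path, tax_id: Optional[int] = None, label: Optional[str] = None) -> "GeneSet":
        """One identifier per line; an optional first line ``taxid:<int>``
        overrides the ``tax_id`` argument."""
        genes: List[str] = []
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if i == 0 and line.lower().startswith("taxid:"):
                    tax_id = int(line.split(":", 1)[1])
                    continue
                genes.append(line)
        if tax_id is None:
            raise ValueError(f"no species: {path} has no 'taxid:' header and none was given")
        return cls(tax_id=int(tax_id), genes=tuple(genes), label=label or Path(path).stem)


@dataclass(frozen=True)
class TermSet:
    """An ordered list of free-text terms, deduplicated case-insensitively."""

    terms: Tuple[str, ...]
    label: Optional[str] = None

    def __post_init__(self):
        seen: Dict[str, str] = {}
        for t in self.terms:
            t = str(t).strip()
            if t and t.lower() not in seen:
                seen[t.lower()] = t
        object.__setattr__(self, "terms", tuple(seen.values()))
        if not self.terms:
            raise ValueError("term set is empty after validation")

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_file(cls, path, label: Optional[str] = None) -> "TermSet":
        with open(path, encoding="utf-8") as fh:
            terms = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        return cls(terms=tuple(terms), label=label or Path(path).stem)


def _count_occurrences(haystack: List[str], needle: List[str]) -> int:
    if len(needle) == 1:
        return haystack.count(needle[0])
    n = len(needle)
    return sum(1 for i in range(len(haystack) - n + 1) if haystack[i : i + n] == needle)


def expand_index(
    index: CitationIndex,
    store: AbstractStore,
    symbols: Mapping[str, str],
    cap: int = 500,
    tax_id: int = 9606,
) -> CitationIndex:
    """Supplement curated citations with abstracts containing "<SYMBOL> gene".

    For each gene the store is scanned for the exact two-word phrase formed
    by the official symbol followed by the word "gene" (case-insensitive
    after tokenization, no insertions allowed).  Matches are ranked by the
    number of occurrences of the symbol in the abstract (descending), ties by
    PMID ascending, and at most ``cap`` are kept as "expanded" citations.
    Curated citations are never removed and do not count toward the cap.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if not symbols:
        raise ValueError("symbols map is empty")
    result = index.copy()
    for gene_id, symbol in symbols.items():
        sym_tokens = tokenize(symbol)
        if not sym_tokens:
            continue
        phrase = sym_tokens + ["gene"]
        matched: List[Tuple[int, int]] = []  # (-occurrences, pmid)
        for rec in store:
            toks = store.tokens(rec.pmid)
            if sym_tokens[0] not in store.token_set(rec.pmid):
                continue
            if match_phrase(phrase, toks, max_insertions=0):
                matched.append((-_count_occurrences(toks, sym_tokens), rec.pmid))
        if not matched:
            continue
        matched.sort()
        top = [pmid for _, pmid in matched[:cap]]
        curated = result.curated(tax_id, gene_id)
        new = [p for p in top if p not in curated]
        if new:
            result.add(tax_id, gene_id, new, provenance="expanded")
    return result


def merge_homolog_citations(
    index: CitationIndex,
    homologs: Optional[HomologTable],
    gene_set: GeneSet,
) -> Dict[str, Set[int]]:
    """Pool each query gene's citations with those of its homologs.

    Only the table's restricted species (human/mouse/fly/worm by default)
    contribute.  A query from a species outside that list is passed through
    unchanged with a warning.  Genes without a homolog group, or absent from
    the index entirely, keep their own (possibly empty) citation set.
    """
    tax_id = gene_set.tax_id
    if homologs is None:
        return {g: index.citations(tax_id, g) for g in gene_set.genes}
    if tax_id not in homologs.restricted:
        warnings.warn(
            f"species {tax_id} is outside the homolog-pooled species list; "
            "citations are used as-is"
        )
        return {g: index.citations(tax_id, g) for g in gene_set.genes}
    out: Dict[str, Set[int]] = {}
    for g in gene_set.genes:
        group = homologs.group_of(tax_id, g)
        if group is None:
            out[g] = index.citations(tax_id, g)
        else:
            pooled: Set[int] = set()
            for t, gid in group:
                if t in homologs.restricted:
                    pooled |= index.citations(t, gid)
            # monotone: the query gene's own citations are always included
            pooled |= index.citations(tax_id, g)
            out[g] = pooled
    return out
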