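"""Full-text matching of free-text terms against abstract text.

The matching contract is deliberately simple and fully specified, so that
term-citation sets are reproducible across machines:

* :func:`tokenize` lowercases and splits on runs of non-alphanumeric
  characters; there is no stemming and no stop-word removal.
* :func:`match_phrase` reports whether a multi-word term occurs in an
  abstract with at most ``max_insertions`` extra tokens between **each**
  consecutive pair of term words (default one insertion, so "disease
  resistance" matches "disease and resistance" but not "disease of the
  resistance").  A single-word term reduces to token membership.
* :func:`term_citations` applies the matcher to every abstract of a store,
  title and body concatenated.

An inverted token→positions map is built per abstract; correctness is
defined by (and tested against) the naive per-window scan.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from typing import Iterable, List, Optional, Sequence, Set

__all__ = ["tokenize", "match_phrase", "term_citations"]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> List[str]:
    """Split free text into lowercase alphanumeric tokens.

    >>> tokenize("Wnt-protein binding.")
    ['wnt', 'protein', 'binding']
    >>> tokenize("p53/TP53")
    ['p53', 'tp53']
    """
    return _TOKEN_RE.findall(text.lower())


def match_phrase(
    term_tokens: Sequence[str],
    abstract_tokens: Sequence[str],
    max_insertions: int = 1,
) -> bool:
    """True iff ``term_tokens`` occur in order in ``abstract_tokens`` with at
    most ``max_insertions`` extra tokens inside each consecutive gap.

    The budget is per gap, not shared across the phrase.  Implemented as a
    reachability sweep over token positions: greedy earliest-match is not
    sound here (a later occurrence of an inner word can be the only one that
    leaves the next word within reach).
    """
    if not term_tokens:
        raise ValueError("term must contain at least one token")
    if max_insertions < 0:
        raise ValueError("max_insertions must be nonnegative")
    if not abstract_tokens:
        return False

    positions: dict[str, list[int]] = {}
    for i, tok in enumerate(abstract_tokens):
        positions.setdefault(tok, []).append(i)

    reachable = positions.get(term_tokens[0])
    if reachable is None:
        return False
    window = 1 + max_insertions
    for tok in term_tokens[1:]:
        cand = positions.get(tok)
        if cand is None:
            return False
        nxt = []
        for q in cand:
            j = bisect_left(reachable, q)
            # previous-word occurrence p with p < q <= p + window
            if j and q - reachable[j - 1] <= window:
                nxt.append(q)
        if not nxt:
            return False
        reachable = nxt
    return True


def term_citations(
    term: str,
    store,
    species: Optional[Iterable[int]] = None,
    max_insertions: int = 1,
) -> Set[int]:
    """PMIDs of all abstracts in ``store`` matching ``term``.

    Title and body are concatenated before tokenization.  ``species``, when
    given, restricts the scan to abstracts tagged with at least one of the
    tax identifiers.
    """
    toks = tokenize(term)
    if not toks:
        raise ValueError(f"term {term!r} is empty after tokenization")
    species_set = frozenset(species) if species is not None else None
    need = set(toks)
    out: Set[int] = set()
    for rec in store:
        if species_set is not None and not (rec.tax_ids & species_set):
            continue
        # cheap prefilter: every term token must be present at all
        if not need <= store.token_set(rec.pmid):
            continue
        if match_phrase(toks, store.tokens(rec.pmid), max_insertions):
            out.add(rec.pmid)
    return out
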