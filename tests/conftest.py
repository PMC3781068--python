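import pytest

from cocite.corpus import AbstractRecord, AbstractStore, CitationIndex, GeneSet
from cocite.synthetic import CorpusSpec, ModuleSpec, generate_corpus

MODULE_MEMBERS = tuple(str(i) for i in range(1, 21))
MODULE_PHRASE = "synaptic plasticity"


def planted_spec(seed=7, rho=20.0, **kw):
    kw.setdefault("n_genes", 200)
    kw.setdefault("n_abstracts", 2000)
    return CorpusSpec(
        modules=(ModuleSpec(members=MODULE_MEMBERS, phrase=MODULE_PHRASE, rho=rho),),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def planted_corpus():
    """200 genes / 2000 abstracts with a 20-gene module enriched 20x."""
    return generate_corpus(planted_spec())


@pytest.fixture(scope="session")
def null_corpus():
    """Same shape, rho=1: the module carries no co-citation enrichment."""
    return generate_corpus(planted_spec(seed=5, rho=1.0))


@pytest.fixture
def tiny_store():
    return AbstractStore(
        [
            AbstractRecord(1, "Study one", "The AKT1 gene is mutated in tumors", frozenset({9606})),
            AbstractRecord(2, "Study two", "AKT1 protein levels rose after treatment", frozenset({9606})),
            AbstractRecord(3, "Study three", "confers disease resistance in plants", frozenset({3702})),
            AbstractRecord(4, "Study four", "disease and resistance are linked", frozenset({9606})),
            AbstractRecord(5, "Study five", "disease of the resistance era", frozenset({9606})),
        ]
    )


@pytest.fixture
def small_index():
    index = CitationIndex()
    index.add(9606, "1", [10, 11])
    index.add(9606, "2", [10])
    index.add(10090, "101", [12])
    return index


@pytest.fixture
def gene_set_ab():
    return GeneSet(9606, ("1", "2"), label="ab")
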