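import pytest

from ontotriage.corpus_io import DocumentRecord, LabeledCorpus, OntologyNode
from ontotriage.imt_features import TermStatistics


@pytest.fixture
def tiny_labeled_corpus():
    """Four labeled abstracts with a clean positive/negative split on the
    token 'bind'."""
    docs = [
        DocumentRecord("P1", title="Protein binding", body="The proteins bind strongly.", gold_label=1),
        DocumentRecord("P2", title="Complex formation", body="They bind and form a complex.", gold_label=1),
        DocumentRecord("N1", title="Cell culture", body="Cells were grown overnight.", gold_label=0),
        DocumentRecord("N2", title="Imaging", body="Microscopy of tissue samples.", gold_label=0),
    ]
    return LabeledCorpus(docs)


@pytest.fixture
def reference_term_stats():
    """Published-style term statistics used as fixture constants (normalized
    n-gram -> (mi, chi2)); never recomputed, only looked up."""
    return TermStatistics({
        "two hybrid": (0.439, 1225.574),
        "immunoprecipit": (0.437, 1110.124103),
        "hybrid": (0.398, 1041.587496),
        "yeast two": (0.348, 1061.789),
        "yeast": (0.173, 402.283),
        "gal4": (0.168, 576.122),
    })


@pytest.fixture
def two_hybrid_node():
    return OntologyNode(node_id="MI:0018", name="two hybrid",
                        synonyms=["2 hybrid", "yeast two hybrid"],
                        keyword="hybrid")
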