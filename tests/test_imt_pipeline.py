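import numpy as np
import pytest

from ontotriage.corpus_io import (AnnotationSet, DocumentRecord,
                                  LabeledCorpus, OntologyNode)
from ontotriage.evaluation import precision_recall_f1
from ontotriage.imt_features import (FEATURE_NAMES, PairFeatureVector,
                                     TermStatistics, build_node_lexicon,
                                     compute_node_popularity,
                                     compute_term_statistics)
from ontotriage.imt_pipeline import (ImtConfig, PairInstance,
                                     extract_evidence_sentence,
                                     generate_pair_instances, pair_confusion,
                                     predict_imt, select_pair_features,
                                     train_imt)
from ontotriage.presets import get_imt_preset, list_imt_presets
from ontotriage.synthetic_fixtures import ImtFixtureSpec, make_imt_fixture
from ontotriage.textnorm import split_sentences

SPEC = ImtFixtureSpec(n_nodes=8, n_docs=30, annotations_per_doc=2.0,
                      mention_rate=1.0, distractor_rate=0.0, seed=7)


@pytest.fixture(scope="module")
def imt_world():
    corpus, nodes, annotations = make_imt_fixture(SPEC)
    lexicons = [build_node_lexicon(n) for n in nodes]
    stats = compute_term_statistics(corpus, annotations, lexicons)
    popularity = compute_node_popularity(annotations)
    return corpus, nodes, annotations, lexicons, stats, popularity


def make_instances(imt_world, config=None):
    corpus, _, annotations, lexicons, stats, popularity = imt_world
    return generate_pair_instances(
        corpus, annotations, lexicons, stats, popularity,
        config or ImtConfig(seed=0),
    )


class TestGeneratePairInstances:
    def test_counts_all_mode(self):
        # 2 docs x 115 nodes with 3 gold pairs -> 3 positives, 227 negatives
        nodes = [OntologyNode(f"MI:{i:04d}", f"method nm{i:03d}") for i in range(115)]
        lexicons = [build_node_lexicon(n) for n in nodes]
        corpus = LabeledCorpus([
            DocumentRecord("D1", body="method nm000 and method nm001 were used."),
            DocumentRecord("D2", body="method nm002 only."),
        ])
        ann = AnnotationSet()
        ann.add("D1", "MI:0000")
        ann.add("D1", "MI:0001")
        ann.add("D2", "MI:0002")
        stats = TermStatistics({})
        instances = generate_pair_instances(corpus, ann, lexicons, stats, {},
                                            ImtConfig(seed=0))
        labels = [i.label for i in instances]
        assert len(instances) == 2 * 115
        assert sum(labels) == 3
        assert len(labels) - sum(labels) == 227

    def test_ratio_sampling_counts_and_reproducibility(self, imt_world):
        cfg = ImtConfig(negative_sampling="ratio", sampling_ratio=2.0, seed=11)
        corpus, _, annotations, lexicons, stats, popularity = imt_world
        inst1 = generate_pair_instances(corpus, annotations, lexicons, stats,
                                        popularity, cfg)
        inst2 = generate_pair_instances(corpus, annotations, lexicons, stats,
                                        popularity, cfg)
        assert inst1 == inst2
        for doc in corpus:
            gold = annotations.nodes_for(doc.doc_id)
            negs = [i for i in inst1
                    if i.features.doc_id == doc.doc_id and i.label == 0]
            expected = min(len(lexicons) - len(gold),
                           int(round(2.0 * max(len(gold), 1))))
            assert len(negs) == expected

    def test_all_nodes_gold_yields_no_negatives(self):
        nodes = [OntologyNode("A:1", "alpha beta"), OntologyNode("A:2", "gamma delta")]
        lexicons = [build_node_lexicon(n) for n in nodes]
        corpus = LabeledCorpus([DocumentRecord("D", body="alpha beta gamma delta")])
        ann = AnnotationSet()
        ann.add("D", "A:1")
        ann.add("D", "A:2")
        instances = generate_pair_instances(corpus, ann, lexicons,
                                            TermStatistics({}), {}, ImtConfig())
        assert all(i.label == 1 for i in instances)

    def test_empty_node_list_error(self, imt_world):
        corpus, _, annotations, _, stats, popularity = imt_world
        with pytest.raises(ValueError):
            generate_pair_instances(corpus, annotations, [], stats, popularity,
                                    ImtConfig())


class TestSelectPairFeatures:
    def test_planted_perfect_feature_ranks_first(self, imt_world):
        instances = make_instances(imt_world)
        # mention_rate 1 / distractor_rate 0: perfect_match_concept == label
        selected = select_pair_features(instances, 1)
        assert selected[0] in ("perfect_match_concept", "term_match_uni_concept",
                               "term_match_bi_concept", "term_match_ratio_uni_concept",
                               "term_match_ratio_bi_concept", "mi_sum_uni_concept",
                               "mi_sum_bi_concept", "chi2_sum_uni_concept",
                               "chi2_sum_bi_concept", "keyword_presence")
        # and specifically the binary perfect-match feature attains maximal
        # chi-square (= n) since it equals the label exactly
        hand = [PairInstance(i.features, i.label) for i in instances]
        top7 = select_pair_features(hand, 7)
        assert "perfect_match_concept" in top7

    def test_n21_returns_all(self, imt_world):
        instances = make_instances(imt_world)
        assert sorted(select_pair_features(instances, 21)) == sorted(FEATURE_NAMES)

    def test_invalid_n(self, imt_world):
        instances = make_instances(imt_world)
        for bad in (0, 22):
            with pytest.raises(ValueError):
                select_pair_features(instances, bad)

    def test_single_label_error(self, imt_world):
        instances = [i for i in make_instances(imt_world) if i.label == 1]
        with pytest.raises(ValueError):
            select_pair_features(instances, 5)


class TestTrainPredict:
    @pytest.mark.parametrize("algorithm", ["random_forest", "random_committee",
                                           "nb_tree", "j48"])
    def test_separable_training_f1(self, imt_world, algorithm):
        instances = make_instances(imt_world)
        model = train_imt(instances, ImtConfig(algorithm=algorithm,
                                               n_features=7, seed=0))
        x = np.array([i.features.values for i in instances])[:, model.feature_indices]
        probs = model.model.predict_proba(x)
        pred = (probs[:, list(model.model.classes_).index(1)] >= 0.5).astype(int)
        y = np.array([i.label for i in instances])
        assert (pred == y).all()

    def test_determinism_same_seed(self, imt_world):
        corpus, _, _, lexicons, stats, popularity = imt_world
        instances = make_instances(imt_world)
        cfg = ImtConfig(algorithm="random_forest", n_features=12, seed=5)
        m1 = train_imt(instances, cfg)
        m2 = train_imt(instances, cfg)
        doc = corpus.documents[0]
        p1 = predict_imt(m1, doc, lexicons, stats, popularity)
        p2 = predict_imt(m2, doc, lexicons, stats, popularity)
        assert p1 == p2

    def test_single_class_error(self, imt_world):
        instances = [i for i in make_instances(imt_world) if i.label == 0]
        with pytest.raises(ValueError):
            train_imt(instances, ImtConfig())

    def test_predictions_sorted_with_evidence(self, imt_world):
        corpus, _, annotations, lexicons, stats, popularity = imt_world
        instances = make_instances(imt_world)
        model = train_imt(instances, ImtConfig(algorithm="j48", n_features=21, seed=0))
        for doc in corpus.documents[:5]:
            preds = predict_imt(model, doc, lexicons, stats, popularity)
            confs = [p.confidence for p in preds]
            assert confs == sorted(confs, reverse=True)
            sentences = {s.text for s in split_sentences(doc.text)}
            for p in preds:
                assert p.confidence >= 0.5
                assert p.evidence_sentence in sentences

    def test_document_with_no_methods_yields_nothing(self, imt_world):
        corpus, _, _, lexicons, stats, popularity = imt_world
        instances = make_instances(imt_world)
        model = train_imt(instances, ImtConfig(algorithm="random_forest",
                                               n_features=7, seed=0))
        blank = DocumentRecord("BLANK", body="Nothing about methods here at all.")
        assert predict_imt(model, blank, lexicons, stats, popularity) == []


class TestEndToEndRecovery:
    @pytest.mark.parametrize("preset", ["rf-12", "rc-12", "nbt-7", "j48-14"])
    def test_heldout_micro_f1_one(self, imt_world, preset):
        corpus, nodes, annotations, lexicons, stats, popularity = imt_world
        instances = make_instances(imt_world)
        model = train_imt(instances, get_imt_preset(preset, seed=0))
        held_corpus, _, held_ann = make_imt_fixture(
            ImtFixtureSpec(**{**SPEC.__dict__, "seed": SPEC.seed + 50})
        )
        predicted = AnnotationSet()
        for doc in held_corpus:
            for p in predict_imt(model, doc, lexicons, stats, popularity):
                predicted.add(p.doc_id, p.node_id)
        c = pair_confusion(held_ann, predicted, held_corpus.doc_ids,
                           [n.node_id for n in nodes])
        assert precision_recall_f1(c)[2] == pytest.approx(1.0)


class TestExtractEvidenceSentence:
    def test_reference_scores_pick_highest(self, reference_term_stats):
        lex = build_node_lexicon(OntologyNode("MI:0018", "yeast two hybrid"))
        text = ("The hybrid construct was expressed. "
                "Cultures of yeast were grown overnight for this.")
        sentences = split_sentences(text)
        sentence, score = extract_evidence_sentence(sentences, lex,
                                                    reference_term_stats)
        assert sentence == "The hybrid construct was expressed."
        assert score == pytest.approx(1041.587496)

    def test_zero_scores_return_longest(self, reference_term_stats):
        lex = build_node_lexicon(OntologyNode("MI:0001", "crystallography"))
        text = "Short one. This sentence is considerably longer than that. Mid size here."
        sentences = split_sentences(text)
        sentence, score = extract_evidence_sentence(sentences, lex,
                                                    reference_term_stats)
        assert score == 0.0
        assert sentence == "This sentence is considerably longer than that."

    def test_single_sentence_document(self, reference_term_stats, two_hybrid_node):
        lex = build_node_lexicon(two_hybrid_node)
        sentences = split_sentences("Only one sentence exists.")
        sentence, _ = extract_evidence_sentence(sentences, lex, reference_term_stats)
        assert sentence == "Only one sentence exists."

    def test_empty_sentences(self, reference_term_stats, two_hybrid_node):
        lex = build_node_lexicon(two_hybrid_node)
        assert extract_evidence_sentence([], lex, reference_term_stats) == ("", 0.0)

    def test_tie_broken_by_length_then_position(self, reference_term_stats):
        lex = build_node_lexicon(OntologyNode("MI:0018", "two hybrid"))
        # both sentences contain "hybrid" once -> same score; longer wins
        text = "A hybrid was made. The hybrid construct was then expressed here."
        sentences = split_sentences(text)
        sentence, score = extract_evidence_sentence(sentences, lex,
                                                    reference_term_stats)
        assert sentence.startswith("The hybrid construct")
        assert score == pytest.approx(1041.587496)

    def test_brute_force_oracle_on_random_fixtures(self, reference_term_stats):
        rng = np.random.default_rng(13)
        vocab = ["hybrid", "yeast", "two", "gal4", "filler", "other", "words"]
        lex = build_node_lexicon(OntologyNode("MI:0018", "yeast two hybrid gal4"))
        for _ in range(50):
            n_sent = int(rng.integers(1, 8))
            parts = []
            for _ in range(n_sent):
                k = int(rng.integers(1, 8))
                parts.append(" ".join(rng.choice(vocab, size=k)).capitalize() + ".")
            sentences = split_sentences(" ".join(parts))
            got_sentence, got_score = extract_evidence_sentence(
                sentences, lex, reference_term_stats)
            # oracle: rescan each sentence independently
            def score_of(s):
                from ontotriage.textnorm import normalize_and_tokenize
                toks = set(normalize_and_tokenize(s.text))
                return sum(reference_term_stats.chi2(u)
                           for u in lex.concept_unigrams if u in toks)
            best = max(score_of(s) for s in sentences)
            assert got_score == pytest.approx(best)
            assert score_of(next(s for s in sentences if s.text == got_sentence)) == pytest.approx(best)
            for s in sentences:
                if score_of(s) == best:
                    assert len(got_sentence) >= len(s.text)


class TestPairConfusion:
    def test_exhaustive_enumeration_small(self):
        gold = AnnotationSet()
        gold.add("D1", "N1")
        gold.add("D2", "N2")
        pred = AnnotationSet()
        pred.add("D1", "N1")
        pred.add("D1", "N2")
        c = pair_confusion(gold, pred, ["D1", "D2"], ["N1", "N2"])
        # enumerate: (D1,N1) tp, (D1,N2) fp, (D2,N2) fn, (D2,N1) tn
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_random_against_bruteforce(self):
        rng = np.random.default_rng(3)
        docs = [f"D{i}" for i in range(5)]
        nodes = [f"N{i}" for i in range(4)]
        for _ in range(30):
            gold, pred = AnnotationSet(), AnnotationSet()
            for d in docs:
                for n in nodes:
                    if rng.random() < 0.3:
                        gold.add(d, n)
                    if rng.random() < 0.3:
                        pred.add(d, n)
            c = pair_confusion(gold, pred, docs, nodes)
            tp = fp = fn = tn = 0
            for d in docs:
                for n in nodes:
                    g = n in gold.nodes_for(d)
                    p = n in pred.nodes_for(d)
                    tp += g and p
                    fp += p and not g
                    fn += g and not p
                    tn += not g and not p
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


class TestImtPresets:
    def test_all_ten_run_labels(self):
        assert set(list_imt_presets()) == {
            "j48-21", "rc-21", "rf-21", "j48-14", "rf-12", "rc-12", "rc-14",
            "rf-7", "nbt-7", "rf-15",
        }

    def test_rf_12(self):
        cfg = get_imt_preset("rf-12")
        assert cfg.algorithm == "random_forest"
        assert cfg.n_features == 12

    def test_rf_7_and_nbt_7(self):
        assert get_imt_preset("rf-7").n_features == 7
        assert get_imt_preset("nbt-7").algorithm == "nb_tree"

    def test_feature_counts_cover_table(self):
        ns = {get_imt_preset(n).n_features for n in list_imt_presets()}
        assert ns == {7, 12, 14, 15, 21}

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ImtConfig(algorithm="svm")
        with pytest.raises(ValueError):
            ImtConfig(n_features=0)
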