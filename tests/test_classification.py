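import numpy as np
import pytest

from headache_nlp.classification import (
    ClassifierSpec,
    CVPlan,
    FeatureExtractor,
    FeatureSpec,
    char_ngrams,
    compute_metrics,
    loocv,
    make_estimator,
    make_folds,
    nested_cv,
    word_ngrams,
)
from headache_nlp.corpus_io import Corpus, NarrativeRecord
from headache_nlp.preprocess import TokenizedDocument, tokenize_corpus


def make_doc(rid, *sentences):
    return TokenizedDocument(
        record_id=rid, sentences=tuple(tuple(s) for s in sentences)
    )


def separable_corpus(n_a=12, n_b=12):
    """Disjoint class vocabularies: perfectly separable by unigrams."""
    records = []
    for i in range(n_a):
        records.append(
            NarrativeRecord(
                record_id=f"m{i}",
                text=f"zon dag licht w{i % 3}.",
                diagnosis="migraine",
                age=40 + i,
                sex="female",
            )
        )
    for i in range(n_b):
        records.append(
            NarrativeRecord(
                record_id=f"c{i}",
                text=f"nacht koud duister v{i % 3}.",
                diagnosis="cluster_headache",
                age=45 + i,
                sex="male",
            )
        )
    return Corpus(records)


class TestNgramFeatures:
    def test_word_ngrams_unigram_bigram(self):
        doc = make_doc("a", ["pijn", "oog"])
        grams = word_ngrams(doc, (1, 2))
        assert sorted(grams) == ["w:oog", "w:pijn", "w:pijn oog"]

    def test_char_ngrams_with_boundary_markers(self):
        doc = make_doc("a", ["oog"])
        grams = set(char_ngrams(doc, (1, 3)))
        assert grams == {
            "c:#", "c:o", "c:g",
            "c:#o", "c:oo", "c:og", "c:g#",
            "c:#oo", "c:oog", "c:og#",
        }

    def test_word_ngrams_do_not_cross_sentence_boundaries(self):
        doc = make_doc("a", ["pijn"], ["oog"])
        assert "w:pijn oog" not in word_ngrams(doc, (1, 2))

    def test_out_of_vocabulary_gives_zero_block(self):
        docs = [make_doc("a", ["pijn", "oog"]), make_doc("b", ["iets", "anders"])]
        ext = FeatureExtractor(docs, None, FeatureSpec(use_char_ngrams=False))
        ext.fit([0])
        X = ext.transform([1])
        assert X.nnz == 0

    def test_unseen_ngrams_ignored_at_transform(self):
        docs = [make_doc("a", ["pijn"]), make_doc("b", ["pijn", "nieuw"])]
        ext = FeatureExtractor(docs, None, FeatureSpec(use_char_ngrams=False))
        ext.fit([0])
        X = ext.transform([1])
        assert X.shape[1] == len(ext.vocabulary_)
        assert X.sum() == 1.0  # only "pijn" counted

    def test_metadata_missing_names_record(self):
        corpus = Corpus(
            [NarrativeRecord(record_id="a", text="x y", diagnosis="migraine")]
        )
        docs = [tokenize_corpus(corpus)["a"]]
        with pytest.raises(ValueError, match="'a'"):
            FeatureExtractor(
                docs, list(corpus.records), FeatureSpec(use_metadata=True)
            )

    def test_metadata_standardised_with_training_stats_only(self):
        corpus = separable_corpus(4, 4)
        docs = [tokenize_corpus(corpus)[r.record_id] for r in corpus]
        spec = FeatureSpec(
            use_word_ngrams=False, use_char_ngrams=False, use_metadata=True
        )
        ext = FeatureExtractor(docs, list(corpus.records), spec)
        train = [0, 1, 2, 3]
        ext.fit(train)
        ages = np.array([corpus[i].age for i in train], dtype=float)
        assert ext.age_stats_ == (ages.mean(), ages.std())
        X = ext.transform(train).toarray()
        assert X[:, 0] == pytest.approx(
            (ages - ages.mean()) / ages.std()
        )
        assert set(X[:, 1]) == {1.0}  # all female in this slice


class TestMakeFolds:
    def test_paper_sized_split_74_38(self):
        labels = ["migraine"] * 74 + ["cluster_headache"] * 38
        folds = make_folds(labels, CVPlan(seed=17))
        sizes = sorted(len(te) for _, te in folds)
        assert sizes == [22, 22, 22, 23, 23]
        y = np.array(labels)
        for _, te in folds:
            assert np.sum(y[te] == "cluster_headache") in (7, 8)
        all_test = np.concatenate([te for _, te in folds])
        assert len(all_test) == 112
        assert len(set(all_test)) == 112  # no instance tested twice

    def test_loocv_yields_singleton_folds(self):
        labels = ["migraine"] * 6 + ["cluster_headache"] * 4
        folds = make_folds(labels, CVPlan(scheme="loocv"))
        assert len(folds) == 10
        assert all(len(te) == 1 for _, te in folds)

    def test_same_seed_identical_assignment(self):
        labels = ["migraine"] * 30 + ["cluster_headache"] * 20
        f1 = make_folds(labels, CVPlan(seed=5))
        f2 = make_folds(labels, CVPlan(seed=5))
        for (_, a), (_, b) in zip(f1, f2):
            assert np.array_equal(a, b)

    def test_k_larger_than_class_rejected(self):
        labels = ["migraine"] * 20 + ["cluster_headache"] * 3
        with pytest.raises(ValueError, match="class size"):
            make_folds(labels, CVPlan(k_outer=5))


class TestComputeMetrics:
    def test_hand_computed_confusion(self):
        truth = ["CH", "CH", "M", "M"]
        pred = ["CH", "M", "M", "M"]
        m = compute_metrics(truth, pred)
        assert m["per_class"]["CH"]["precision"] == pytest.approx(1.0)
        assert m["per_class"]["CH"]["recall"] == pytest.approx(0.5)
        assert m["per_class"]["CH"]["f1"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.75)

    def test_perfect_predictions(self):
        m = compute_metrics(["a", "b"], ["a", "b"])
        assert m["accuracy"] == 1.0
        assert m["macro_f1"] == 1.0

    def test_majority_only_predictions_closed_form(self):
        truth = ["M"] * 67 + ["CH"] * 33
        pred = ["M"] * 100
        m = compute_metrics(truth, pred)
        assert m["accuracy"] == pytest.approx(0.67)
        assert m["per_class"]["CH"]["recall"] == 0.0
        assert m["per_class"]["M"]["f1"] == pytest.approx(
            2 * 0.67 / (1 + 0.67)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(["a"], ["a", "b"])

    def test_f1_is_harmonic_mean_of_p_and_r(self):
        rng = np.random.default_rng(0)
        labels = np.array(["M", "CH"])
        truth = labels[rng.integers(0, 2, 50)]
        pred = labels[rng.integers(0, 2, 50)]
        m = compute_metrics(list(truth), list(pred))
        for c in ("M", "CH"):
            p = m["per_class"][c]["precision"]
            r = m["per_class"][c]["recall"]
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert m["per_class"][c]["f1"] == pytest.approx(expected)


@pytest.fixture(scope="module")
def separable_setup():
    corpus = separable_corpus()
    docs = tokenize_corpus(corpus)
    return corpus, docs


class TestNestedCV:
    def test_separable_corpus_perfect_scores(self, separable_setup):
        corpus, docs = separable_setup
        report = nested_cv(
            corpus,
            docs,
            FeatureSpec(),
            ClassifierSpec(algorithm="logistic_regression"),
            CVPlan(k_outer=3, k_inner=2, seed=1),
        )
        assert report.aggregate["accuracy"] == 1.0
        assert report.aggregate["macro_f1"] == 1.0

    def test_bitwise_reproducible_given_seed(self, separable_setup):
        corpus, docs = separable_setup
        args = (
            corpus, docs, FeatureSpec(),
            ClassifierSpec(algorithm="svm_linear"),
            CVPlan(k_outer=3, k_inner=2, seed=9),
        )
        assert nested_cv(*args).to_dict() == nested_cv(*args).to_dict()

    def test_fold_averages_equal_mean_of_per_fold_values(self, separable_setup):
        corpus, docs = separable_setup
        report = nested_cv(
            corpus, docs, FeatureSpec(),
            ClassifierSpec(algorithm="naive_bayes"),
            CVPlan(k_outer=3, k_inner=2, seed=2),
        )
        assert report.aggregate["accuracy"] == pytest.approx(
            np.mean([f.metrics["accuracy"] for f in report.folds])
        )

    def test_outer_tests_disjoint_from_inner_training(self, separable_setup):
        corpus, docs = separable_setup
        report = nested_cv(
            corpus, docs, FeatureSpec(),
            ClassifierSpec(algorithm="logistic_regression"),
            CVPlan(k_outer=3, k_inner=2, seed=3),
        )
        for fold in report.folds:
            test = set(fold.test_record_ids)
            assert fold.inner_train_record_ids  # audit trail present
            for inner_train in fold.inner_train_record_ids:
                assert not test & set(inner_train)

    def test_vocabulary_excludes_test_only_tokens(self):
        """A marker token present only in one record never enters the
        vocabulary of folds that hold that record out."""
        corpus = separable_corpus(6, 6)
        records = list(corpus.records)
        marker_rec = NarrativeRecord(
            record_id="m0",
            text="zon dag licht w0 uniekmarker.",
            diagnosis="migraine",
            age=40,
            sex="female",
        )
        records[0] = marker_rec
        corpus = Corpus(records)
        docs = tokenize_corpus(corpus)
        doc_list = [docs[r.record_id] for r in corpus]
        spec = FeatureSpec(use_char_ngrams=False)
        ext = FeatureExtractor(doc_list, records, spec)
        train_without_marker = [i for i, r in enumerate(records) if r.record_id != "m0"]
        ext.fit(train_without_marker)
        assert "w:uniekmarker" not in ext.vocabulary_


class TestLOOCV:
    def test_separable_corpus_perfect_accuracy(self, separable_setup):
        corpus, docs = separable_setup
        report = loocv(
            corpus, docs, FeatureSpec(use_char_ngrams=False),
            ClassifierSpec(algorithm="logistic_regression", hyper_grid=(1.0,)),
            CVPlan(scheme="loocv", k_inner=2, seed=4),
        )
        assert report.pooled["accuracy"] == 1.0
        assert len(report.folds) == len(corpus)

    def test_pooled_predictions_match_independent_per_round_oracle(self):
        """Six independent hold-one-out fits reproduce the pooled result."""
        corpus = separable_corpus(3, 3)
        docs = tokenize_corpus(corpus)
        doc_list = [docs[r.record_id] for r in corpus]
        y = np.array([r.diagnosis for r in corpus])
        spec = FeatureSpec(use_char_ngrams=False)
        report = loocv(
            corpus, docs, spec,
            ClassifierSpec(algorithm="naive_bayes", hyper_grid=(1.0,)),
            CVPlan(scheme="loocv", k_inner=2, seed=0),
        )
        for i in range(len(corpus)):
            train = [j for j in range(len(corpus)) if j != i]
            ext = FeatureExtractor(doc_list, None, spec, nonnegative=True).fit(train)
            clf = make_estimator(
                ClassifierSpec(algorithm="naive_bayes", hyper_grid=(1.0,)), 1.0
            )
            clf.fit(ext.transform(train), y[train])
            expected = clf.predict(ext.transform([i]))[0]
            fold = report.folds[i]
            assert fold.predictions == [expected]

    def test_same_seed_identical_report(self):
        corpus = separable_corpus(4, 4)
        docs = tokenize_corpus(corpus)
        args = (
            corpus, docs, FeatureSpec(use_char_ngrams=False),
            ClassifierSpec(algorithm="logistic_regression", hyper_grid=(0.1, 1.0)),
            CVPlan(scheme="loocv", k_inner=2, seed=6),
        )
        assert loocv(*args).to_dict() == loocv(*args).to_dict()
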