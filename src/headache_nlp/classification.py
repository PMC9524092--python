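"""Diagnosis classification from attack descriptions.

Feature families: word n-grams (within sentences) and character n-grams
(within tokens, with explicit ``#`` boundary markers), both with n in a
configurable range (default 1-3), plus optional patient metadata (age,
sex).  Classifiers: multinomial naive Bayes, linear-kernel SVM and logistic
regression, all with balanced class weighting (uniform priors for NB,
inverse-frequency weights for SVM/LR).

Evaluation is nested stratified cross-validation: an inner stratified
k-fold grid search (maximising macro-F1) chooses the regularisation /
smoothing strength per outer fold, the winner is refit on the full outer
training portion and scored on the held-out fold.  Vocabulary, idf and
metadata scaling statistics are always functions of the training portion
only — the report carries fingerprints so this can be audited.
Leave-one-out CV is the N-fold special case with pooled predictions.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC

from .corpus_io import Corpus, NarrativeRecord
from .preprocess import TokenizedDocument

logger = logging.getLogger(__name__)

ALGORITHMS = ("naive_bayes", "svm_linear", "logistic_regression")
DEFAULT_GRID = (0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature families enter the vector representation."""

    use_word_ngrams: bool = True
    use_char_ngrams: bool = True
    n_range: tuple[int, int] = (1, 3)
    use_metadata: bool = False
    weighting: str = "count"  # count | binary | tfidf

    def __post_init__(self) -> None:
        if not (self.use_word_ngrams or self.use_char_ngrams or self.use_metadata):
            raise ValueError("at least one feature family must be enabled")
        lo, hi = self.n_range
        if not (1 <= lo <= hi):
            raise ValueError("n_range must satisfy 1 <= n_min <= n_max")
        if self.weighting not in ("count", "binary", "tfidf"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


#: The three standard feature groups by name.
FEATURE_GROUPS: dict[str, FeatureSpec] = {
    "ngrams": FeatureSpec(),
    "metadata": FeatureSpec(
        use_word_ngrams=False, use_char_ngrams=False, use_metadata=True
    ),
    "ngrams+metadata": FeatureSpec(use_metadata=True),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm plus its regularisation/smoothing candidate grid."""

    algorithm: str
    hyper_grid: tuple[float, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if not self.hyper_grid:
            raise ValueError("hyper_grid must be non-empty")

    @property
    def needs_nonnegative(self) -> bool:
        return self.algorithm == "naive_bayes"


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation layout; all randomness flows from ``seed``."""

    scheme: str = "stratified_kfold"  # stratified_kfold | loocv
    k_outer: int = 5
    k_inner: int = 5
    seed: int = 17
    optimization_metric: str = "macro_f1"

    def __post_init__(self) -> None:
        if self.scheme not in ("stratified_kfold", "loocv"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "stratified_kfold" and self.k_outer < 2:
            raise ValueError("k_outer must be >= 2")


def make_estimator(spec: ClassifierSpec, value: float):
    if spec.algorithm == "naive_bayes":
        # balanced weighting realised as uniform class priors
        return MultinomialNB(alpha=value, fit_prior=False)
    if spec.algorithm == "svm_linear":
        # 2000 dual iterations: converges on separable text data; on noise
        # it stops early rather than chasing an unattainable optimum
        return LinearSVC(
            C=value, class_weight="balanced", max_iter=2000, random_state=0
        )
    return LogisticRegression(
        C=value,
        class_weight="balanced",
        solver="liblinear",
        max_iter=1000,
        random_state=0,
    )


def word_ngrams(doc: TokenizedDocument, n_range: tuple[int, int]) -> list[str]:
    """Word n-grams within sentence boundaries, keyed ``w:tok tok ...``."""
    lo, hi = n_range
    grams: list[str] = []
    for sent in doc.sentences:
        for n in range(lo, hi + 1):
            for i in range(len(sent) - n + 1):
                grams.append("w:" + " ".join(sent[i : i + n]))
    return grams


def char_ngrams(doc: TokenizedDocument, n_range: tuple[int, int]) -> list[str]:
    """Character n-grams within ``#``-padded tokens, keyed ``c:...``.

    Padding marks word boundaries, so n-grams never span the gap a removed
    stop word leaves behind.
    """
    lo, hi = n_range
    grams: list[str] = []
    for tok in doc.tokens:
        padded = f"#{tok}#"
        for n in range(lo, hi + 1):
            for i in range(len(padded) - n + 1):
                grams.append("c:" + padded[i : i + n])
    return grams


def doc_feature_counter(doc: TokenizedDocument, spec: FeatureSpec) -> Counter:
    """All n-gram features of one document with their occurrence counts."""
    c: Counter = Counter()
    if spec.use_word_ngrams:
        c.update(word_ngrams(doc, spec.n_range))
    if spec.use_char_ngrams:
        c.update(char_ngrams(doc, spec.n_range))
    return c


class FeatureExtractor:
    """Fit-on-train / transform-anywhere feature matrices for a fixed corpus.

    Per-document n-gram counters are precomputed once (they depend only on
    the document itself); :meth:`fit` derives everything train-dependent —
    the vocabulary, idf weights, age scaling — from the given training
    indices only.  Unseen n-grams in held-out documents are ignored.
    """

    def __init__(
        self,
        docs: Sequence[TokenizedDocument],
        records: Sequence[NarrativeRecord] | None,
        spec: FeatureSpec,
        nonnegative: bool = False,
    ) -> None:
        self.spec = spec
        self.nonnegative = nonnegative
        self.counters = [doc_feature_counter(d, spec) for d in docs]
        self.record_ids = [d.record_id for d in docs]
        if spec.use_metadata:
            if records is None:
                raise ValueError("metadata features requested but no records given")
            self.ages = np.empty(len(records))
            self.sexes = np.empty(len(records))
            for i, rec in enumerate(records):
                if rec.age is None or rec.sex is None:
                    raise ValueError(
                        f"record {rec.record_id!r} lacks age/sex needed for "
                        "metadata features"
                    )
                self.ages[i] = rec.age
                self.sexes[i] = 1.0 if rec.sex == "female" else 0.0
        self.vocabulary_: dict[str, int] | None = None
        self.idf_: np.ndarray | None = None
        self.age_stats_: tuple[float, float] | None = None

    def spawn(self) -> "FeatureExtractor":
        """An unfitted extractor sharing the per-document counters.

        Counters depend only on each document, so sharing them across fits
        cannot leak training information between folds.
        """
        new = object.__new__(FeatureExtractor)
        new.spec = self.spec
        new.nonnegative = self.nonnegative
        new.counters = self.counters
        new.record_ids = self.record_ids
        if self.spec.use_metadata:
            new.ages = self.ages
            new.sexes = self.sexes
        new.vocabulary_ = None
        new.idf_ = None
        new.age_stats_ = None
        return new

    def fit(self, train_idx: Sequence[int]) -> "FeatureExtractor":
        vocab: set[str] = set()
        for i in train_idx:
            vocab.update(self.counters[i])
        self.vocabulary_ = {f: j for j, f in enumerate(sorted(vocab))}
        if self.spec.weighting == "tfidf":
            df = np.zeros(len(self.vocabulary_))
            for i in train_idx:
                for f in self.counters[i]:
                    df[self.vocabulary_[f]] += 1
            n = len(train_idx)
            self.idf_ = np.log((1 + n) / (1 + df)) + 1.0
        if self.spec.use_metadata:
            ages = self.ages[np.asarray(train_idx)]
            if self.nonnegative:
                lo, hi = float(ages.min()), float(ages.max())
                self.age_stats_ = (lo, max(hi - lo, 1e-12))
            else:
                self.age_stats_ = (
                    float(ages.mean()),
                    float(ages.std(ddof=0)) or 1.0,
                )
        return self

    def transform(self, idx: Sequence[int]) -> sp.csr_matrix:
        if self.vocabulary_ is None:
            raise RuntimeError("fit() must be called before transform()")
        data, indices, indptr = [], [], [0]
        for i in idx:
            for f, cnt in self.counters[i].items():
                j = self.vocabulary_.get(f)
                if j is None:
                    continue  # out-of-vocabulary: ignored
                indices.append(j)
                data.append(1.0 if self.spec.weighting == "binary" else float(cnt))
            indptr.append(len(indices))
        X = sp.csr_matrix(
            (data, indices, indptr), shape=(len(idx), len(self.vocabulary_))
        )
        if self.spec.weighting == "tfidf":
            X = X.multiply(self.idf_).tocsr()
        if self.spec.use_metadata:
            center, scale = self.age_stats_
            age_col = (self.ages[np.asarray(idx)] - center) / scale
            if self.nonnegative:
                age_col = np.clip(age_col, 0.0, 1.0)
            meta = np.column_stack([age_col, self.sexes[np.asarray(idx)]])
            X = sp.hstack([X, sp.csr_matrix(meta)], format="csr")
        return X

    def fingerprint(self) -> str:
        """SHA-256 over the fitted vocabulary and scaling statistics."""
        if self.vocabulary_ is None:
            raise RuntimeError("fit() must be called before fingerprint()")
        h = hashlib.sha256()
        for f in sorted(self.vocabulary_):
            h.update(f.encode("utf-8"))
            h.update(b"\x00")
        h.update(repr(self.age_stats_).encode())
        if self.idf_ is not None:
            h.update(np.round(self.idf_, 12).tobytes())
        return h.hexdigest()


def extract_features(
    docs: Sequence[TokenizedDocument],
    records: Sequence[NarrativeRecord] | None,
    spec: FeatureSpec,
    fit_on: Sequence[int],
    nonnegative: bool = False,
) -> FeatureExtractor:
    """Build a feature extractor fitted on ``fit_on`` indices only."""
    return FeatureExtractor(docs, records, spec, nonnegative=nonnegative).fit(fit_on)


def make_folds(labels: Sequence[str], plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Outer (train_idx, test_idx) pairs; deterministic given the plan seed.

    Stratified folds keep each fold's class proportions within one instance
    of the global split; LOOCV yields one singleton test fold per instance.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    if plan.scheme == "loocv":
        return [(tr, te) for tr, te in LeaveOneOut().split(y)]
    smallest = min(np.bincount(np.unique(y, return_inverse=True)[1]))
    if plan.k_outer > smallest:
        raise ValueError(
            f"k={plan.k_outer} exceeds the smaller class size ({smallest})"
        )
    skf = StratifiedKFold(n_splits=plan.k_outer, shuffle=True, random_state=plan.seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def compute_metrics(
    truth: Sequence[str], predictions: Sequence[str], classes: Sequence[str] | None = None
) -> dict:
    """Accuracy, per-class precision/recall/F1 and macro-F1.

    Undefined ratios (no predicted/true instances of a class) score 0 with a
    warning, matching the conservative convention for small folds.
    """
    truth = list(truth)
    predictions = list(predictions)
    if len(truth) != len(predictions):
        raise ValueError("truth and predictions differ in length")
    if classes is None:
        classes = sorted(set(truth) | set(predictions))
    p, r, f1, support = precision_recall_fscore_support(
        truth, predictions, labels=list(classes), zero_division=0
    )
    if (0.0 in p or 0.0 in r) and not getattr(compute_metrics, "_warned", False):
        compute_metrics._warned = True  # warn once; grid search hits this often
        logger.warning("zero-division in precision/recall set to 0")
    acc = float(np.mean(np.asarray(truth) == np.asarray(predictions)))
    return {
        "accuracy": acc,
        "per_class": {
            c: {"precision": float(p[i]), "recall": float(r[i]), "f1": float(f1[i])}
            for i, c in enumerate(classes)
        },
        "macro_f1": float(np.mean(f1)),
    }


@dataclass
class FoldResult:
    fold: int
    test_record_ids: list[str]
    truth: list[str]
    predictions: list[str]
    best_param: float
    metrics: dict
    vocab_fingerprint: str
    age_stats: tuple[float, float] | None
    inner_train_record_ids: list[list[str]] = field(default_factory=list)
    inner_vocab_fingerprints: list[str] = field(default_factory=list)


@dataclass
class EvaluationReport:
    """Per-fold and aggregated scores for one classifier x feature setup."""

    setup: dict
    folds: list[FoldResult]
    aggregate: dict
    pooled: dict

    def to_dict(self) -> dict:
        return {
            "setup": self.setup,
            "aggregate": self.aggregate,
            "pooled": self.pooled,
            "folds": [
                {
                    "fold": f.fold,
                    "test_record_ids": f.test_record_ids,
                    "truth": f.truth,
                    "predictions": f.predictions,
                    "best_param": f.best_param,
                    "metrics": f.metrics,
                    "vocab_fingerprint": f.vocab_fingerprint,
                }
                for f in self.folds
            ],
        }


def _aligned(corpus: Corpus, docs: Mapping[str, TokenizedDocument]):
    records = list(corpus.records)
    for rec in records:
        if rec.record_id not in docs:
            raise ValueError(f"no tokenized document for record {rec.record_id!r}")
        if rec.diagnosis is None:
            raise ValueError(f"record {rec.record_id!r} is unlabeled")
    doc_list = [docs[r.record_id] for r in records]
    y = np.asarray([r.diagnosis for r in records])
    return records, doc_list, y


def _grid_search(
    extractor_factory,
    grid: Sequence[float],
    cspec: ClassifierSpec,
    y: np.ndarray,
    train_idx: np.ndarray,
    k_inner: int,
    seed: int,
    classes: Sequence[str],
    audit: FoldResult | None = None,
    record_ids: Sequence[str] | None = None,
) -> float:
    """Inner stratified grid search maximising macro-F1.

    Ties break toward the first-listed grid value.  Each inner split fits
    its own feature extractor on the inner-training portion only.
    """
    inner = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    scores = np.zeros(len(grid))
    for itr, ite in inner.split(np.zeros(len(train_idx)), y[train_idx]):
        inner_train = train_idx[itr]
        inner_val = train_idx[ite]
        ext = extractor_factory().fit(inner_train)
        Xtr = ext.transform(inner_train)
        Xva = ext.transform(inner_val)
        if audit is not None and record_ids is not None:
            audit.inner_train_record_ids.append(
                [record_ids[i] for i in inner_train]
            )
            audit.inner_vocab_fingerprints.append(ext.fingerprint())
        for gi, value in enumerate(grid):
            clf = make_estimator(cspec, value)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xtr, y[inner_train])
            m = compute_metrics(y[inner_val], clf.predict(Xva), classes)
            scores[gi] += m["macro_f1"]
    return float(grid[int(np.argmax(scores))])  # argmax: first max wins


def nested_cv(
    corpus: Corpus,
    docs: Mapping[str, TokenizedDocument],
    feature_spec: FeatureSpec,
    classifier_spec: ClassifierSpec,
    plan: CVPlan,
) -> EvaluationReport:
    """Nested stratified cross-validation of one classifier x feature setup.

    Outer folds estimate performance; an inner stratified ``k_inner``-fold
    grid search inside each outer training portion picks the hyperparameter
    (macro-F1, first-listed wins ties), which is refit on the full outer
    training portion.  Aggregate metrics are the means of the per-fold
    values; ``pooled`` scores the concatenated outer predictions.
    """
    records, doc_list, y = _aligned(corpus, docs)
    classes = sorted(set(y))
    record_ids = [r.record_id for r in records]

    base = FeatureExtractor(
        doc_list, records, feature_spec,
        nonnegative=classifier_spec.needs_nonnegative,
    )
    factory = base.spawn

    folds: list[FoldResult] = []
    for fold_i, (tr, te) in enumerate(make_folds(y, plan)):
        if len(set(y[tr])) < 2:
            raise ValueError(f"outer fold {fold_i}: training portion has one class")
        fr = FoldResult(
            fold=fold_i,
            test_record_ids=[record_ids[i] for i in te],
            truth=[str(v) for v in y[te]],
            predictions=[],
            best_param=np.nan,
            metrics={},
            vocab_fingerprint="",
            age_stats=None,
        )
        best = _grid_search(
            factory,
            classifier_spec.hyper_grid,
            classifier_spec,
            y,
            tr,
            plan.k_inner,
            plan.seed + 1000 * (fold_i + 1),
            classes,
            audit=fr,
            record_ids=record_ids,
        )
        ext = factory().fit(tr)
        clf = make_estimator(classifier_spec, best)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(ext.transform(tr), y[tr])
        pred = clf.predict(ext.transform(te))
        fr.predictions = [str(v) for v in pred]
        fr.best_param = best
        fr.metrics = compute_metrics(y[te], pred, classes)
        fr.vocab_fingerprint = ext.fingerprint()
        fr.age_stats = ext.age_stats_
        folds.append(fr)

    aggregate = _mean_metrics([f.metrics for f in folds], classes)
    all_truth = [t for f in folds for t in f.truth]
    all_pred = [p for f in folds for p in f.predictions]
    pooled = compute_metrics(all_truth, all_pred, classes)
    return EvaluationReport(
        setup={
            "algorithm": classifier_spec.algorithm,
            "hyper_grid": list(classifier_spec.hyper_grid),
            "feature_spec": feature_spec.__dict__.copy(),
            "scheme": plan.scheme,
            "k_outer": plan.k_outer,
            "k_inner": plan.k_inner,
            "seed": plan.seed,
        },
        folds=folds,
        aggregate=aggregate,
        pooled=pooled,
    )


def loocv(
    corpus: Corpus,
    docs: Mapping[str, TokenizedDocument],
    feature_spec: FeatureSpec,
    classifier_spec: ClassifierSpec,
    plan: CVPlan | None = None,
) -> EvaluationReport:
    """Leave-one-out evaluation with an inner stratified grid search.

    Each of the N rounds trains on N-1 instances (inner ``k_inner``-fold
    grid search within them) and predicts the held-out instance; metrics
    are computed over the pooled N predictions.
    """
    plan = plan or CVPlan(scheme="loocv")
    records, doc_list, y = _aligned(corpus, docs)
    classes = sorted(set(y))
    record_ids = [r.record_id for r in records]

    base = FeatureExtractor(
        doc_list, records, feature_spec,
        nonnegative=classifier_spec.needs_nonnegative,
    )
    factory = base.spawn

    folds: list[FoldResult] = []
    for fold_i, (tr, te) in enumerate(
        make_folds(y, CVPlan(scheme="loocv", seed=plan.seed))
    ):
        best = _grid_search(
            factory,
            classifier_spec.hyper_grid,
            classifier_spec,
            y,
            tr,
            plan.k_inner,
            plan.seed + 1000 * (fold_i + 1),
            classes,
        )
        ext = factory().fit(tr)
        clf = make_estimator(classifier_spec, best)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(ext.transform(tr), y[tr])
        pred = clf.predict(ext.transform(te))
        folds.append(
            FoldResult(
                fold=fold_i,
                test_record_ids=[record_ids[te[0]]],
                truth=[str(v) for v in y[te]],
                predictions=[str(v) for v in pred],
                best_param=best,
                metrics={},
                vocab_fingerprint=ext.fingerprint(),
                age_stats=ext.age_stats_,
            )
        )
    all_truth = [t for f in folds for t in f.truth]
    all_pred = [p for f in folds for p in f.predictions]
    pooled = compute_metrics(all_truth, all_pred, classes)
    return EvaluationReport(
        setup={
            "algorithm": classifier_spec.algorithm,
            "hyper_grid": list(classifier_spec.hyper_grid),
            "feature_spec": feature_spec.__dict__.copy(),
            "scheme": "loocv",
            "k_inner": plan.k_inner,
            "seed": plan.seed,
        },
        folds=folds,
        aggregate=pooled,
        pooled=pooled,
    )


def _mean_metrics(fold_metrics: list[dict], classes: Sequence[str]) -> dict:
    out = {
        "accuracy": float(np.mean([m["accuracy"] for m in fold_metrics])),
        "macro_f1": float(np.mean([m["macro_f1"] for m in fold_metrics])),
        "per_class": {},
    }
    for c in classes:
        out["per_class"][c] = {
            k: float(np.mean([m["per_class"][c][k] for m in fold_metrics]))
            for k in ("precision", "recall", "f1")
        }
    return out


def evaluate_all(
    corpus: Corpus,
    docs: Mapping[str, TokenizedDocument],
    plan: CVPlan,
    feature_groups: Mapping[str, FeatureSpec] | None = None,
    algorithms: Sequence[str] = ALGORITHMS,
) -> dict[tuple[str, str], EvaluationReport]:
    """The full classifiers x feature-groups grid of nested-CV reports."""
    feature_groups = feature_groups or FEATURE_GROUPS
    out = {}
    for algo in algorithms:
        for gname, fspec in feature_groups.items():
            out[(algo, gname)] = nested_cv(
                corpus, docs, fspec, ClassifierSpec(algorithm=algo), plan
            )
    return out


def reports_to_dataframe(reports: Mapping[tuple[str, str], EvaluationReport]):
    """Flatten an evaluate_all grid into a results-table-shaped DataFrame."""
    import pandas as pd

    rows = []
    for (algo, gname), rep in reports.items():
        agg = rep.aggregate
        row = {
            "classifier": algo,
            "features": gname,
            "accuracy": agg["accuracy"],
            "macro_f1": agg["macro_f1"],
        }
        for c, m in agg["per_class"].items():
            for k, v in m.items():
                row[f"{c}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
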