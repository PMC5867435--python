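"""Microblog text classification, ordinal sentiment scoring and agreement metrics.

The classification procedure mirrors the study design for coding microblog
posts: hold out a test fraction first, oversample minority classes *within
training folds only*, select hyperparameters by k-fold cross-validation over a
tuning grid, refit on the full (oversampled) training split, and report both
cross-validated and holdout metrics.

Two tasks share one machinery:

* ``relevance`` — five-class topic classification (four care-quality feedback
  classes plus not-care-quality), selected by macro-F1;
* ``sentiment`` — 1-5 star prediction for care-quality posts, selected by
  exact accuracy (with within-one-star accuracy also reported).

The model family is a linear bag-of-words classifier (token counts, uni+bigrams,
multinomial logistic regression); the procedure, not the family, carries the
scientific content here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, train_test_split

from .simulate import CorpusItem
from .types import ValidationError

logger = logging.getLogger("carevoice")

DEFAULT_GRID = ({"C": 0.1}, {"C": 1.0}, {"C": 10.0})


@dataclass
class LabelledText:
    text: str
    label: str
    stars: Optional[int] = None


def _as_labelled(corpus: Sequence) -> list[LabelledText]:
    out = []
    for item in corpus:
        if isinstance(item, (LabelledText, CorpusItem)):
            out.append(LabelledText(item.text, item.label, item.stars))
        else:
            text, label, stars = item
            out.append(LabelledText(text, label, stars))
    return out


# ---------------------------------------------------------------------------
# Oversampling

def oversample(corpus: Sequence, seed: int = 0) -> list[LabelledText]:
    """Balance classes by within-class sampling with replacement.

    Every class is brought up to the majority class's count; the majority
    class itself is untouched, and the original items always remain (the
    additions are appended after them).
    """
    items = _as_labelled(corpus)
    if not items:
        raise ValidationError("cannot oversample an empty corpus")
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[LabelledText]] = {}
    for it in items:
        by_label.setdefault(it.label, []).append(it)
    target = max(len(group) for group in by_label.values())
    out = list(items)
    for label in sorted(by_label):
        group = by_label[label]
        deficit = target - len(group)
        if deficit > 0:
            picks = rng.integers(0, len(group), size=deficit)
            out.extend(group[int(i)] for i in picks)
    return out


# ---------------------------------------------------------------------------
# Model

@dataclass
class TextModel:
    """A fitted linear bag-of-words classifier for one task."""

    task: str  # "relevance" | "sentiment"
    vectorizer: CountVectorizer
    classifier: LogisticRegression
    majority_label: object
    classes: tuple

    @property
    def vocabulary(self) -> dict:
        return self.vectorizer.vocabulary_

    def _predict(self, texts: Sequence[str]) -> list:
        X = self.vectorizer.transform(list(texts))
        preds = self.classifier.predict(X)
        in_vocab = np.asarray(X.sum(axis=1)).ravel() > 0
        n_oov = int((~in_vocab).sum())
        if n_oov:
            logger.warning(
                "%s: %d text(s) contained no in-vocabulary token; assigned training-majority label %r",
                self.task, n_oov, self.majority_label,
            )
        return [p if ok else self.majority_label for p, ok in zip(preds, in_vocab)]


def classify(model: TextModel, texts: Sequence[str]) -> list:
    """Assign a taxonomy label to each text (relevance models only)."""
    if model.task != "relevance":
        raise ValidationError(f"classify requires a relevance model, got task={model.task!r}")
    return model._predict(texts)


def score_sentiment(model: TextModel, texts: Sequence[str]) -> list[int]:
    """Assign a 1-5 star score to each text (sentiment models only)."""
    if model.task != "sentiment":
        raise ValidationError(f"score_sentiment requires a sentiment model, got task={model.task!r}")
    return [int(s) for s in model._predict(texts)]


def _fit_one(texts, labels, params, seed):
    vec = CountVectorizer(lowercase=True, token_pattern=r"[a-z0-9_]+", ngram_range=(1, 2), min_df=2)
    X = vec.fit_transform(texts)
    clf = LogisticRegression(C=params.get("C", 1.0), max_iter=2000, random_state=seed)
    clf.fit(X, labels)
    return vec, clf


def _metric(task, truth, pred):
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if task == "relevance":
        return float(f1_score(truth, pred, average="macro", zero_division=0))
    return float(np.mean(truth == pred))


def train_text_model(
    corpus: Sequence,
    task: str,
    n_folds: int = 5,
    grid: Sequence[dict] = DEFAULT_GRID,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[TextModel, dict]:
    """Train a text model with holdout-first splitting and leakage-safe CV.

    Returns the refitted model and a cv_report recording, per grid point, the
    per-fold metric; plus the selected parameters, holdout metrics (macro and
    micro averages for relevance; exact and within-one-star accuracy for
    sentiment) and the index partition used, so leakage can be audited.
    """
    if task not in ("relevance", "sentiment"):
        raise ValidationError(f"unknown task {task!r}")
    if not grid:
        raise ValidationError("hyperparameter grid is empty")
    if n_folds < 2:
        raise ValidationError("n_folds must be at least 2")
    items = _as_labelled(corpus)
    if task == "sentiment":
        items = [it for it in items if it.stars is not None]
        labels = np.array([it.stars for it in items])
    else:
        labels = np.array([it.label for it in items])
    if len(items) == 0:
        raise ValidationError("corpus has no usable items for this task")
    texts = np.array([it.text for it in items], dtype=object)
    indices = np.arange(len(items))

    counts = Counter(labels.tolist())
    stratify = labels if min(counts.values()) >= 2 else None
    train_idx, hold_idx = train_test_split(
        indices, test_size=holdout_fraction, random_state=seed, stratify=stratify
    )

    # Cross-validate each grid point on the training split only.
    cv_counts = Counter(labels[train_idx].tolist())
    n_folds_eff = min(n_folds, min(cv_counts.values()))
    if n_folds_eff < 2:
        n_folds_eff = 2
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    fold_metrics: list[list[float]] = []
    for params in grid:
        scores = []
        for fold_train, fold_val in skf.split(train_idx, labels[train_idx]):
            tr = train_idx[fold_train]
            va = train_idx[fold_val]
            balanced = oversample(
                [LabelledText(texts[i], str(labels[i]), None) for i in tr], seed=seed
            )
            vec, clf = _fit_one([b.text for b in balanced], [b.label for b in balanced], params, seed)
            pred = clf.predict(vec.transform(texts[va].tolist()))
            scores.append(_metric(task, labels[va].astype(str), pred))
        fold_metrics.append(scores)
    mean_scores = [float(np.mean(s)) for s in fold_metrics]
    best = int(np.argmax(mean_scores))
    best_params = grid[best]

    # Refit on the full (oversampled) training split.
    balanced = oversample(
        [LabelledText(texts[i], str(labels[i]), None) for i in train_idx], seed=seed
    )
    vec, clf = _fit_one([b.text for b in balanced], [b.label for b in balanced], best_params, seed)
    majority = Counter(labels[train_idx].tolist()).most_common(1)[0][0]
    model = TextModel(
        task=task,
        vectorizer=vec,
        classifier=clf,
        majority_label=int(majority) if task == "sentiment" else majority,
        classes=tuple(clf.classes_.tolist()),
    )

    hold_truth = labels[hold_idx].astype(str)
    hold_pred = np.array(
        [str(p) for p in (classify(model, texts[hold_idx].tolist()) if task == "relevance"
                          else score_sentiment(model, texts[hold_idx].tolist()))]
    )
    report = {
        "task": task,
        "grid": list(grid),
        "fold_metrics": fold_metrics,
        "mean_cv_metric": mean_scores,
        "selected_params": best_params,
        "n_folds": n_folds_eff,
        "train_indices": [int(i) for i in train_idx],
        "holdout_indices": [int(i) for i in hold_idx],
    }
    if task == "relevance":
        report["holdout_macro_f1"] = float(f1_score(hold_truth, hold_pred, average="macro", zero_division=0))
        report["holdout_micro_f1"] = float(f1_score(hold_truth, hold_pred, average="micro", zero_division=0))
        report["holdout_accuracy"] = float(np.mean(hold_truth == hold_pred))
    else:
        t = hold_truth.astype(int)
        p = hold_pred.astype(int)
        exact, within1 = star_accuracy(t, p)
        report["holdout_exact_accuracy"] = exact
        report["holdout_within_one_accuracy"] = within1
    return model, report


# ---------------------------------------------------------------------------
# Agreement and evaluation metrics

def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement rate; p_e the agreement expected by chance
    from the product of the two raters' marginal distributions.  Degenerate
    marginals with p_e = 1 (both raters constant) leave kappa undefined and
    raise :class:`ValidationError` explicitly.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValidationError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValidationError("cannot compute kappa on empty label vectors")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    count_a = Counter(a)
    count_b = Counter(b)
    p_e = sum(count_a[lab] * count_b.get(lab, 0) for lab in count_a) / n**2
    if abs(1.0 - p_e) < 1e-12:
        raise ValidationError("kappa undefined: chance agreement p_e equals 1")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class ClassMetrics:
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    support: int
    defined: bool = True


@dataclass
class MetricsReport:
    per_class: dict = field(default_factory=dict)
    macro_precision: float = float("nan")
    macro_recall: float = float("nan")
    macro_f1: float = float("nan")
    micro_precision: float = float("nan")
    micro_recall: float = float("nan")
    micro_f1: float = float("nan")
    accuracy: float = float("nan")
    undefined_classes: tuple = ()


def classification_metrics(truth: Sequence, predicted: Sequence) -> MetricsReport:
    """Per-class precision/recall/F1 plus macro and overall (micro) averages.

    Classes with a zero denominator (absent from truth and/or predictions)
    are flagged undefined rather than silently scored 0; macro averages run
    over the defined classes only.
    """
    t = list(truth)
    p = list(predicted)
    if len(t) != len(p):
        raise ValidationError(f"label vectors differ in length: {len(t)} vs {len(p)}")
    labels = sorted(set(t) | set(p), key=str)
    prec, rec, f1, support = precision_recall_fscore_support(
        t, p, labels=labels, zero_division=np.nan
    )
    report = MetricsReport()
    undefined = []
    for i, lab in enumerate(labels):
        defined = not (np.isnan(prec[i]) or np.isnan(rec[i]) or np.isnan(f1[i]))
        if not defined:
            undefined.append(lab)
        report.per_class[lab] = ClassMetrics(
            precision=None if np.isnan(prec[i]) else float(prec[i]),
            recall=None if np.isnan(rec[i]) else float(rec[i]),
            f1=None if np.isnan(f1[i]) else float(f1[i]),
            support=int(support[i]),
            defined=defined,
        )
    report.undefined_classes = tuple(undefined)
    report.macro_precision = float(np.nanmean(prec))
    report.macro_recall = float(np.nanmean(rec))
    report.macro_f1 = float(np.nanmean(f1))
    mp, mr, mf, _ = precision_recall_fscore_support(
        t, p, labels=labels, average="micro", zero_division=np.nan
    )
    report.micro_precision = float(mp)
    report.micro_recall = float(mr)
    report.micro_f1 = float(mf)
    report.accuracy = float(np.mean(np.array(t, dtype=object) == np.array(p, dtype=object)))
    return report


def star_accuracy(truth_stars: Sequence[int], predicted_stars: Sequence[int]) -> tuple[float, float]:
    """Exact and within-one-star agreement rates for 1-5 star predictions."""
    t = np.asarray(list(truth_stars), dtype=int)
    p = np.asarray(list(predicted_stars), dtype=int)
    if t.shape != p.shape:
        raise ValidationError(f"star vectors differ in length: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValidationError("cannot compute star accuracy on empty vectors")
    for arr, name in ((t, "truth"), (p, "predicted")):
        if arr.min() < 1 or arr.max() > 5:
            raise ValidationError(f"{name} stars outside [1, 5]")
    exact = float(np.mean(t == p))
    within_one = float(np.mean(np.abs(t - p) <= 1))
    return exact, within_one
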