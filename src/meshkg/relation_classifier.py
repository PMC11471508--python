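"""The D-Model relation classifier and its explanation/agreement tooling.

The D-Model is a dense multilayer perceptron over flattened qualifier
matrices: an input layer of size q^2 (900 for the 30-qualifier
vocabulary), one hidden layer of half that size with ReLU, and a softmax
output over either the three relation superclasses or the individual
relation types. Training uses cross-entropy with Adam and early stopping
on dev-set accuracy; everything is seeded and deterministic.

The model is implemented directly in numpy because downstream explanation
needs exact input gradients: Integrated Gradients attributes the model's
class score to individual matrix cells by integrating the gradient along
the straight path from a baseline (the all-zero matrix) to the input.
Qualifier-level scores aggregate cell attributions over each qualifier's
row and column, and drive the selection of the reduced vocabulary.

Two independently trained heads — superclass and relation type — are
combined by an agreement filter: a predicted relation type is accepted
only if its parent superclass matches the superclass head's prediction.
The cross-tabulation of the two heads' correctness over a test set (the
agreement matrix) quantifies how many errors this filter catches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .matrix_builder import (
    FULL_VOCAB,
    REDUCED_VOCAB,
    LabeledMatrix,
    QualifierMatrix,
    QualifierVocabulary,
    build_matrix,
    flatten,
    reduce_matrix,
    select_publications,
)
from .publications import PublicationRecord

__all__ = [
    "ModelConfig",
    "DModel",
    "EvaluationReport",
    "AgreementMatrix",
    "CandidateClassification",
    "train_dmodel",
    "evaluate",
    "compute_metrics",
    "pairwise_error_share",
    "integrated_gradients",
    "select_qualifiers",
    "agreement_filter",
    "agreement_matrix",
    "classify_candidates",
    "NO_QUALIFIER_DATA",
    "HEAD_DISAGREEMENT",
    "ASSIGNED",
]

logger = logging.getLogger(__name__)

NO_QUALIFIER_DATA = "no_qualifier_data"
HEAD_DISAGREEMENT = "head_disagreement"
ASSIGNED = "assigned"


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one D-Model head.

    ``input_size`` is the squared vocabulary size; ``hidden_size`` defaults
    to half of it. ``task`` selects which label a LabeledMatrix provides
    ("superclass" or "type").
    """

    input_size: int = 900
    hidden_size: int | None = None
    task: str = "superclass"
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    patience: int = 10
    normalize: bool = True
    seed: int = 0

    def resolved_hidden(self) -> int:
        return self.hidden_size if self.hidden_size is not None else self.input_size // 2


def _label_of(lm: LabeledMatrix, task: str) -> str:
    if task == "superclass":
        return lm.superclass
    if task == "type":
        return lm.relation_type
    raise ValueError(f"unknown task {task!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class DModel:
    """A trained two-layer perceptron head with a fixed label ordering."""

    def __init__(
        self,
        config: ModelConfig,
        labels: Sequence[str],
        params: Mapping[str, np.ndarray],
    ):
        self.config = config
        self.labels = tuple(labels)
        self.params = {k: np.asarray(v, dtype=np.float64) for k, v in params.items()}

    # -- feature preprocessing -------------------------------------------
    def preprocess(self, x: np.ndarray) -> np.ndarray:
        """Sum-normalise a feature vector (counts -> proportions)."""
        x = np.asarray(x, dtype=np.float64)
        if not self.config.normalize:
            return x
        s = x.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(s > 0, x / np.where(s > 0, s, 1.0), x)
        return out

    # -- forward pass -----------------------------------------------------
    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z1 = x @ self.params["W1"] + self.params["b1"]
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ self.params["W2"] + self.params["b2"]
        return z1, logits

    def logits(self, x: np.ndarray) -> np.ndarray:
        """Raw class scores of the plain network function (no input
        preprocessing — callers integrate gradients in this space)."""
        return self._forward(np.asarray(x, dtype=np.float64))[1]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(self.preprocess(x)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        proba = np.atleast_2d(self.predict_proba(x))
        idx = proba.argmax(axis=1)
        return np.array([self.labels[i] for i in idx])

    def predict_one(self, x: np.ndarray) -> str:
        return str(self.predict(np.atleast_2d(x))[0])

    # -- gradients --------------------------------------------------------
    def class_score(self, x: np.ndarray, target: int) -> float:
        """Logit of class ``target`` at input ``x`` (no preprocessing)."""
        return float(self.logits(np.asarray(x, dtype=np.float64))[..., target])

    def class_score_grad(self, x: np.ndarray, target: int) -> np.ndarray:
        """d logit_target / d x, exact, via the chain rule."""
        x = np.asarray(x, dtype=np.float64)
        z1, _ = self._forward(x)
        relu_mask = (z1 > 0).astype(np.float64)
        # dlogit/da1 = W2[:, target]; da1/dz1 = relu'(z1); dz1/dx = W1
        return self.params["W1"] @ (relu_mask * self.params["W2"][:, target])

    # -- persistence ------------------------------------------------------
    def save(self, fh: IO[str]) -> None:
        doc = {
            "format": "meshkg-dmodel/1",
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "input_size", "hidden_size", "task", "learning_rate",
                    "epochs", "batch_size", "patience", "normalize", "seed",
                )
            },
            "labels": list(self.labels),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        json.dump(doc, fh)

    @classmethod
    def load(cls, fh: IO[str]) -> "DModel":
        doc = json.load(fh)
        if doc.get("format") != "meshkg-dmodel/1":
            raise ValueError("not a recognised D-Model checkpoint")
        return cls(ModelConfig(**doc["config"]), doc["labels"], doc["params"])


def _dataset_arrays(
    split: Sequence[LabeledMatrix], task: str, labels: Sequence[str], normalize: bool
) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([flatten(lm.matrix) for lm in split])
    if normalize:
        s = X.sum(axis=1, keepdims=True)
        X = np.where(s > 0, X / np.where(s > 0, s, 1.0), X)
    label_index = {l: i for i, l in enumerate(labels)}
    y = np.array([label_index[_label_of(lm, task)] for lm in split])
    return X, y


def train_dmodel(
    train_split: Sequence[LabeledMatrix],
    dev_split: Sequence[LabeledMatrix],
    config: ModelConfig,
) -> DModel:
    """Train one D-Model head; returns the epoch state with the best dev
    accuracy (early stopping after ``config.patience`` stale epochs)."""
    labels = sorted({_label_of(lm, config.task) for lm in train_split})
    if len(labels) < 2:
        raise ValueError("training data contains a single class")
    n_classes = len(labels)

    X, y = _dataset_arrays(train_split, config.task, labels, config.normalize)
    if X.shape[1] != config.input_size:
        raise ValueError(
            f"feature size {X.shape[1]} != config.input_size {config.input_size}"
        )
    Xd, yd = _dataset_arrays(dev_split, config.task, labels, config.normalize)

    rng = np.random.default_rng(config.seed)
    d, h = config.input_size, config.resolved_hidden()
    params = {
        "W1": rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h)),
        "b1": np.zeros(h),
        "W2": rng.normal(0.0, np.sqrt(2.0 / h), size=(h, n_classes)),
        "b2": np.zeros(n_classes),
    }
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    model = DModel(config, labels, params)
    best = {k: v.copy() for k, v in params.items()}
    best_acc = -1.0
    stale = 0

    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            z1 = xb @ params["W1"] + params["b1"]
            a1 = np.maximum(z1, 0.0)
            logits = a1 @ params["W2"] + params["b2"]
            proba = _softmax(logits)
            delta = proba
            delta[np.arange(len(yb)), yb] -= 1.0
            delta /= len(yb)
            grads = {
                "W2": a1.T @ delta,
                "b2": delta.sum(axis=0),
            }
            da1 = delta @ params["W2"].T
            dz1 = da1 * (z1 > 0)
            grads["W1"] = xb.T @ dz1
            grads["b1"] = dz1.sum(axis=0)

            t += 1
            for k in params:
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                m_hat = adam_m[k] / (1 - beta1**t)
                v_hat = adam_v[k] / (1 - beta2**t)
                params[k] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        dev_logits = np.maximum(Xd @ params["W1"] + params["b1"], 0.0) @ params["W2"] + params["b2"]
        dev_acc = float((dev_logits.argmax(axis=1) == yd).mean())
        if dev_acc > best_acc:
            best_acc = dev_acc
            best = {k: v.copy() for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                logger.info("early stop at epoch %d (best dev acc %.4f)", epoch, best_acc)
                break

    return DModel(config, labels, best)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class one-vs-rest contingency metrics plus overall scores.

    ``precision``/``recall``/``f1`` with an empty denominator are reported
    as 0 and the class is listed in ``zero_division_classes``.
    """

    labels: tuple[str, ...]
    confusion: np.ndarray  # rows = true, columns = predicted
    tp: Mapping[str, int]
    tn: Mapping[str, int]
    fp: Mapping[str, int]
    fn: Mapping[str, int]
    precision: Mapping[str, float]
    recall: Mapping[str, float]
    f1: Mapping[str, float]
    accuracy: float
    macro_f1: float
    weighted_f1: float
    zero_division_classes: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())


def compute_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str] | None = None
) -> EvaluationReport:
    """Build the evaluation report from label sequences."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = tuple(labels)
    index = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    cm = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1

    total = cm.sum()
    tp, tn, fp, fn = {}, {}, {}, {}
    precision, recall, f1 = {}, {}, {}
    zero_div = []
    for l in labels:
        i = index[l]
        tp_i = int(cm[i, i])
        fp_i = int(cm[:, i].sum() - cm[i, i])
        fn_i = int(cm[i, :].sum() - cm[i, i])
        tn_i = int(total - tp_i - fp_i - fn_i)
        tp[l], tn[l], fp[l], fn[l] = tp_i, tn_i, fp_i, fn_i
        if tp_i + fp_i == 0 or tp_i + fn_i == 0:
            zero_div.append(l)
        precision[l] = tp_i / (tp_i + fp_i) if tp_i + fp_i else 0.0
        recall[l] = tp_i / (tp_i + fn_i) if tp_i + fn_i else 0.0
        denom = precision[l] + recall[l]
        f1[l] = 2 * precision[l] * recall[l] / denom if denom else 0.0

    support = {l: tp[l] + fn[l] for l in labels}
    accuracy = float(np.trace(cm) / total) if total else 0.0
    macro_f1 = float(np.mean([f1[l] for l in labels]))
    weighted_f1 = (
        float(sum(f1[l] * support[l] for l in labels) / total) if total else 0.0
    )
    return EvaluationReport(
        labels=labels,
        confusion=cm,
        tp=tp, tn=tn, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1,
        accuracy=accuracy, macro_f1=macro_f1, weighted_f1=weighted_f1,
        zero_division_classes=tuple(zero_div),
    )


def evaluate(model: DModel, test_split: Sequence[LabeledMatrix]) -> EvaluationReport:
    """Evaluate one head on a test split."""
    if not test_split:
        raise ValueError("test split is empty")
    X = np.stack([flatten(lm.matrix) for lm in test_split])
    y_true = [_label_of(lm, model.config.task) for lm in test_split]
    y_pred = list(model.predict(X))
    labels = list(model.labels) + sorted(set(y_true) - set(model.labels))
    return compute_metrics(y_true, y_pred, labels=labels)


def pairwise_error_share(report: EvaluationReport, class_a: str, class_b: str) -> float:
    """Fraction of all misclassifications that are confusions between one
    specific pair of classes (in either direction)."""
    idx = {l: i for i, l in enumerate(report.labels)}
    cm = report.confusion
    errors = cm.sum() - np.trace(cm)
    if errors == 0:
        return 0.0
    a, b = idx[class_a], idx[class_b]
    return float((cm[a, b] + cm[b, a]) / errors)


# ---------------------------------------------------------------------------
# Integrated Gradients


def integrated_gradients(
    model,
    input_vector: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
    target: int | None = None,
) -> np.ndarray:
    """Riemann approximation of Integrated Gradients.

    attribution_i = (x_i - b_i) * (1/steps) * sum_{k=1..steps}
                    dF/dx_i evaluated at b + (k/steps)(x - b)

    where F is the model's score for ``target`` (default: the class the
    model predicts at x, by highest score). ``model`` must expose
    ``class_score(x, target)`` and ``class_score_grad(x, target)``; any
    differentiable scorer with that surface works, not just a DModel.

    As steps grows the attributions satisfy the completeness axiom:
    their sum converges to F(x) - F(baseline).
    """
    x = np.asarray(input_vector, dtype=np.float64)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=np.float64)
    if b.shape != x.shape:
        raise ValueError("baseline must have the input's shape")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not (hasattr(model, "class_score") and hasattr(model, "class_score_grad")):
        raise TypeError("model does not expose a differentiable score surface")

    if target is None:
        if hasattr(model, "logits"):
            target = int(np.argmax(model.logits(x)))
        else:
            raise ValueError("target must be given for scorers without logits()")

    grad_sum = np.zeros_like(x)
    for k in range(1, steps + 1):
        point = b + (k / steps) * (x - b)
        grad_sum += model.class_score_grad(point, target)
    return (x - b) * grad_sum / steps


def qualifier_attribution_scores(
    attributions: np.ndarray, vocab: QualifierVocabulary
) -> np.ndarray:
    """Aggregate cell-level |attributions| to qualifier level: each
    qualifier's score is the absolute-attribution mass on its row plus its
    column of the q x q attribution matrix."""
    q = vocab.size
    a = np.abs(np.asarray(attributions, dtype=np.float64).reshape(q, q))
    return a.sum(axis=1) + a.sum(axis=0)


def select_qualifiers(
    model: DModel,
    sample_matrices: Sequence[LabeledMatrix],
    hierarchy: Mapping[str, str],
    k: int = 10,
    steps: int = 50,
) -> frozenset[str]:
    """The union over superclasses of the top-k qualifiers by mean
    Integrated-Gradients attribution.

    For each superclass, attributions are computed per sample matrix of
    that superclass (baseline zero, target = predicted class, in the
    model's normalised feature space), aggregated to qualifier level, and
    averaged; the top-k qualifiers per superclass are pooled.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vocab = sample_matrices[0].matrix.vocab
    by_super: dict[str, list[LabeledMatrix]] = {}
    for lm in sample_matrices:
        by_super.setdefault(lm.superclass, []).append(lm)

    selected: set[str] = set()
    for superclass in sorted(set(hierarchy.values())):
        samples = by_super.get(superclass, [])
        if not samples:
            logger.warning("no sample matrices for superclass %r; skipped", superclass)
            continue
        scores = np.zeros(vocab.size)
        for lm in samples:
            x = model.preprocess(flatten(lm.matrix))
            attr = integrated_gradients(model, x, steps=steps)
            scores += qualifier_attribution_scores(attr, vocab)
        scores /= len(samples)
        # top-k, ties broken by vocabulary order for determinism
        top = np.argsort(-scores, kind="stable")[:k]
        selected.update(vocab.names[i] for i in top)
    return frozenset(selected)


# ---------------------------------------------------------------------------
# Agreement filter and matrix


def agreement_filter(
    type_prediction: str,
    superclass_prediction: str,
    hierarchy: Mapping[str, str],
) -> str | None:
    """Accept the predicted relation type only when its parent superclass
    agrees with the superclass head's prediction."""
    if type_prediction not in hierarchy:
        raise KeyError(f"relation type {type_prediction!r} absent from hierarchy")
    if hierarchy[type_prediction] == superclass_prediction:
        return type_prediction
    return None


@dataclass(frozen=True)
class AgreementMatrix:
    """Cross-tabulation of per-sample correctness of the two heads."""

    both_correct: int
    type_wrong_only: int
    super_wrong_only: int
    both_wrong: int

    @property
    def total(self) -> int:
        return self.both_correct + self.type_wrong_only + self.super_wrong_only + self.both_wrong

    @property
    def total_type_wrong(self) -> int:
        return self.type_wrong_only + self.both_wrong

    @property
    def total_super_wrong(self) -> int:
        return self.super_wrong_only + self.both_wrong

    @property
    def both_correct_rate(self) -> float:
        """Percent of samples both heads get right."""
        return 100.0 * self.both_correct / self.total

    @property
    def both_wrong_rate(self) -> float:
        """Percent of samples both heads get wrong."""
        return 100.0 * self.both_wrong / self.total

    @property
    def type_error_detection_rate(self) -> float:
        """Percent of type-head errors on which the superclass head
        disagrees-by-being-right (wrong type, correct superclass)."""
        return 100.0 * self.type_wrong_only / self.total_type_wrong

    @property
    def super_error_detection_rate(self) -> float:
        """Percent of superclass-head errors with a correct type head."""
        return 100.0 * self.super_wrong_only / self.total_super_wrong


def agreement_matrix(
    type_correct_flags: Sequence[bool], superclass_correct_flags: Sequence[bool]
) -> AgreementMatrix:
    if len(type_correct_flags) != len(superclass_correct_flags):
        raise ValueError("flag sequences must have equal length")
    tc = np.asarray(type_correct_flags, dtype=bool)
    sc = np.asarray(superclass_correct_flags, dtype=bool)
    return AgreementMatrix(
        both_correct=int((tc & sc).sum()),
        type_wrong_only=int((~tc & sc).sum()),
        super_wrong_only=int((tc & ~sc).sum()),
        both_wrong=int((~tc & ~sc).sum()),
    )


# ---------------------------------------------------------------------------
# End-to-end candidate classification


@dataclass(frozen=True)
class CandidateClassification:
    pair: tuple[str, str]
    relation_type: str | None
    reason: str  # no_qualifier_data | head_disagreement | assigned


def classify_candidates(
    candidates: Sequence[tuple[str, str]],
    corpus: Sequence[PublicationRecord],
    model_super: DModel,
    model_type: DModel,
    hierarchy: Mapping[str, str],
    vocab: QualifierVocabulary = FULL_VOCAB,
    reduced_vocab: QualifierVocabulary = REDUCED_VOCAB,
    cap: int = 20,
) -> list[CandidateClassification]:
    """Run the full per-candidate pipeline: select publications, build and
    reduce the qualifier matrix, predict with both heads, apply the
    agreement filter. All failure modes come back as reasons, never
    exceptions."""
    out = []
    for x, y in candidates:
        pubs = select_publications(corpus, x, y, cap=cap)
        if not pubs:
            out.append(CandidateClassification((x, y), None, NO_QUALIFIER_DATA))
            continue
        matrix = build_matrix(pubs, x, y, vocab=vocab)
        reduced = reduce_matrix(matrix, reduced_vocab)
        features = flatten(reduced)
        pred_type = model_type.predict_one(features)
        pred_super = model_super.predict_one(features)
        accepted = agreement_filter(pred_type, pred_super, hierarchy)
        if accepted is None:
            out.append(CandidateClassification((x, y), None, HEAD_DISAGREEMENT))
        else:
            out.append(CandidateClassification((x, y), accepted, ASSIGNED))
    return out
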