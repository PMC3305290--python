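"""Motif-frequency features, maximum-margin classification and feature ranking.

The feature matrix counts, for every hairpin, the occurrences of every
catalog motif in its ss-string (raw counts by default; binary and
length-normalized variants are available).  A soft-margin SVM (linear or
Gaussian kernel) is trained on these features; with the linear kernel each
motif receives a normal-based weight

    w_j = sum_i alpha_i y_i x_ij

summed over the support vectors, and motifs are ranked by |w_j| (descending).
Incremental selection then retrains on the top-N ranked features for
N = step, 2*step, ... and records accuracy, specificity and sensitivity on
an evaluation set; the best N is the accuracy argmax (smallest N on ties).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .discovery import MotifCatalog, MotifRecord, SSMotif
from .hairpins import Hairpin, SSString

__all__ = [
    "FeatureMatrix",
    "TrainedModel",
    "MetricsReport",
    "build_feature_matrix",
    "count_matrix",
    "train_svm",
    "compute_feature_weights",
    "rank_motifs",
    "incremental_selection",
    "incremental_selection_cv",
    "SelectionResult",
    "evaluate",
    "roc_auc",
    "predict",
]

LABEL_TO_Y = {"positive": 1, "negative": -1}


@dataclass
class FeatureMatrix:
    """Hairpins x motifs occurrence-count matrix."""

    X: np.ndarray
    row_ids: list[str]
    motif_texts: list[str]

    def __post_init__(self):
        if self.X.shape != (len(self.row_ids), len(self.motif_texts)):
            raise ValueError("feature matrix dimensions do not match row/column ids")


def count_matrix(motifs: list[SSMotif], ss_list: list[SSString], mode: str = "count") -> np.ndarray:
    """Occurrence counts of each motif (columns) in each ss-string (rows).

    ``mode``: "count" (raw occurrence counts), "binary" (presence), or
    "normalized" (count divided by ss-string length).
    """
    if mode not in ("count", "binary", "normalized"):
        raise ValueError(f"unknown feature mode {mode!r}")
    n = len(ss_list)
    lens = np.array([len(s) for s in ss_list], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.int64)
    total = int(lens.sum())
    flat_nuc = np.empty(total, dtype=np.uint8)
    flat_str = np.empty(total, dtype=np.uint8)
    seq_id = np.empty(total, dtype=np.int64)
    for i, ss in enumerate(ss_list):
        o = offsets[i]
        flat_nuc[o : o + len(ss)] = ss.nuc
        flat_str[o : o + len(ss)] = ss.struct
        seq_id[o : o + len(ss)] = i
    pos_in_seq = np.arange(total, dtype=np.int64) - offsets[seq_id]

    X = np.zeros((n, len(motifs)), dtype=np.float64)
    starts_cache: dict[int, np.ndarray] = {}
    for j, motif in enumerate(motifs):
        m = len(motif)
        if m == 0 or total == 0:
            continue
        if m not in starts_cache:
            starts_cache[m] = np.nonzero(pos_in_seq + m <= lens[seq_id])[0]
        cand = starts_cache[m]
        if len(cand) == 0:
            continue
        ok = np.ones(len(cand), dtype=bool)
        for t, sym in enumerate(motif.symbols):
            p = cand + t
            if sym.nuc != "N":
                ok &= flat_nuc[p] == sym.nuc_code
            if sym.struct != "S":
                ok &= flat_str[p] == sym.struct_code
        hits = cand[ok]
        if len(hits):
            X[:, j] = np.bincount(seq_id[hits], minlength=n)
    if mode == "binary":
        X = (X > 0).astype(np.float64)
    elif mode == "normalized":
        X = X / np.maximum(lens, 1)[:, None]
    return X


def build_feature_matrix(
    catalog: MotifCatalog,
    corpus: list[tuple[Hairpin, SSString]],
    mode: str = "count",
) -> FeatureMatrix:
    """Featurize a corpus of (hairpin, ss-string) pairs against a catalog."""
    if len(catalog) == 0:
        raise ValueError("catalog must be nonempty")
    if not corpus:
        raise ValueError("corpus must be nonempty")
    ss_list = [ss for _, ss in corpus]
    X = count_matrix(catalog.motifs, ss_list, mode=mode)
    return FeatureMatrix(X=X, row_ids=[hp.id for hp, _ in corpus], motif_texts=catalog.motif_texts)


@dataclass
class TrainedModel:
    """A trained SVM in self-contained form (no retraining needed to predict)."""

    kernel: str  # "linear" or "gaussian"
    C: float
    gamma: float | None  # None for linear
    support_vectors: np.ndarray  # (n_sv, k)
    dual_coef: np.ndarray  # alpha_i * y_i, (n_sv,)
    bias: float
    selected_motifs: list[str]  # ordered motif texts for the feature columns
    feature_mode: str = "count"

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError("feature count does not match the model")
        if self.kernel == "linear":
            kernel_matrix = X @ self.support_vectors.T
        elif self.kernel == "gaussian":
            sq = (
                (X**2).sum(axis=1)[:, None]
                - 2 * X @ self.support_vectors.T
                + (self.support_vectors**2).sum(axis=1)[None, :]
            )
            kernel_matrix = np.exp(-self.gamma * np.maximum(sq, 0.0))
        else:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        return kernel_matrix @ self.dual_coef + self.bias

    def save(self, path) -> None:
        payload = {
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "selected_motifs": self.selected_motifs,
            "feature_mode": self.feature_mode,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            kernel=payload["kernel"],
            C=payload["C"],
            gamma=payload["gamma"],
            support_vectors=np.asarray(payload["support_vectors"], dtype=np.float64),
            dual_coef=np.asarray(payload["dual_coef"], dtype=np.float64),
            bias=float(payload["bias"]),
            selected_motifs=list(payload["selected_motifs"]),
            feature_mode=payload.get("feature_mode", "count"),
        )


def _as_y(labels) -> np.ndarray:
    y = np.asarray([LABEL_TO_Y.get(v, v) for v in labels], dtype=np.float64)
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be positive/negative (or +1/-1)")
    return y


def train_svm(
    X,
    y,
    kernel: str = "linear",
    C: float = 1.0,
    gamma: float | None = None,
    motif_texts: list[str] | None = None,
    feature_mode: str = "count",
) -> TrainedModel:
    """Fit a soft-margin SVM; decision(x) = sum_i alpha_i y_i k(x_i, x) + b.

    ``gamma`` defaults to 1/k (k = number of features) for the Gaussian
    kernel and is ignored by the linear kernel.  Features are used unscaled
    so that linear weights stay interpretable as per-motif contributions.
    """
    if isinstance(X, FeatureMatrix):
        motif_texts = motif_texts or X.motif_texts
        X = X.X
    X = np.asarray(X, dtype=np.float64)
    yv = _as_y(y)
    if len(np.unique(yv)) < 2:
        raise ValueError("training labels must contain both classes")
    if C <= 0:
        raise ValueError("C must be > 0")
    if kernel not in ("linear", "gaussian"):
        raise ValueError(f"unknown kernel {kernel!r}")
    if kernel == "gaussian":
        gamma_value = gamma if gamma is not None else 1.0 / X.shape[1]
        clf = SVC(kernel="rbf", C=C, gamma=gamma_value)
    else:
        gamma_value = None
        clf = SVC(kernel="linear", C=C)
    clf.fit(X, yv)
    # sklearn orders classes_ as [-1, 1]; decision_function > 0 <=> class +1
    model = TrainedModel(
        kernel=kernel,
        C=C,
        gamma=gamma_value,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        selected_motifs=list(motif_texts) if motif_texts is not None else [],
        feature_mode=feature_mode,
    )
    return model


def compute_feature_weights(model: TrainedModel) -> np.ndarray:
    """Normal-based weights w_j = sum_i alpha_i y_i x_ij (linear kernel only)."""
    if model.kernel != "linear":
        raise ValueError("feature weights are defined for the linear kernel only")
    return model.dual_coef @ model.support_vectors


def rank_motifs(
    catalog: MotifCatalog, weights: np.ndarray, mode: str = "abs"
) -> tuple[MotifCatalog, np.ndarray]:
    """Rank motifs by weight, descending.

    ``mode="abs"`` (default) sorts on |w_j| so that discriminative motifs of
    both classes rise to the top; ``mode="signed"`` sorts on w_j directly.
    Ties break lexicographically on the motif text.  Returns the re-ordered
    catalog (ranks filled 1..k, weights attached) and the column permutation.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != len(catalog):
        raise ValueError("one weight per motif required")
    if mode not in ("abs", "signed"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    key = np.abs(weights) if mode == "abs" else weights
    order = sorted(range(len(catalog)), key=lambda j: (-key[j], catalog[j].motif.text))
    records = []
    for rank, j in enumerate(order, start=1):
        rec = catalog[j]
        records.append(
            MotifRecord(
                motif=rec.motif,
                support_pos=rec.support_pos,
                support_neg=rec.support_neg,
                origin=rec.origin,
                weight=float(weights[j]),
                rank=rank,
            )
        )
    return MotifCatalog(records), np.asarray(order, dtype=np.int64)


@dataclass
class MetricsReport:
    """Binary classification metrics: accuracy, specificity, sensitivity."""

    tp: int
    tn: int
    fp: int
    fn: int
    roc_points: np.ndarray | None = None
    auc: float | None = None

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.tn + self.fp + self.fn, 1)

    @property
    def sp(self) -> float:
        return self.tn / max(self.tn + self.fp, 1)

    @property
    def se(self) -> float:
        return self.tp / max(self.tp + self.fn, 1)

    def as_dict(self) -> dict:
        d = {
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "ACC": self.acc,
            "SP": self.sp,
            "SE": self.se,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        return d

    def pretty(self) -> str:
        parts = [f"ACC = {100 * self.acc:.2f}%", f"SP = {100 * self.sp:.2f}%", f"SE = {100 * self.se:.2f}%"]
        if self.auc is not None:
            parts.append(f"AUC = {self.auc:.4f}")
        parts.append(f"(TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn})")
        return "  ".join(parts)


def evaluate(predictions, labels) -> MetricsReport:
    """Confusion-count metrics from predicted vs true labels."""
    yp = _as_y(predictions)
    yt = _as_y(labels)
    if len(yp) != len(yt):
        raise ValueError(f"length mismatch: {len(yp)} predictions vs {len(yt)} labels")
    if len(np.unique(yt)) < 2:
        raise ValueError("labels must contain both classes for SP/SE")
    tp = int(((yp == 1) & (yt == 1)).sum())
    tn = int(((yp == -1) & (yt == -1)).sum())
    fp = int(((yp == 1) & (yt == -1)).sum())
    fn = int(((yp == -1) & (yt == 1)).sum())
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn)


def roc_auc(decision_values, labels) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep; AUC by the trapezoid rule.

    The AUC equals the rank statistic: the probability that a random
    positive outscores a random negative, ties counted half.
    """
    scores = np.asarray(decision_values, dtype=np.float64)
    yt = _as_y(labels)
    if len(np.unique(yt)) < 2:
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, _ = roc_curve(yt, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class SelectionResult:
    curve: pd.DataFrame  # columns: n, acc, sp, se
    best_n: int
    best_model: TrainedModel


def incremental_selection(
    ranked_catalog: MotifCatalog,
    X_train: np.ndarray,
    y_train,
    X_eval: np.ndarray,
    y_eval,
    step: int = 100,
    kernel: str = "linear",
    C: float = 1.0,
    gamma: float | None = None,
    feature_mode: str = "count",
) -> SelectionResult:
    """Accuracy curve over top-N ranked features, N = step, 2*step, ..., k.

    ``X_train``/``X_eval`` columns must follow the ranked catalog order.
    Returns the metric curve, the accuracy-maximizing N (smallest on ties)
    and the model retrained at that N.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    k = len(ranked_catalog)
    if X_train.shape[1] != k or X_eval.shape[1] != k:
        raise ValueError("feature matrices must have one column per ranked motif")
    ns = list(range(step, k + 1, step))
    if not ns or ns[-1] != k:
        ns.append(k)
    rows = []
    best = None  # (acc, n, model)
    texts = ranked_catalog.motif_texts
    for n in ns:
        model = train_svm(
            X_train[:, :n],
            y_train,
            kernel=kernel,
            C=C,
            gamma=gamma,
            motif_texts=texts[:n],
            feature_mode=feature_mode,
        )
        scores = model.decision_function(X_eval[:, :n])
        preds = np.where(scores > 0, 1, -1)
        rep = evaluate(preds, y_eval)
        rows.append({"n": n, "acc": rep.acc, "sp": rep.sp, "se": rep.se})
        if best is None or rep.acc > best[0]:
            best = (rep.acc, n, model)
    curve = pd.DataFrame(rows)
    return SelectionResult(curve=curve, best_n=best[1], best_model=best[2])


def incremental_selection_cv(
    ranked_catalog: MotifCatalog,
    X: np.ndarray,
    y,
    n_folds: int = 5,
    step: int = 100,
    kernel: str = "linear",
    C: float = 1.0,
    gamma: float | None = None,
    seed: int = 0,
    feature_mode: str = "count",
) -> SelectionResult:
    """Cross-validated variant of :func:`incremental_selection`.

    Choosing N on the held-out test set leaks it into model selection;
    this variant scores each N by mean accuracy over stratified folds of
    the training data, then refits the best-N model on all of it.
    """
    from sklearn.model_selection import StratifiedKFold

    if step < 1:
        raise ValueError("step must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    yv = _as_y(y)
    k = len(ranked_catalog)
    if X.shape[1] != k:
        raise ValueError("feature matrix must have one column per ranked motif")
    ns = list(range(step, k + 1, step))
    if not ns or ns[-1] != k:
        ns.append(k)
    folds = list(
        StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X, yv)
    )
    texts = ranked_catalog.motif_texts
    rows = []
    best = None
    for n in ns:
        accs, sps, ses = [], [], []
        for train_idx, val_idx in folds:
            model = train_svm(
                X[train_idx][:, :n], yv[train_idx], kernel=kernel, C=C, gamma=gamma
            )
            scores = model.decision_function(X[val_idx][:, :n])
            rep = evaluate(np.where(scores > 0, 1, -1), yv[val_idx])
            accs.append(rep.acc)
            sps.append(rep.sp)
            ses.append(rep.se)
        acc = float(np.mean(accs))
        rows.append({"n": n, "acc": acc, "sp": float(np.mean(sps)), "se": float(np.mean(ses))})
        if best is None or acc > best[0]:
            best = (acc, n)
    best_model = train_svm(
        X[:, : best[1]], yv, kernel=kernel, C=C, gamma=gamma,
        motif_texts=texts[: best[1]], feature_mode=feature_mode,
    )
    return SelectionResult(curve=pd.DataFrame(rows), best_n=best[1], best_model=best_model)


def predict(
    hairpins: list[Hairpin], model: TrainedModel
) -> tuple[list[str], np.ndarray, list[tuple[str, str]]]:
    """Classify hairpins with a trained model.

    Hairpins are featurized against the model's own ordered motif list; the
    sign of the decision value gives the label.  Records that cannot be
    encoded are reported in the error list and skipped (their label is
    ``"error"`` and decision value NaN).
    """
    motifs = [SSMotif.from_text(t) for t in model.selected_motifs]
    ss_list: list[SSString | None] = []
    errors: list[tuple[str, str]] = []
    for hp in hairpins:
        try:
            ss_list.append(hp.encode())
        except ValueError as exc:
            errors.append((hp.id, str(exc)))
            ss_list.append(None)
    good = [i for i, ss in enumerate(ss_list) if ss is not None]
    decisions = np.full(len(hairpins), np.nan)
    labels = ["error"] * len(hairpins)
    if good:
        X = count_matrix(motifs, [ss_list[i] for i in good], mode=model.feature_mode)
        scores = model.decision_function(X)
        for i, s in zip(good, scores):
            decisions[i] = s
            labels[i] = "positive" if s > 0 else "negative"
    return labels, decisions, errors
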