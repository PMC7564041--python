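"""Ranking quality metrics and the two validation protocols.

* :func:`auroc` — mid-rank AU-ROC (equal to the Mann-Whitney U statistic
  over n+ * n-) plus the confusion metrics of the score > 0 classification
  convention.
* :func:`leave_one_out` — exact L1O: the whole rule selection is redone for
  every held-out sample.  The default incremental path caches each rule's
  full-data coverage and re-derives every fold's counts (a-1, b or b-1,
  c or c-1, d or d-1) from it, which is bit-identical to literally
  retraining from scratch (``method="naive"``) because removing one sample
  can only shift a rule's urn counts in those ways; a prefilter keeps only
  rules that could reach the cutoff in at least one of the reachable count
  states.
* :func:`randomization_test` — Y-scrambling: training labels are permuted
  (class counts preserved), the model is retrained from scratch per shuffle
  and the external-set AU-ROC distribution is summarized by a Gaussian fit,
  a z-score for the true model and a normal upper-tail p.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import matthews_corrcoef, roc_auc_score, roc_curve

from .hypergeom import tail_table
from .library import Library
from .model import VotingModel, iter_rule_coverage, score, train

__all__ = [
    "RocSummary",
    "auroc",
    "LeaveOneOutResult",
    "leave_one_out",
    "RandomizationReport",
    "randomization_test",
]


@dataclass
class RocSummary:
    """AU-ROC, the ROC curve and threshold-0 confusion metrics."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float

    def metrics(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "mcc": self.mcc,
        }


def auroc(scores, labels, *, threshold: float = 0.0) -> RocSummary:
    """Mid-rank AU-ROC of ``scores`` against boolean ``labels``, with the
    confusion metrics of the net-score > ``threshold`` classification.

    Negative-looking rankings are reported as AUC < 0.5 (the 1 - AUC
    symmetry), never as negative values.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AU-ROC needs both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    pred = scores > threshold
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    return RocSummary(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        accuracy=(tp + tn) / len(labels),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        precision=tp / (tp + fp) if tp + fp else 0.0,
        mcc=float(matthews_corrcoef(labels, pred)),
    )


@dataclass
class LeaveOneOutResult:
    """Held-out vote score per sample plus the ranking summary."""

    sample_ids: list
    scores: np.ndarray
    labels: np.ndarray
    summary: RocSummary

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "held_out_score": self.scores,
                "label": self.labels.astype(int),
            }
        )


def _check_loo_feasible(labels: np.ndarray) -> None:
    if labels.sum() < 2 or (~labels).sum() < 2:
        bad = np.where(labels if labels.sum() < 2 else ~labels)[0]
        raise ValueError(
            "leave-one-out needs >= 2 samples per class so every fold keeps "
            f"both classes; removing sample index {bad[0]} would empty one"
        )


def leave_one_out(
    lib: Library,
    orders: Sequence[int],
    p_c: float,
    *,
    method: str = "incremental",
    positive_only: bool = False,
) -> LeaveOneOutResult:
    """Exact leave-one-out: for each sample, retrain on the other a-1
    (recomputing b and every rule's c, d, tails and votes) and score the
    held-out sample with that fold's model."""
    labels = lib.label_array()
    _check_loo_feasible(labels)
    if method == "naive":
        scores = _loo_naive(lib, orders, p_c, positive_only)
    elif method == "incremental":
        scores = _loo_incremental(lib, orders, p_c, positive_only)
    else:
        raise ValueError(f"unknown method {method!r}")
    return LeaveOneOutResult(lib.sample_ids, scores, labels, auroc(scores, labels))


def _loo_naive(lib, orders, p_c, positive_only) -> np.ndarray:
    a = lib.a
    scores = np.zeros(a, dtype=np.int64)
    X = lib.samples.to_numpy(dtype=object)
    import warnings

    for i in range(a):
        keep = np.ones(a, dtype=bool)
        keep[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty fold models are expected
            fold_model = train(
                lib.subset(keep), orders, p_c, positive_only=positive_only
            )
        scores[i] = fold_model.vote_scores(X[i : i + 1])[0]
    return scores


def _loo_incremental(lib, orders, p_c, positive_only) -> np.ndarray:
    a, b = lib.a, lib.b
    labels = lib.label_array()
    codes = lib.codes()
    tables = {b: tail_table(a - 1, b), b - 1: tail_table(a - 1, b - 1)}

    # Retention pass: keep a rule iff some reachable single-removal count
    # state could put a tail at or below p_c.  Removing one sample maps
    # (c, d) to itself (uncovered), (c-1, d) (covered non-interest) or
    # (c-1, d-1) (covered interest), with b dropping by one iff the removed
    # sample is of interest.
    retained = []
    for rule, mask in iter_rule_coverage(codes, lib.alphabets, tuple(orders)):
        c = int(mask.sum())
        if c == 0:
            continue
        d = int(mask[labels].sum())
        states = []
        if (a - b) - (c - d) > 0:  # remove uncovered non-interest
            states.append((b, c, d))
        if b - d > 0:  # remove uncovered interest
            states.append((b - 1, c, d))
        if c - d > 0:  # remove covered non-interest
            states.append((b, c - 1, d))
        if d > 0:  # remove covered interest
            states.append((b - 1, c - 1, d - 1))
        for bb, cc, dd in states:
            t = tables[bb]
            if t.upper[cc, dd] <= p_c or (not positive_only and t.lower[cc, dd] <= p_c):
                retained.append((mask, c, d, rule))
                break

    # Fold pass: a rule contributes to sample i's held-out score only if it
    # covers i; its fold counts are then (c-1, d-label[i]) with b-label[i].
    scores = np.zeros(a, dtype=np.int64)
    for mask, c, d, _rule in retained:
        for i in np.flatnonzero(mask):
            li = bool(labels[i])
            t = tables[b - 1 if li else b]
            cc, dd = c - 1, d - int(li)
            if cc == 0:
                continue
            if t.upper[cc, dd] <= p_c:
                scores[i] += 1
            elif not positive_only and t.lower[cc, dd] <= p_c:
                scores[i] -= 1
    return scores


@dataclass
class RandomizationReport:
    """Y-scrambling outcome: the true (training, external) AU-ROC point, the
    shuffled points, and the Gaussian summary of the shuffled external
    AU-ROC distribution."""

    true_training_auc: float
    true_external_auc: float
    shuffled: pd.DataFrame  # columns: shuffle, training_auc, external_auc
    mean: float
    sd: float
    z: float
    p: float

    @property
    def max_shuffled_external(self) -> float:
        return float(self.shuffled["external_auc"].max())


def randomization_test(
    train_lib: Library,
    external_lib: Library,
    n_shuffles: int,
    seed: int,
    orders: Sequence[int],
    p_c: float,
    *,
    positive_only: bool = False,
) -> RandomizationReport:
    """Retrain on label-permuted training data ``n_shuffles`` times and
    compare the true model's external AU-ROC against the shuffled
    distribution (Gaussian fit, z-score, normal upper-tail p).

    External labels are never touched; shuffles permute the training labels,
    preserving class counts.  Reproducible for a fixed seed (per-shuffle
    substreams are spawned from one master seed sequence).
    """
    if n_shuffles < 1:
        raise ValueError(f"n_shuffles must be >= 1, got {n_shuffles}")
    ext_labels = external_lib.label_array()

    def _point(lib: Library) -> tuple[float, float]:
        model = train(lib, orders, p_c, positive_only=positive_only)
        tr = auroc(score(model, lib).scores, lib.label_array()).auc
        ex = auroc(score(model, external_lib).scores, ext_labels).auc
        return tr, ex

    import warnings

    true_tr, true_ex = _point(train_lib)
    master = np.random.SeedSequence(seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shuffled models may come up empty
        for s, child in enumerate(master.spawn(n_shuffles)):
            rng = np.random.default_rng(child)
            permuted = train_lib.labels.copy()
            permuted[:] = rng.permutation(permuted.to_numpy())
            shuffled_lib = Library(
                train_lib.samples,
                permuted,
                train_lib.missing_token,
                train_lib.alphabets,
            )
            tr, ex = _point(shuffled_lib)
            rows.append((s, tr, ex))
    shuffled = pd.DataFrame(rows, columns=["shuffle", "training_auc", "external_auc"])
    mean = float(shuffled["external_auc"].mean())
    sd = float(shuffled["external_auc"].std(ddof=1)) if n_shuffles > 1 else float("nan")
    z = (true_ex - mean) / sd if sd and sd > 0 else float("inf")
    p = float(norm.sf(z))
    return RandomizationReport(true_tr, true_ex, shuffled, mean, sd, z, p)
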