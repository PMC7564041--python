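"""The SSIR consensus model: rule significance, selection, voting, ranking.

Training evaluates every canonical rule of the requested orders against a
two-class library.  For a rule condensing c samples of which d are of
interest, the upper hypergeometric tail p(d+) measures enrichment and the
lower tail p(d-) depletion; with a cutoff p_c < 0.5 a rule enters the pool
with vote +1 when p(d+) <= p_c and with vote -1 when p(d-) <= p_c (at most
one can hold, since p(d+) + p(d-) >= 1).  A sample's score is the sum of the
votes of all pool rules that condense it; the scores rank the samples, for
the training set and for external samples alike.

The central object is :class:`SSIRClassifier`, a scikit-learn style
estimator (``fit`` / ``decision_function`` / ``predict``); the module-level
:func:`train` and :func:`score` are thin wrappers over it operating on
:class:`~ssir.library.Library` objects.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterator, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .hypergeom import UrnCounts, lower_tail, tail_table, upper_tail
from .library import Library
from .rules import (
    Rule,
    Selector,
    enumerate_rules,
    matches_matrix,
    rule_from_text,
    rule_to_text,
    sample_rules,
)

__all__ = [
    "RuleEvaluation",
    "VotingModel",
    "RankingResult",
    "SSIRClassifier",
    "evaluate_rule",
    "train",
    "score",
    "descriptor_votes",
]

MAX_EXHAUSTIVE_ORDER = 4


@dataclass(frozen=True)
class RuleEvaluation:
    """One rule's urn counts, both tail p-values and its vote.

    ``vote`` is +1 (enrichment, p_plus <= p_c), -1 (depletion,
    p_minus <= p_c) or None when no cutoff has been applied.
    """

    rule: Rule
    counts: UrnCounts
    p_plus: float
    p_minus: float
    vote: int | None

    @property
    def p_value(self) -> float:
        """The significance that admits the rule: p_plus for a +1 vote,
        p_minus for -1; min of the two when no vote is set."""
        if self.vote == 1:
            return self.p_plus
        if self.vote == -1:
            return self.p_minus
        return min(self.p_plus, self.p_minus)


@dataclass
class VotingModel:
    """The selected rule pool acting as a voting expert system."""

    evaluations: tuple[RuleEvaluation, ...]
    p_c: float
    a: int
    b: int
    orders: tuple[int, ...]
    mode: str
    seed: int | None
    n_rules_evaluated: int
    descriptors: tuple[str, ...]
    missing_token: str = "?"

    @property
    def n_rules(self) -> int:
        return len(self.evaluations)

    def vote_scores(self, X) -> np.ndarray:
        """Integer vote sum per sample of a (samples x descriptors) token
        array or DataFrame; works identically for training and external
        samples (unseen tokens fail positive selectors and satisfy negated
        ones)."""
        X = _token_matrix(X)
        if X.shape[1] != len(self.descriptors):
            raise ValueError(
                f"schema mismatch: model has {len(self.descriptors)} descriptors, "
                f"samples have {X.shape[1]}"
            )
        scores = np.zeros(X.shape[0], dtype=np.int64)
        for ev in self.evaluations:
            mask = matches_matrix(ev.rule, X, self.missing_token)
            scores[mask] += ev.vote
        return scores

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write the model as a JSON header line plus one rule per line in
        the rule text format (1-based ``pos:LEVEL`` selectors, descriptor
        names in a sidecar column, counts, admitting p-value and vote)."""
        header = {
            "a": self.a,
            "b": self.b,
            "p_c": self.p_c,
            "orders": list(self.orders),
            "mode": self.mode,
            "seed": self.seed,
            "n_rules_evaluated": self.n_rules_evaluated,
            "missing_token": self.missing_token,
            "descriptors": list(self.descriptors),
        }
        with open(path, "w") as fh:
            fh.write("#ssir-model\t" + json.dumps(header) + "\n")
            fh.write("rule\tdescriptors\tc\td\tp_value\tvote\n")
            for ev in self.evaluations:
                names = "&".join(self.descriptors[p] for p in ev.rule.positions)
                fh.write(
                    f"{rule_to_text(ev.rule)}\t{names}\t{ev.counts.c}\t{ev.counts.d}"
                    f"\t{ev.p_value!r}\t{ev.vote:+d}\n"
                )

    @classmethod
    def load(cls, path) -> "VotingModel":
        """Reload a saved model; reloaded models reproduce identical scores
        bit-exactly (votes are integers and rules round-trip textually)."""
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#ssir-model\t"):
                raise ValueError(f"{path}: not an SSIR model file")
            header = json.loads(first.split("\t", 1)[1])
            fh.readline()  # column header
            table = tail_table(header["a"], header["b"])
            evaluations = []
            for line in fh:
                if not line.strip():
                    continue
                text, _names, c, d, _p, vote = line.rstrip("\n").split("\t")
                c, d, vote = int(c), int(d), int(vote)
                evaluations.append(
                    RuleEvaluation(
                        rule_from_text(text),
                        UrnCounts(header["a"], header["b"], c, d),
                        float(table.upper[c, d]),
                        float(table.lower[c, d]),
                        vote,
                    )
                )
        return cls(
            tuple(evaluations),
            header["p_c"],
            header["a"],
            header["b"],
            tuple(header["orders"]),
            header["mode"],
            header["seed"],
            header["n_rules_evaluated"],
            tuple(header["descriptors"]),
            header["missing_token"],
        )


@dataclass
class RankingResult:
    """Per-sample vote totals and the ranking they induce (score descending,
    ties kept in input order)."""

    sample_ids: list
    scores: np.ndarray
    order: np.ndarray  # positions sorted best-first
    ranks: np.ndarray  # 1-based rank per sample (input order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.sample_ids, "score": self.scores, "rank": self.ranks}
        )


def _ranking(sample_ids, scores: np.ndarray) -> RankingResult:
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=np.int64)
    ranks[order] = np.arange(1, len(scores) + 1)
    return RankingResult(list(sample_ids), scores, order, ranks)


def _token_matrix(X) -> np.ndarray:
    if isinstance(X, Library):
        X = X.samples
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=object)
    X = np.asarray(X, dtype=object)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x descriptors array")
    return X


def _infer_alphabets(X: np.ndarray, missing_token: str) -> tuple[tuple[str, ...], ...]:
    return tuple(
        tuple(sorted(set(X[:, j]) - {missing_token})) for j in range(X.shape[1])
    )


def _codes(X: np.ndarray, alphabets) -> np.ndarray:
    out = np.full(X.shape, -1, dtype=np.int32)
    for j, alphabet in enumerate(alphabets):
        lookup = {tok: i for i, tok in enumerate(alphabet)}
        out[:, j] = [lookup.get(v, -1) for v in X[:, j]]
    return out


def iter_rule_coverage(
    codes: np.ndarray,
    alphabets: Sequence[Sequence[str]],
    orders: Sequence[int],
    *,
    mode: str = "exhaustive",
    seed: int | None = None,
    n_rules: int | None = None,
) -> Iterator[tuple[Rule, np.ndarray]]:
    """Stream (rule, coverage mask) pairs over the requested rule space.

    Coverage masks are boolean over samples; missing cells (code -1) match
    no selector.  This is the single enumeration path shared by training and
    by the incremental leave-one-out cache.
    """
    valid = codes >= 0
    if mode == "exhaustive":
        for k in orders:
            if k > MAX_EXHAUSTIVE_ORDER:
                raise ValueError(
                    f"exhaustive enumeration is limited to order <= "
                    f"{MAX_EXHAUSTIVE_ORDER} (combinatorial explosion); use mode='sample'"
                )
            for rule in enumerate_rules(alphabets, k):
                yield rule, _rule_mask(rule, codes, valid, alphabets)
    elif mode == "sample":
        if seed is None or n_rules is None:
            raise ValueError("mode='sample' requires both seed and n_rules")
        for i, k in enumerate(orders):
            for rule in sample_rules(alphabets, k, n_rules, seed + i):
                yield rule, _rule_mask(rule, codes, valid, alphabets)
    else:
        raise ValueError(f"unknown enumeration mode {mode!r}")


def _rule_mask(rule: Rule, codes, valid, alphabets) -> np.ndarray:
    mask = None
    for sel in rule.selectors:
        level_idx = alphabets[sel.position].index(sel.level)
        col = codes[:, sel.position]
        m = (col != level_idx) & valid[:, sel.position] if sel.negated else col == level_idx
        mask = m if mask is None else mask & m
    return mask


class SSIRClassifier(ClassifierMixin, BaseEstimator):
    """Two-class ranking by superposed significant interaction rules.

    Fitting enumerates (or uniformly samples) all canonical conjunction
    rules of the requested orders over the categorical feature alphabets,
    keeps those whose hypergeometric tail p-value is at or below ``p_c``
    with a +/-1 vote, and scores samples by summing the votes of matching
    rules.  ``decision_function`` returns the vote totals;``predict``
    assigns the positive class (``classes_[1]``) to scores above
    ``decision_threshold``.

    Parameters
    ----------
    orders : sequence of int, default (1, 2)
        Rule orders to enumerate (number of constrained descriptors per
        rule); exhaustive enumeration is limited to orders <= 4.
    p_c : float, default 0.01
        Raw significance cutoff, 0 < p_c < 0.5.
    mode : {"exhaustive", "sample"}
        Systematic enumeration, or uniform Monte Carlo sampling of
        ``n_rules`` rules per order (requires ``random_state``).
    n_rules : int, optional
        Draws per order in sample mode.
    random_state : int, optional
        Seed for sample mode.
    positive_only : bool, default False
        Admit only +1 (enrichment) rules to the pool.
    missing_token : str, default "?"
        Token matching no selector.
    alphabets : sequence of sequences, optional
        Per-feature level sets; inferred from X (sorted observed tokens)
        when omitted.  Pass a library's alphabets to pin the rule space,
        e.g. across cross-validation folds.
    decision_threshold : int, default 0
        Net score above which ``predict`` returns the positive class.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels; ``classes_[1]`` is the interest class.
    model_ : VotingModel
        The selected rule pool with votes and training metadata.
    n_rules_evaluated_ : int
        Rules examined during fit (zero-coverage rules included).
    """

    def __init__(
        self,
        orders=(1, 2),
        p_c=0.01,
        mode="exhaustive",
        n_rules=None,
        random_state=None,
        positive_only=False,
        missing_token="?",
        alphabets=None,
        decision_threshold=0,
    ):
        self.orders = orders
        self.p_c = p_c
        self.mode = mode
        self.n_rules = n_rules
        self.random_state = random_state
        self.positive_only = positive_only
        self.missing_token = missing_token
        self.alphabets = alphabets
        self.decision_threshold = decision_threshold

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            descriptors = tuple(str(c) for c in X.columns)
        elif isinstance(X, Library):
            descriptors = tuple(X.descriptors)
        else:
            descriptors = None
        if descriptors is None or getattr(self, "_descriptor_names", None):
            descriptors = getattr(self, "_descriptor_names", None) or descriptors
        X = _token_matrix(X)
        if descriptors is None:
            descriptors = tuple(f"D{j + 1}" for j in range(X.shape[1]))
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError(f"{y.shape[0]} labels for {X.shape[0]} samples")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"SSIR needs exactly two classes, got {list(self.classes_)}"
            )
        if not 0.0 < self.p_c < 0.5:
            raise ValueError(f"p_c must lie in (0, 0.5), got {self.p_c}")
        orders = tuple(int(k) for k in self.orders)
        if not orders or any(k < 1 for k in orders):
            raise ValueError(f"orders must be positive integers, got {orders}")
        interest = y == self.classes_[1]
        a, b = len(interest), int(interest.sum())

        alphabets = (
            tuple(tuple(al) for al in self.alphabets)
            if self.alphabets is not None
            else _infer_alphabets(X, self.missing_token)
        )
        if len(alphabets) != X.shape[1]:
            raise ValueError(
                f"{len(alphabets)} alphabets for {X.shape[1]} descriptors"
            )
        codes = _codes(X, alphabets)
        table = tail_table(a, b)
        selected = []
        n_seen = 0
        for rule, mask in iter_rule_coverage(
            codes,
            alphabets,
            orders,
            mode=self.mode,
            seed=self.random_state,
            n_rules=self.n_rules,
        ):
            n_seen += 1
            c = int(mask.sum())
            if c == 0:  # matches nothing: upper tail is 1, never significant
                continue
            d = int(mask[interest].sum())
            p_plus = float(table.upper[c, d])
            p_minus = float(table.lower[c, d])
            if p_plus <= self.p_c:
                vote = 1
            elif p_minus <= self.p_c and not self.positive_only:
                vote = -1
            else:
                continue
            selected.append(
                RuleEvaluation(rule, UrnCounts(a, b, c, d), p_plus, p_minus, vote)
            )
        if not selected:
            warnings.warn(
                f"no rule reached p_c={self.p_c}; the model is empty and scores "
                "every sample 0",
                stacklevel=2,
            )
        self.model_ = VotingModel(
            tuple(selected),
            float(self.p_c),
            a,
            b,
            orders,
            self.mode,
            self.random_state,
            n_seen,
            descriptors,
            self.missing_token,
        )
        self.n_features_in_ = X.shape[1]
        self.n_rules_evaluated_ = n_seen
        self.rule_evaluations_ = self.model_.evaluations
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.vote_scores(X).astype(float)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[(scores > self.decision_threshold).astype(int)]


def evaluate_rule(rule: Rule, lib: Library) -> RuleEvaluation:
    """Evaluate one rule against a library: urn counts from its matched set
    and both tail p-values (no vote assigned; votes belong to a cutoff)."""
    if not 0 < lib.b < lib.a:
        raise ValueError(
            f"training library needs both classes, got b={lib.b} of a={lib.a}"
        )
    for sel in rule.selectors:
        if not 0 <= sel.position < lib.n_descriptors:
            raise IndexError(
                f"selector position {sel.position} out of range for "
                f"{lib.n_descriptors} descriptors"
            )
        if sel.level not in lib.alphabets[sel.position]:
            raise ValueError(
                f"level {sel.level!r} absent from the alphabet of descriptor "
                f"{lib.descriptors[sel.position]!r}"
            )
    mask = matches_matrix(rule, lib.samples.to_numpy(dtype=object), lib.missing_token)
    c = int(mask.sum())
    d = int(mask[lib.label_array()].sum())
    counts = UrnCounts(lib.a, lib.b, c, d)
    return RuleEvaluation(
        rule,
        counts,
        float(upper_tail(lib.a, lib.b, c, d)),
        float(lower_tail(lib.a, lib.b, c, d)),
        None,
    )


def train(
    lib: Library,
    orders: Sequence[int],
    p_c: float,
    *,
    mode: str = "exhaustive",
    seed: int | None = None,
    n_rules: int | None = None,
    positive_only: bool = False,
) -> VotingModel:
    """Fit the SSIR consensus model on a library (thin wrapper over
    :class:`SSIRClassifier` keyed to the library's alphabets)."""
    est = SSIRClassifier(
        orders=tuple(orders),
        p_c=p_c,
        mode=mode,
        n_rules=n_rules,
        random_state=seed,
        positive_only=positive_only,
        missing_token=lib.missing_token,
        alphabets=lib.alphabets,
    )
    est._descriptor_names = tuple(lib.descriptors)
    est.fit(lib.samples, lib.label_array())
    return est.model_


def score(model: VotingModel, samples) -> RankingResult:
    """Vote totals and ranking for a Library, DataFrame or token array
    sharing the model's descriptor schema."""
    if isinstance(samples, Library):
        ids = samples.sample_ids
    elif isinstance(samples, pd.DataFrame):
        ids = list(samples.index)
    else:
        ids = list(range(np.asarray(samples, dtype=object).shape[0]))
    return _ranking(ids, model.vote_scores(samples))


def descriptor_votes(model: VotingModel) -> pd.DataFrame:
    """Per-descriptor appearance tallies in +1 and -1 rules, sorted by total
    descending (ties in descriptor order) — SSIR's variable-selection view."""
    plus = np.zeros(len(model.descriptors), dtype=np.int64)
    minus = np.zeros(len(model.descriptors), dtype=np.int64)
    for ev in model.evaluations:
        target = plus if ev.vote == 1 else minus
        for p in ev.rule.positions:
            target[p] += 1
    out = pd.DataFrame(
        {
            "descriptor": list(model.descriptors),
            "plus_rules": plus,
            "minus_rules": minus,
            "total": plus + minus,
        }
    )
    out = out[out["total"] > 0]
    out = out.sort_values("total", ascending=False, kind="stable").reset_index(drop=True)
    return out
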