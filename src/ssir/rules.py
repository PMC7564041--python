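"""Conjunction rules over categorical fingerprints.

A rule of order k constrains k distinct descriptor positions, each with a
selector that either requires a level (``2:L``) or excludes one (``2:!L``,
the bar notation of set algebra); all remaining positions are wildcards.  A
sample matches the rule when every selector is satisfied; a missing cell
satisfies no selector, positive or negated.

Canonical form removes the one systematic redundancy of the representation:
on a two-level position, excluding one level is the same selector as
requiring the other, so negated selectors on binary positions are rewritten
positively.  With that convention the number of canonical selectors on a
position with m levels is 2 if m <= 2 else 2m, and the order-k rule space
over all-binary data has exactly C(n, k) * 2^k members — e.g. 26,564,760
order-2 rules over 3645 binary descriptors.

Enumeration nests three combinatorial layers — position combinations, level
variations, negation flags — in a fixed lexicographic order so streams are
reproducible.  ``sample_rules`` draws uniformly from the canonical space by
integer unranking, so Monte Carlo exploration is exact even for spaces too
large to materialize.
"""

from __future__ import annotations

import itertools
import random
from collections.abc import Iterator, Sequence
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Selector",
    "Rule",
    "canonicalize",
    "matches",
    "matches_matrix",
    "selector_options",
    "enumerate_rules",
    "count_rules",
    "sample_rules",
    "rule_to_text",
    "rule_from_text",
]


@dataclass(frozen=True, order=True)
class Selector:
    """One per-position constraint: require ``level`` at ``position``
    (``negated=False``) or exclude it (``negated=True``)."""

    position: int
    level: str
    negated: bool = False

    def __str__(self) -> str:
        bar = "!" if self.negated else ""
        return f"{self.position + 1}:{bar}{self.level}"


@dataclass(frozen=True)
class Rule:
    """A conjunction of selectors on pairwise-distinct positions.

    Selectors are stored sorted by position.  Order 0 (no selectors, the
    all-wildcard rule matching everything) is disallowed.
    """

    selectors: tuple[Selector, ...]

    def __post_init__(self) -> None:
        sels = tuple(sorted(self.selectors, key=lambda s: s.position))
        if len(sels) == 0:
            raise ValueError("a rule needs at least one selector (order >= 1)")
        positions = [s.position for s in sels]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate positions in rule: {positions}")
        object.__setattr__(self, "selectors", sels)

    @property
    def order(self) -> int:
        return len(self.selectors)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.selectors)

    def __str__(self) -> str:
        return "&".join(str(s) for s in self.selectors)


def canonicalize(rule: Rule, alphabets: Sequence[Sequence[str]]) -> Rule:
    """Rewrite negated selectors on two-level positions as the positive
    selector of the other level; idempotent."""
    new = []
    for sel in rule.selectors:
        alphabet = alphabets[sel.position]
        if sel.negated and len(alphabet) == 2 and sel.level in alphabet:
            other = alphabet[1] if alphabet[0] == sel.level else alphabet[0]
            sel = Selector(sel.position, other, False)
        new.append(sel)
    return Rule(tuple(new))


def _selector_ok(sel: Selector, token: str, missing_token: str) -> bool:
    if token == missing_token:
        return False
    return (token != sel.level) if sel.negated else (token == sel.level)


def matches(rule: Rule, fingerprint: Sequence[str], missing_token: str = "?") -> bool:
    """True iff every selector of ``rule`` is satisfied by the sample."""
    n = len(fingerprint)
    for sel in rule.selectors:
        if not 0 <= sel.position < n:
            raise IndexError(f"selector position {sel.position} out of range for {n} descriptors")
        if not _selector_ok(sel, fingerprint[sel.position], missing_token):
            return False
    return True


def matches_matrix(rule: Rule, X: np.ndarray, missing_token: str = "?") -> np.ndarray:
    """Vectorized :func:`matches` over a (samples x descriptors) token array."""
    X = np.asarray(X, dtype=object)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x descriptors array")
    mask = np.ones(X.shape[0], dtype=bool)
    for sel in rule.selectors:
        if not 0 <= sel.position < X.shape[1]:
            raise IndexError(
                f"selector position {sel.position} out of range for {X.shape[1]} descriptors"
            )
        col = X[:, sel.position]
        if sel.negated:
            mask &= (col != sel.level) & (col != missing_token)
        else:
            mask &= col == sel.level
    return mask


def selector_options(alphabet: Sequence[str]) -> list[tuple[str, bool]]:
    """Canonical (level, negated) selector choices for one position, in
    enumeration order: positives in alphabet order, then negations (omitted
    on two-level positions where they are redundant)."""
    alphabet = list(alphabet)
    options = [(level, False) for level in alphabet]
    if len(alphabet) != 2:
        options += [(level, True) for level in alphabet]
    return options


def enumerate_rules(alphabets: Sequence[Sequence[str]], order: int) -> Iterator[Rule]:
    """Yield every distinct canonical rule of the given order exactly once,
    in lexicographic (positions, then selector) order."""
    n = len(alphabets)
    _check_order(order, n)
    options = [selector_options(al) for al in alphabets]
    for combo in itertools.combinations(range(n), order):
        for choice in itertools.product(*(options[p] for p in combo)):
            yield Rule(
                tuple(
                    Selector(p, level, negated)
                    for p, (level, negated) in zip(combo, choice)
                )
            )


def _check_order(order: int, n: int) -> None:
    if not 1 <= order <= n:
        raise ValueError(f"rule order must satisfy 1 <= k <= {n}, got {order}")


def _position_weights(alphabets: Sequence[Sequence[str]]) -> list[int]:
    return [len(sel_opts) for sel_opts in map(selector_options, alphabets)]


def count_rules(
    alphabets: Sequence[Sequence[str]], order: int, *, method: str = "closed-form"
) -> int:
    """Number of distinct canonical rules of the given order.

    ``closed-form`` evaluates the generating polynomial
    prod_i (1 + w_i x) at the x^k coefficient, where w_i is the canonical
    selector count of position i (exact integer arithmetic).  ``enumerate``
    streams the full rule space and counts, as an independent cross-check.
    """
    n = len(alphabets)
    _check_order(order, n)
    if method == "enumerate":
        return _count_by_streaming(alphabets, order)
    if method != "closed-form":
        raise ValueError(f"unknown method {method!r}")
    weights = _position_weights(alphabets)
    coeffs = [1] + [0] * order  # coefficients of x^0..x^k
    for w in weights:
        for j in range(min(order, len(coeffs) - 1), 0, -1):
            coeffs[j] += coeffs[j - 1] * w
    return coeffs[order]


def _count_by_streaming(alphabets: Sequence[Sequence[str]], order: int) -> int:
    # Streams the same nested combinatorial structure as enumerate_rules but
    # counts selector tuples without building Rule objects.
    options = [selector_options(al) for al in alphabets]
    total = 0
    for combo in itertools.combinations(range(len(alphabets)), order):
        total += sum(1 for _ in itertools.product(*(options[p] for p in combo)))
    return total


def sample_rules(
    alphabets: Sequence[Sequence[str]],
    order: int,
    n_rules: int,
    seed: int,
) -> list[Rule]:
    """Draw ``n_rules`` canonical rules uniformly with replacement.

    Each draw unranks a uniform integer in [0, count_rules) via a
    suffix-count table over position combinations, so the sampler is exactly
    uniform and reproducible for a fixed seed even on spaces far too large
    to materialize.
    """
    n = len(alphabets)
    _check_order(order, n)
    if n_rules < 1:
        raise ValueError(f"n_rules must be >= 1, got {n_rules}")
    options = [selector_options(al) for al in alphabets]
    weights = [len(o) for o in options]
    # S[j][i] = number of weighted ways to pick j positions from i..n-1
    S = [[0] * (n + 1) for _ in range(order + 1)]
    S[0] = [1] * (n + 1)
    for j in range(1, order + 1):
        for i in range(n - 1, -1, -1):
            S[j][i] = S[j][i + 1] + weights[i] * S[j - 1][i + 1]
    total = S[order][0]
    if total == 0:
        raise ValueError("empty rule space")
    rng = random.Random(seed)
    out = []
    for _ in range(n_rules):
        idx = rng.randrange(total)
        sels = []
        i, j = 0, order
        while j > 0:
            skip = S[j][i + 1]  # ranks whose first chosen position is > i
            if idx < skip:
                i += 1
                continue
            idx -= skip
            block = S[j - 1][i + 1]  # ranks per selector choice at position i
            choice, idx = divmod(idx, block)
            level, negated = options[i][choice]
            sels.append(Selector(i, level, negated))
            i += 1
            j -= 1
        out.append(Rule(tuple(sels)))
    return out


def rule_to_text(rule: Rule) -> str:
    """Serialize as ``pos:LEVEL`` / ``pos:!LEVEL`` joined by ``&`` with
    1-based positions, e.g. ``2:L&4:H``."""
    return str(rule)


def rule_from_text(text: str) -> Rule:
    """Parse the :func:`rule_to_text` format (bit-exact round trip)."""
    sels = []
    for part in text.strip().split("&"):
        pos_s, _, level = part.partition(":")
        if not pos_s or not level:
            raise ValueError(f"malformed selector {part!r} in rule {text!r}")
        negated = level.startswith("!")
        if negated:
            level = level[1:]
        sels.append(Selector(int(pos_s) - 1, level, negated))
    return Rule(tuple(sels))
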