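"""Seeded generator of fingerprint libraries with planted rule structure.

The generator emulates the shape of categorical expression-call matrices
(samples x descriptors, a small symbolic alphabet per descriptor, a binary
class label) and plants known conjunction rules into the interest class so
every pipeline stage — enumeration, significance, voting, cross-validation,
Y-scrambling — can be exercised against a known ground truth.

Mechanism: labels are assigned to the requested balance; every cell is
drawn i.i.d. from the background level distribution; then, for each
interest-class sample and each planted rule independently, the rule's
selector pattern is imposed with probability ``penetrance``.  Non-interest
samples receive the pattern only by background chance, which makes the
planted enrichment follow exactly the urn model the significance test
assumes.

Defaults model a small two-class cohort: 40 samples, 30 binary A/P
descriptors, balanced classes, uniform background, one planted order-2 rule
at full penetrance.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import Library, write_library
from .rules import Rule, Selector, rule_to_text

__all__ = ["PlantedRule", "PlantSpec", "generate", "write_synthetic"]

DEFAULT_ALPHABET = ("A", "P")


@dataclass(frozen=True)
class PlantedRule:
    """A rule imposed on interest-class samples with a given penetrance."""

    selectors: tuple[Selector, ...]
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance must lie in [0, 1], got {self.penetrance}")
        Rule(self.selectors)  # validates non-empty, distinct positions

    @property
    def rule(self) -> Rule:
        return Rule(self.selectors)


def default_planted_rule() -> tuple[PlantedRule, ...]:
    return (PlantedRule((Selector(0, "P"), Selector(1, "P")), penetrance=1.0),)


@dataclass
class PlantSpec:
    """Generation recipe: cohort size, descriptor alphabets, planted rules,
    background level distribution, label balance and seed."""

    n_samples: int = 40
    n_descriptors: int = 30
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    planted_rules: tuple[PlantedRule, ...] = field(default_factory=default_planted_rule)
    background: tuple[float, ...] | None = None  # uniform when None
    label_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_descriptors < 1:
            raise ValueError("need >= 2 samples and >= 1 descriptor")
        if not 0.0 < self.label_balance < 1.0:
            raise ValueError(f"label balance must lie in (0, 1), got {self.label_balance}")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if len(bg) != len(self.alphabet) or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be a distribution over the alphabet")
        positions: dict[int, Selector] = {}
        for planted in self.planted_rules:
            for sel in planted.selectors:
                if not 0 <= sel.position < self.n_descriptors:
                    raise ValueError(
                        f"planted position {sel.position} out of range for "
                        f"{self.n_descriptors} descriptors"
                    )
                if sel.level not in self.alphabet and not sel.negated:
                    raise ValueError(
                        f"planted level {sel.level!r} not in alphabet {self.alphabet}"
                    )
                prev = positions.get(sel.position)
                if prev is not None and prev != sel:
                    raise ValueError(
                        f"contradictory planted selectors at position {sel.position}: "
                        f"{prev} vs {sel}"
                    )
                positions[sel.position] = sel


def generate(spec: PlantSpec) -> tuple[Library, dict]:
    """Generate a library and its ground-truth manifest; deterministic for a
    fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_descriptors
    alphabet = list(spec.alphabet)
    background = (
        np.full(len(alphabet), 1.0 / len(alphabet))
        if spec.background is None
        else np.asarray(spec.background, dtype=float)
    )

    n_interest = int(round(n * spec.label_balance))
    n_interest = min(max(n_interest, 1), n - 1)
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:n_interest]] = True

    matrix = rng.choice(alphabet, size=(n, m), p=background).astype(object)

    for i in np.flatnonzero(labels):
        for planted in spec.planted_rules:
            if rng.random() >= planted.penetrance:
                continue
            for sel in planted.selectors:
                if sel.negated:
                    others = [tok for tok in alphabet if tok != sel.level]
                    matrix[i, sel.position] = others[rng.integers(len(others))]
                else:
                    matrix[i, sel.position] = sel.level

    width = len(str(n))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    descriptors = [f"G{j + 1:0{len(str(m))}d}" for j in range(m)]
    samples = pd.DataFrame(matrix, index=sample_ids, columns=descriptors)
    lib = Library(samples, pd.Series(labels, index=sample_ids), alphabets=tuple(tuple(alphabet) for _ in range(m)))
    manifest = {
        "seed": spec.seed,
        "n_samples": n,
        "n_descriptors": m,
        "alphabet": alphabet,
        "background": background.tolist(),
        "label_balance": spec.label_balance,
        "n_interest": int(labels.sum()),
        "interest_samples": [sid for sid, flag in zip(sample_ids, labels) if flag],
        "planted_rules": [
            {"rule": rule_to_text(p.rule), "penetrance": p.penetrance}
            for p in spec.planted_rules
        ],
    }
    return lib, manifest


def write_synthetic(spec: PlantSpec, out_dir) -> tuple[Library, dict]:
    """Generate and write ``library.tsv`` plus ``manifest.json``; byte
    identical for a fixed seed."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib, manifest = generate(spec)
    write_library(lib, out / "library.tsv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return lib, manifest
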