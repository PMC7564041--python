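"""Shared fixtures: the 9x5 three-level toy library and small planted
synthetic libraries."""

import numpy as np
import pandas as pd
import pytest

from ssir.library import Library
from ssir.synthetic import PlantSpec, PlantedRule, generate
from ssir.rules import Selector

# Synthetic stand-in for the classic 9-individual, 5-descriptor, 3-level
# (L/M/H) demonstration table: constructed so that 5 of 9 individuals are of
# interest and the rule "D2:L & D4:H" selects exactly I2, I3, I6 and I9, of
# which I2, I3 and I9 are of interest (c=4, d=3 in an a=9, b=5 urn).
TOY_ROWS = [
    ("I1", "L", "M", "L", "L", "M", True),
    ("I2", "M", "L", "H", "H", "L", True),
    ("I3", "H", "L", "M", "H", "H", True),
    ("I4", "M", "M", "L", "M", "L", False),
    ("I5", "L", "H", "M", "L", "H", True),
    ("I6", "H", "L", "L", "H", "M", False),
    ("I7", "M", "M", "H", "L", "L", False),
    ("I8", "L", "H", "M", "M", "H", False),
    ("I9", "H", "L", "L", "H", "L", True),
]


def make_toy_library() -> Library:
    samples = pd.DataFrame(
        [list(r[1:6]) for r in TOY_ROWS],
        index=[r[0] for r in TOY_ROWS],
        columns=[f"D{i}" for i in range(1, 6)],
    )
    labels = pd.Series([r[6] for r in TOY_ROWS], index=samples.index)
    return Library(samples, labels)


@pytest.fixture
def toy_library() -> Library:
    return make_toy_library()


@pytest.fixture
def toy_tsv(tmp_path):
    path = tmp_path / "toy.tsv"
    lines = ["id\tD1\tD2\tD3\tD4\tD5\tlabel"]
    for r in TOY_ROWS:
        lines.append("\t".join([r[0], *r[1:6], "1" if r[6] else "0"]))
    path.write_text("\n".join(lines) + "\n")
    return path


def noiseless_planted_spec(seed=0, n_samples=40, n_descriptors=30):
    """Planted order-2 rule at full penetrance on a background that never
    produces the pattern by chance (all-'A' background on an A/P alphabet):
    the rule separates the classes perfectly and is recoverable in every
    leave-one-out fold."""
    return PlantSpec(
        n_samples=n_samples,
        n_descriptors=n_descriptors,
        alphabet=("A", "P"),
        planted_rules=(
            PlantedRule((Selector(0, "P"), Selector(1, "P")), penetrance=1.0),
        ),
        background=(1.0, 0.0),
        seed=seed,
    )


def noisy_planted_spec(seed=0, penetrance=1.0, n_samples=40, n_descriptors=30):
    """Planted order-2 rule over a uniform binary background."""
    return PlantSpec(
        n_samples=n_samples,
        n_descriptors=n_descriptors,
        alphabet=("A", "P"),
        planted_rules=(
            PlantedRule((Selector(0, "P"), Selector(1, "P")), penetrance=penetrance),
        ),
        seed=seed,
    )


def random_library(seed, n_samples=12, n_descriptors=5, alphabet=("A", "B", "C")):
    """Pure-noise library (no planted structure)."""
    lib, _ = generate(
        PlantSpec(
            n_samples=n_samples,
            n_descriptors=n_descriptors,
            alphabet=alphabet,
            planted_rules=(),
            seed=seed,
        )
    )
    return lib


@pytest.fixture
def planted_library():
    lib, manifest = generate(noiseless_planted_spec(seed=3))
    return lib, manifest
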