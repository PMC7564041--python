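"""Two-class categorical fingerprint libraries: data model, I/O, preprocessing.

A :class:`Library` is a table of samples x descriptors where every cell is a
symbolic level token (e.g. microarray A/M/P detection calls, or L/M/H
expression levels) plus a binary interest label per sample.  The alphabets —
the set of levels each descriptor may take — are part of the library schema:
they are inferred once from the observed tokens at construction and preserved
by sample subsetting, so a cross-validation fold enumerates exactly the same
rule space as the full library.

Preprocessing mirrors the standard pipeline for categorical call matrices:
dropping constant descriptors, merging levels (e.g. marginal M calls into A
or P) and preselecting the k most level-balanced descriptors by Shannon
entropy.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Library",
    "read_library",
    "write_library",
    "drop_constant_descriptors",
    "merge_levels",
    "select_balanced_descriptors",
    "level_entropy",
    "descriptor_manifest",
]

MISSING_TOKEN = "?"


def _infer_alphabets(samples: pd.DataFrame, missing_token: str) -> tuple[tuple[str, ...], ...]:
    alphabets = []
    for col in samples.columns:
        tokens = sorted(set(samples[col]) - {missing_token})
        alphabets.append(tuple(tokens))
    return tuple(alphabets)


@dataclass
class Library:
    """Samples x descriptors level matrix with binary interest labels.

    Parameters
    ----------
    samples : pandas.DataFrame
        String tokens; index = sample ids, columns = descriptor names.
    labels : pandas.Series
        Boolean, aligned with ``samples.index``; True marks the interest
        class.
    missing_token : str
        Token standing for a missing call; matches no selector.
    alphabets : tuple of tuple of str, optional
        Per-descriptor level sets.  Inferred from the observed tokens
        (sorted) when omitted; pass explicitly to pin a schema.
    """

    samples: pd.DataFrame
    labels: pd.Series
    missing_token: str = MISSING_TOKEN
    alphabets: tuple[tuple[str, ...], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples.shape[0] == 0 or self.samples.shape[1] == 0:
            raise ValueError("empty matrix: a library needs >=1 sample and >=1 descriptor")
        if self.samples.index.has_duplicates:
            dupes = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        self.labels = self.labels.reindex(self.samples.index)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValueError(f"label missing for samples: {missing}")
        self.labels = self.labels.astype(bool)
        if self.alphabets is None:
            self.alphabets = _infer_alphabets(self.samples, self.missing_token)
        else:
            self.alphabets = tuple(tuple(al) for al in self.alphabets)
            if len(self.alphabets) != self.samples.shape[1]:
                raise ValueError(
                    f"{len(self.alphabets)} alphabets for {self.samples.shape[1]} descriptors"
                )
            for name, alphabet, observed in zip(
                self.samples.columns, self.alphabets, _infer_alphabets(self.samples, self.missing_token)
            ):
                stray = set(observed) - set(alphabet)
                if stray:
                    raise ValueError(
                        f"descriptor {name!r}: tokens {sorted(stray)} absent from "
                        f"declared alphabet {list(alphabet)}"
                    )

    # -- basic views ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def descriptors(self) -> list[str]:
        return list(self.samples.columns)

    @property
    def a(self) -> int:
        """Total number of samples."""
        return self.samples.shape[0]

    @property
    def b(self) -> int:
        """Number of interest-class samples."""
        return int(self.labels.sum())

    @property
    def n_descriptors(self) -> int:
        return self.samples.shape[1]

    def codes(self) -> np.ndarray:
        """Integer-coded matrix: cell -> index into its descriptor's alphabet,
        -1 for the missing token or any token outside the alphabet."""
        out = np.full(self.samples.shape, -1, dtype=np.int32)
        values = self.samples.to_numpy(dtype=object)
        for j, alphabet in enumerate(self.alphabets):
            lookup = {tok: i for i, tok in enumerate(alphabet)}
            out[:, j] = [lookup.get(v, -1) for v in values[:, j]]
        return out

    def label_array(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=bool)

    def subset(self, keep) -> "Library":
        """Row subset (boolean mask or positional indices); the descriptor
        schema, including alphabets, is preserved."""
        keep = np.asarray(keep)
        samples = self.samples.iloc[keep] if keep.dtype != bool else self.samples.loc[keep]
        labels = self.labels.loc[samples.index]
        return Library(samples.copy(), labels.copy(), self.missing_token, self.alphabets)


def read_library(
    path,
    *,
    orient: str = "samples-in-rows",
    label_col: str = "label",
    positive_label: str = "1",
    delimiter: str | None = None,
    missing_token: str = MISSING_TOKEN,
    alphabets: Mapping[str, Sequence[str]] | None = None,
) -> Library:
    """Read a delimited text library.

    The first column holds sample ids (descriptor names under
    ``orient="genes-in-rows"``, where the table is transposed first).  The
    label column (default ``label``) is removed from the matrix; a cell equal
    to ``positive_label`` marks the interest class.  Delimiter is
    auto-detected (tab or comma) unless given.  ``alphabets`` optionally
    declares allowed tokens per descriptor; stray tokens then raise.
    """
    if orient not in ("samples-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown orientation {orient!r}")
    if delimiter is None:
        table = pd.read_csv(path, sep=None, engine="python", dtype=str, index_col=0)
    else:
        table = pd.read_csv(path, sep=delimiter, dtype=str, index_col=0)
    if orient == "genes-in-rows":
        table = table.T
    if label_col not in table.columns:
        raise ValueError(f"label column {label_col!r} not found in {list(table.columns)[:8]}...")
    raw_labels = table[label_col]
    if raw_labels.isna().any():
        missing = table.index[raw_labels.isna()].tolist()
        raise ValueError(f"label missing for samples: {missing}")
    labels = raw_labels == positive_label
    samples = table.drop(columns=[label_col]).fillna(missing_token)
    declared = None
    if alphabets is not None:
        declared = tuple(tuple(alphabets[name]) for name in samples.columns)
    return Library(samples, labels, missing_token, declared)


def write_library(
    lib: Library,
    path,
    *,
    orient: str = "samples-in-rows",
    delimiter: str = "\t",
    label_col: str = "label",
) -> None:
    """Write the library back as delimited text (labels as 1/0).

    Inverse of :func:`read_library` with ``positive_label="1"``.
    """
    table = lib.samples.copy()
    table[label_col] = np.where(lib.label_array(), "1", "0")
    if orient == "genes-in-rows":
        table = table.T
    table.to_csv(path, sep=delimiter)


def drop_constant_descriptors(lib: Library) -> Library:
    """Remove descriptors showing fewer than two distinct observed levels."""
    keep = [j for j, alphabet in enumerate(_infer_alphabets(lib.samples, lib.missing_token)) if len(alphabet) >= 2]
    samples = lib.samples.iloc[:, keep].copy()
    if samples.shape[1] == 0:
        raise ValueError("all descriptors are constant; nothing left to mine")
    alphabets = tuple(lib.alphabets[j] for j in keep)
    return Library(samples, lib.labels.copy(), lib.missing_token, alphabets)


def merge_levels(lib: Library, mapping: Mapping) -> Library:
    """Recode level tokens, e.g. ``{"M": "A"}`` to fold marginal calls into
    absent.

    ``mapping`` is either a global token->token map applied to every
    descriptor, or a descriptor-name -> {token: token} map.  Alphabets are
    recomputed from the recoded matrix; descriptors that become constant are
    kept (chain :func:`drop_constant_descriptors` to remove them).
    """
    samples = lib.samples.copy()
    per_descriptor = mapping and all(isinstance(v, Mapping) for v in mapping.values())
    for col in samples.columns:
        m = mapping.get(col, {}) if per_descriptor else mapping
        if m:
            samples[col] = samples[col].map(lambda tok: m.get(tok, tok))
    merged = Library(samples, lib.labels.copy(), lib.missing_token, None)
    for name, alphabet in zip(merged.descriptors, merged.alphabets):
        if len(alphabet) == 0:
            raise ValueError(f"merge left descriptor {name!r} with an empty alphabet")
    return merged


def level_entropy(column: pd.Series, missing_token: str = MISSING_TOKEN) -> float:
    """Shannon entropy (bits) of the level frequencies in one descriptor,
    missing cells excluded."""
    counts = column[column != missing_token].value_counts()
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(-(p * np.log2(p)).sum())


def select_balanced_descriptors(lib: Library, k: int) -> Library:
    """Keep the k descriptors with the highest level entropy (the most
    balanced level counts), ties broken by input order."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > lib.n_descriptors:
        raise ValueError(f"k={k} exceeds descriptor count {lib.n_descriptors}")
    entropies = np.array([level_entropy(lib.samples[c], lib.missing_token) for c in lib.samples.columns])
    order = np.argsort(-entropies, kind="stable")[:k]
    keep = np.sort(order)  # preserve input order among the selected
    samples = lib.samples.iloc[:, keep].copy()
    alphabets = tuple(lib.alphabets[j] for j in keep)
    return Library(samples, lib.labels.copy(), lib.missing_token, alphabets)


def descriptor_manifest(lib: Library) -> pd.DataFrame:
    """Per-descriptor summary: name, alphabet, level entropy (bits)."""
    return pd.DataFrame(
        {
            "descriptor": lib.descriptors,
            "alphabet": [",".join(al) for al in lib.alphabets],
            "entropy_bits": [level_entropy(lib.samples[c], lib.missing_token) for c in lib.samples.columns],
        }
    )
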