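"""Finding catalog and ground-truth label generation.

A chest-radiograph exam carries zero or more of eight pathological
findings.  Each finding has a clinical urgency rank (1 = most urgent)
assigned by expert radiologists and an institutional prevalence.  An exam
with no finding is "normal" and sits below every finding in urgency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FindingCatalog",
    "default_catalog",
    "sample_labels",
    "urgency_rank",
    "urgency_rank_vector",
    "DEFAULT_FINDING_COUNTS",
    "DEFAULT_SAMPLE_SIZE",
]

# Institutional prevalence survey: positives among 600 annotated exams,
# listed in decreasing clinical urgency.
DEFAULT_FINDING_COUNTS: tuple[tuple[str, int], ...] = (
    ("pneumothorax", 23),
    ("congestion", 124),
    ("pleural_effusion", 236),
    ("infiltrate", 100),
    ("atelectasis", 124),
    ("cardiomegaly", 117),
    ("mass", 38),
    ("foreign_object", 298),
)
DEFAULT_SAMPLE_SIZE = 600


@dataclass(frozen=True)
class FindingCatalog:
    """Ordered findings with urgency ranks 1..K and per-finding prevalence.

    The list order *is* the urgency order: ``names[i]`` has rank ``i + 1``.
    Prevalences are kept as exact fractions (``positives / total``) where
    they originate from a count table, to avoid compounding rounding.
    An all-negative exam falls into the implicit "normal" tier with rank
    ``K + 1``; normal is not a catalog entry.
    """

    names: tuple[str, ...]
    prevalences: tuple[Fraction, ...]

    _prev_array: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.prevalences):
            raise ValueError("names and prevalences must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("finding names must be unique")
        for p in self.prevalences:
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence {p} outside [0, 1]")
        object.__setattr__(
            self, "_prev_array", np.array([float(p) for p in self.prevalences])
        )

    @property
    def n_findings(self) -> int:
        return len(self.names)

    @property
    def ranks(self) -> tuple[int, ...]:
        """Urgency rank of each finding, 1 = most urgent."""
        return tuple(range(1, len(self.names) + 1))

    @property
    def normal_rank(self) -> int:
        """Rank assigned to exams with no positive finding (lowest tier)."""
        return len(self.names) + 1

    @property
    def class_names(self) -> tuple[str, ...]:
        """Catalog findings plus the trailing "normal" class."""
        return self.names + ("normal",)

    def prevalence_array(self) -> np.ndarray:
        return self._prev_array

    def rank_of(self, name: str) -> int:
        return self.names.index(name) + 1

    def expected_normal_fraction(self) -> float:
        """P(no finding) under independent per-finding sampling."""
        return float(np.prod(1.0 - self._prev_array))

    @classmethod
    def from_counts(
        cls, counts: Sequence[tuple[str, int]], total: int
    ) -> "FindingCatalog":
        names = tuple(name for name, _ in counts)
        prevs = tuple(Fraction(k, total) for _, k in counts)
        return cls(names, prevs)

    @classmethod
    def from_csv(cls, path) -> "FindingCatalog":
        """Read a catalog from CSV with columns name, rank, positives, total.

        Rows may appear in any order; they are sorted by rank, which must
        be 1..K consecutive.
        """
        df = pd.read_csv(path)
        required = {"name", "rank", "positives", "total"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalog CSV missing columns: {sorted(missing)}")
        df = df.sort_values("rank")
        if list(df["rank"]) != list(range(1, len(df) + 1)):
            raise ValueError("catalog ranks must be consecutive 1..K")
        counts = [(str(r["name"]), int(r["positives"])) for _, r in df.iterrows()]
        totals = df["total"].unique()
        if len(totals) != 1:
            # heterogeneous denominators are allowed; fall back to per-row
            prevs = tuple(
                Fraction(int(r["positives"]), int(r["total"]))
                for _, r in df.iterrows()
            )
            return cls(tuple(n for n, _ in counts), prevs)
        return cls.from_counts(counts, int(totals[0]))

    def to_csv(self, path) -> None:
        rows = []
        for name, rank, p in zip(self.names, self.ranks, self.prevalences):
            rows.append(
                {
                    "name": name,
                    "rank": rank,
                    "positives": p.numerator,
                    "total": p.denominator,
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


def default_catalog() -> FindingCatalog:
    """The embedded institutional catalog (eight findings, counts over 600)."""
    return FindingCatalog.from_counts(DEFAULT_FINDING_COUNTS, DEFAULT_SAMPLE_SIZE)


def sample_labels(
    catalog: FindingCatalog, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw ground-truth label vectors.

    Findings are sampled independently Bernoulli(prevalence); co-occurrence
    structure is deliberately not modelled.  Returns a boolean vector of
    length K, or a (size, K) matrix when ``size`` is given.
    """
    p = catalog.prevalence_array()
    if size is None:
        return rng.random(p.shape[0]) < p
    return rng.random((size, p.shape[0])) < p


def urgency_rank(labels: np.ndarray, catalog: FindingCatalog) -> int:
    """Priority rank of one exam: the minimum rank among positive findings.

    All-negative exams return ``catalog.normal_rank`` (K + 1).  Only
    presence matters; neither severity nor finding combinations enter.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != (catalog.n_findings,):
        raise ValueError(
            f"label vector length {labels.shape} does not match "
            f"catalog with {catalog.n_findings} findings"
        )
    positive = np.flatnonzero(labels)
    if positive.size == 0:
        return catalog.normal_rank
    return int(positive[0]) + 1


def urgency_rank_vector(labels: np.ndarray, catalog: FindingCatalog) -> np.ndarray:
    """Vectorized :func:`urgency_rank` over a (n, K) boolean label matrix."""
    labels = np.asarray(labels, dtype=bool)
    if labels.ndim != 2 or labels.shape[1] != catalog.n_findings:
        raise ValueError("expected a (n, K) label matrix aligned with the catalog")
    ranks = np.arange(1, catalog.n_findings + 1)
    masked = np.where(labels, ranks, catalog.normal_rank)
    return masked.min(axis=1)
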