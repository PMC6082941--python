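"""Core domain containers for diallelic insertion/deletion (InDel) panels.

Genotypes are stored as insertion-allele dosage: 2 = II (insertion
homozygote), 1 = ID (heterozygote), 0 = DD (deletion homozygote),
-1 = missing.  All downstream statistics are computed from these codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

# genotype call codes
MISSING = -1
DD = 0
ID = 1
II = 2

CODE_TO_STR = {II: "II", ID: "ID", DD: "DD", MISSING: "MISSING"}
STR_TO_CODE = {v: k for k, v in CODE_TO_STR.items()}


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class DegenerateInputError(ValueError):
    """Raised when a statistic is requested for data that cannot support it."""


class LocusCounts(NamedTuple):
    """Genotype counts at a single diallelic locus (non-missing calls only)."""

    n_II: int
    n_ID: int
    n_DD: int

    @property
    def n(self) -> int:
        """Number of individuals with a non-missing call."""
        return self.n_II + self.n_ID + self.n_DD

    @property
    def n_insertion(self) -> int:
        """Number of insertion-allele copies."""
        return 2 * self.n_II + self.n_ID

    def validate(self) -> "LocusCounts":
        if min(self.n_II, self.n_ID, self.n_DD) < 0:
            raise ValidationError(f"negative genotype count: {self}")
        return self


@dataclass
class GenotypeMatrix:
    """Individuals x loci diallelic calls with population labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``calls``.
    population_labels
        Population name per sample (parallel to ``sample_ids``).
    locus_ids
        Unique locus identifiers, one per column of ``calls``.
    calls
        ``(n_samples, n_loci)`` int8 array of insertion dosages
        (2/1/0, -1 for missing).
    rs_numbers
        Optional rs-number annotation per locus; keys are locus ids.
    """

    sample_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    rs_numbers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.population_labels = list(self.population_labels)
        self.locus_ids = list(self.locus_ids)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(self.population_labels) != len(self.sample_ids):
            raise ValidationError("one population label required per sample")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("duplicate locus ids")
        bad = ~np.isin(self.calls, (II, ID, DD, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call code {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_ids.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus id {locus!r}") from None

    def subset_population(self, population: str) -> "GenotypeMatrix":
        mask = [p == population for p in self.population_labels]
        if not any(mask):
            raise KeyError(f"unknown population {population!r}")
        idx = np.flatnonzero(mask)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            [self.population_labels[i] for i in idx],
            list(self.locus_ids),
            self.calls[idx],
            dict(self.rs_numbers),
        )

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.locus_ids != other.locus_ids:
            raise ValidationError("locus sets differ; cannot concatenate")
        return GenotypeMatrix(
            self.sample_ids + other.sample_ids,
            self.population_labels + other.population_labels,
            list(self.locus_ids),
            np.vstack([self.calls, other.calls]),
            {**self.rs_numbers, **other.rs_numbers},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.population_labels == other.population_labels
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class FreqTable:
    """Population x locus insertion-allele frequencies.

    The deletion frequency is always ``1 - insertion_freq`` by construction;
    only the insertion frequency is stored.
    """

    freqs: pd.DataFrame  # index = population ids, columns = locus ids
    sample_sizes: pd.Series | None = None  # individuals per population

    def __post_init__(self) -> None:
        self.freqs = self.freqs.astype(float)
        vals = self.freqs.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValidationError("insertion frequencies must lie in [0, 1]")
        if self.freqs.index.has_duplicates or self.freqs.columns.has_duplicates:
            raise ValidationError("duplicate population or locus ids")
        if self.sample_sizes is not None:
            self.sample_sizes = self.sample_sizes.reindex(self.freqs.index)

    @property
    def population_ids(self) -> list[str]:
        return list(self.freqs.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.freqs.columns)

    def row(self, population: str) -> np.ndarray:
        return self.freqs.loc[population].to_numpy()

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix) -> "FreqTable":
        """Per-population insertion frequencies from observed calls."""
        rows, sizes = {}, {}
        for pop in gm.populations:
            sub = gm.subset_population(pop)
            obs = sub.calls != MISSING
            with np.errstate(invalid="ignore"):
                p = np.where(
                    obs.sum(axis=0) > 0,
                    np.where(sub.calls == MISSING, 0, sub.calls).sum(axis=0)
                    / (2.0 * np.maximum(obs.sum(axis=0), 1)),
                    np.nan,
                )
            rows[pop] = p
            sizes[pop] = sub.n_samples
        df = pd.DataFrame.from_dict(rows, orient="index", columns=gm.locus_ids)
        return cls(df, pd.Series(sizes))


@dataclass
class DistanceMatrix:
    """Labelled square symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError("matrix shape does not match label count")
        if len(set(self.labels)) != k:
            raise ValidationError("duplicate labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValidationError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValidationError("distances must be non-negative")

    @property
    def size(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class QMatrix:
    """Per-individual ancestry proportions across K clusters."""

    sample_ids: list[str]
    proportions: np.ndarray  # (n_samples, K)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2:
            raise ValidationError("proportions must be 2-D (samples x K)")
        if self.proportions.shape[0] != len(self.sample_ids):
            raise ValidationError("one row of proportions per sample required")
        if np.any(self.proportions < 0):
            raise ValidationError("ancestry proportions must be non-negative")
        if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each row of Q must sum to 1 (tol 1e-9)")

    @property
    def K(self) -> int:
        return self.proportions.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"cluster_{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.proportions, index=self.sample_ids, columns=cols)
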