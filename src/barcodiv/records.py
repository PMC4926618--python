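"""Core domain containers: barcode sequences, ranked lineages, reference libraries
and species-by-event incidence matrices.

A :class:`SequenceRecord` is one barcode read or contig together with the survey
metadata the downstream stages need (marker name, sampling event, optional
morphospecies label).  A :class:`Lineage` is an ordered ranked taxonomy running
from the most inclusive rank to the least inclusive one.  A
:class:`ReferenceLibrary` couples taxonomically tagged reference sequences with
their lineages.  An :class:`IncidenceMatrix` records how many individuals of
each delimited species were seen in each sampling event and drives rarefaction
and nonparametric richness estimation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

IUPAC = set("ACGTURYSWKMBDHVN-")

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN-", "TGCAAYRSWMKVHDBN-")


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with its survey metadata."""

    id: str
    bases: str
    marker: str = ""
    event_id: str | None = None
    morphospecies: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence record must have a non-empty id")
        if not self.bases:
            raise DataError(f"record {self.id!r}: empty sequence")
        bad = set(self.bases.upper()) - IUPAC
        if bad:
            raise DataError(
                f"record {self.id!r}: non-IUPAC symbols {sorted(bad)!r}"
            )
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_aligned(self) -> bool:
        return "-" in self.bases

    def degapped(self) -> "SequenceRecord":
        """Return a copy with gap characters removed."""
        if "-" not in self.bases:
            return self
        return self.replace_bases(self.bases.replace("-", ""))

    def reverse_complement(self) -> "SequenceRecord":
        return self.replace_bases(self.bases.translate(_COMPLEMENT)[::-1])

    def replace_bases(self, bases: str) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            bases=bases,
            marker=self.marker,
            event_id=self.event_id,
            morphospecies=self.morphospecies,
        )


def check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


@dataclass(frozen=True)
class Lineage:
    """Ordered ranked taxonomy, most inclusive rank first.

    ``ranks`` is a tuple of ``(rank_name, taxon_name)`` pairs, e.g.
    ``(("family", "Fabaceae"), ("genus", "Acacia"))``.  An empty lineage means
    the taxonomy is unknown.
    """

    ranks: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = [r for r, _ in self.ranks]
        if len(names) != len(set(names)):
            raise DataError(f"duplicate rank names in lineage {self.ranks!r}")

    def __len__(self) -> int:
        return len(self.ranks)

    def __bool__(self) -> bool:
        return bool(self.ranks)

    def __iter__(self):
        return iter(self.ranks)

    @property
    def rank_names(self) -> tuple[str, ...]:
        return tuple(r for r, _ in self.ranks)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.ranks)

    def is_prefix_of(self, other: "Lineage") -> bool:
        """True if this lineage equals the first ``len(self)`` ranks of ``other``."""
        return self.ranks == other.ranks[: len(self.ranks)]

    def truncated(self, n_ranks: int) -> "Lineage":
        return Lineage(self.ranks[:n_ranks])

    def joined(self, sep: str = ";") -> str:
        return sep.join(self.taxa)


@dataclass
class ReferenceLibrary:
    """Taxonomically tagged reference sequences.

    Every reference id has a lineage entry; a missing entry in the supplied
    mapping becomes an empty (unknown) lineage.
    """

    records: list[SequenceRecord]
    lineages: dict[str, Lineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_unique_ids(self.records)
        for rec in self.records:
            self.lineages.setdefault(rec.id, Lineage())
        unknown = set(self.lineages) - {r.id for r in self.records}
        if unknown:
            raise DataError(
                f"lineage entries without reference sequences: {sorted(unknown)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def check_disjoint(self, queries: Sequence[SequenceRecord]) -> None:
        clash = {q.id for q in queries} & set(self.ids)
        if clash:
            raise DataError(f"query ids collide with reference ids: {sorted(clash)}")


class IncidenceMatrix:
    """Species-by-sampling-event occurrence counts.

    Rows are delimited species, columns sampling events; entries are
    nonnegative individual counts.  The derived 0/1 incidence is what the
    nonparametric richness estimators consume.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.astype(int)
        if (counts.to_numpy() < 0).any():
            raise DataError("incidence counts must be nonnegative")
        if counts.shape[1] < 1:
            raise DataError("at least one sampling event is required")
        empty = counts.index[(counts.to_numpy().sum(axis=1) == 0)]
        if len(empty):
            raise DataError(
                f"species with zero occurrences: {list(map(str, empty))}"
            )
        self.counts = counts

    @classmethod
    def from_observations(
        cls, species: Sequence[str], events: Sequence[str]
    ) -> "IncidenceMatrix":
        """Build from parallel per-individual (species, event) observations."""
        if len(species) != len(events):
            raise DataError("species and event lists differ in length")
        df = pd.crosstab(pd.Index(species, name="species"),
                         pd.Index(events, name="event"))
        return cls(df)

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def events(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_events(self) -> int:
        return self.counts.shape[1]

    @property
    def incidence(self) -> np.ndarray:
        """Binary species x event incidence (1 when the species occurs)."""
        return (self.counts.to_numpy() > 0).astype(int)

    def incidence_frequencies(self) -> np.ndarray:
        """Per-species number of events in which the species occurs (Y_i)."""
        return self.incidence.sum(axis=1)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "IncidenceMatrix":
        return cls(pd.read_csv(path, index_col=0))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with model provenance.

    Saturated distances (Jukes-Cantor undefined at p >= 3/4) are stored as
    ``numpy.inf`` sentinels; consumers must check :meth:`saturated_pairs`.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    model: str = "p"
    gap_policy: str = "pairwise-deletion"

    def __post_init__(self) -> None:
        n = len(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise DataError("distance matrix shape does not match id count")
        if not np.allclose(np.diag(v), 0.0):
            raise DataError("distance matrix diagonal must be zero")
        finite = v[np.isfinite(v)]
        if (finite < 0).any():
            raise DataError("distances must be nonnegative")
        if not np.allclose(v, v.T, equal_nan=True):
            raise DataError("distance matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    @property
    def n(self) -> int:
        return len(self.ids)

    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        idx = np.argwhere(~np.isfinite(self.values))
        for i, j in idx:
            if i < j:
                out.append((self.ids[i], self.ids[j]))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids),
                            columns=list(self.ids))
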