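"""Species × sampling-unit incidence matrices and descriptive summaries.

The incidence matrix is the bridge between raw collection records and the
richness estimators: entry (i, j) is True when species i was observed in
sampling unit j. Its row sums are the incidence frequencies Y_i ("how many
units contained species i") and the column count m is the number of
sampling units. A unit containing several species contributes one incidence
to each of them, so sum(Y) equals the total number of species observations,
which can exceed m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import CollectionRecord, filter_records

__all__ = ["EmptyInputError", "IncidenceMatrix", "build_incidence", "species_counts"]


class EmptyInputError(ValueError):
    """An operation that needs at least one record received none."""


@dataclass(frozen=True)
class IncidenceMatrix:
    """Presence/absence of each species in each sampling unit.

    ``presence`` is a boolean array with shape (n_species, m).
    """

    species: tuple[str, ...]
    units: tuple[str, ...]
    presence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.presence, dtype=bool)
        object.__setattr__(self, "presence", p)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "units", tuple(self.units))
        if p.shape != (len(self.species), len(self.units)):
            raise ValueError(
                f"presence shape {p.shape} does not match "
                f"{len(self.species)} species x {len(self.units)} units"
            )

    @property
    def incidence_frequencies(self) -> np.ndarray:
        """Y_i: number of units containing each species."""
        return self.presence.sum(axis=1)

    @property
    def m(self) -> int:
        """Number of sampling units."""
        return len(self.units)

    @property
    def s_obs(self) -> int:
        """Number of species observed in at least one unit."""
        return int((self.incidence_frequencies >= 1).sum())

    @classmethod
    def from_frequencies(
        cls,
        frequencies: Sequence[int],
        m: int,
        species: Sequence[str] | None = None,
    ) -> "IncidenceMatrix":
        """Build a matrix with given marginals using a nested layout.

        Species i is placed in the first Y_i units. The marginals (Y, m) are
        exact; the co-occurrence pattern is synthetic (maximally nested) and
        should only be relied on where marginals are all that matters, e.g.
        the Chao2 statistic and its unit-resampling bootstrap.
        """
        Y = np.asarray(frequencies, dtype=int)
        if m < 1:
            raise ValueError("m must be >= 1")
        if np.any(Y < 0) or np.any(Y > m):
            raise ValueError("frequencies must lie in 0..m")
        if species is None:
            species = [f"species_{i + 1}" for i in range(len(Y))]
        units = tuple(f"unit_{j + 1}" for j in range(m))
        presence = np.zeros((len(Y), m), dtype=bool)
        for i, y in enumerate(Y):
            presence[i, :y] = True
        return cls(tuple(species), units, presence)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=list(self.species),
                            columns=list(self.units))


def build_incidence(
    records: Iterable[CollectionRecord], unit: str = "sample_id"
) -> IncidenceMatrix:
    """Build an incidence matrix from collection records.

    ``unit`` names the record attribute defining the sampling unit
    (default: each sample is its own unit). Species are ordered
    lexicographically; units keep first-appearance order.
    """
    recs = list(records)
    if not recs:
        raise EmptyInputError("cannot build an incidence matrix from zero records")
    unit_ids: list[str] = []
    unit_index: dict[str, int] = {}
    species_sets: dict[str, set[int]] = {}
    for rec in recs:
        uid = getattr(rec, unit)
        if uid is None:
            raise ValueError(f"record {rec.sample_id!r} has no {unit!r} value")
        uid = str(uid)
        if uid not in unit_index:
            unit_index[uid] = len(unit_ids)
            unit_ids.append(uid)
        j = unit_index[uid]
        for sp in rec.species_present:
            species_sets.setdefault(sp, set()).add(j)
    species = tuple(sorted(species_sets))
    presence = np.zeros((len(species), len(unit_ids)), dtype=bool)
    for i, sp in enumerate(species):
        presence[i, sorted(species_sets[sp])] = True
    return IncidenceMatrix(species, tuple(unit_ids), presence)


def species_counts(
    records: Iterable[CollectionRecord],
    *,
    locality: str | None = None,
    year: int | None = None,
    site: str | None = None,
) -> pd.DataFrame:
    """Per-species incidence counts (and mean substrate temperature).

    Returns a DataFrame indexed by species with columns ``n_samples`` (number
    of samples in which the species was observed) and ``mean_temperature``
    (mean over the samples that both contain the species and carry a
    temperature; NaN when none do). The total number of species observations
    is ``df["n_samples"].sum()``, also stored in
    ``df.attrs["total_observations"]``. An empty input yields a zero-row
    table.
    """
    recs = filter_records(records, locality=locality, year=year, site=site)
    counts: dict[str, int] = {}
    temps: dict[str, list[float]] = {}
    for rec in recs:
        for sp in rec.species_present:
            counts[sp] = counts.get(sp, 0) + 1
            if rec.temperature is not None:
                temps.setdefault(sp, []).append(float(rec.temperature))
    species = sorted(counts)
    df = pd.DataFrame(
        {
            "n_samples": [counts[sp] for sp in species],
            "mean_temperature": [
                float(np.mean(temps[sp])) if sp in temps else np.nan
                for sp in species
            ],
        },
        index=pd.Index(species, name="species"),
    )
    df.attrs["total_observations"] = int(df["n_samples"].sum()) if species else 0
    df.attrs["n_records"] = len(recs)
    return df
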