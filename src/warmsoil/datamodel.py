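"""Typed data model for the factorial field experiment.

The experiment layout is a randomized complete block design:
2 managements x 2 warming levels x blocks x biennial sampling years.
Every analysis stage joins against :class:`StudyDesign`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MANAGEMENTS = ("conservation", "conventional")
WARMING_LEVELS = ("ambient", "warmed")

#: taxonomic ranks carried by a lineage, most to least inclusive
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    """Raised when input data violates a documented invariant."""


class ConfigurationError(ValueError):
    """Raised when a required configuration value is absent or inconsistent."""


def plot_id_for(management: str, warming: str, block: int) -> str:
    """Deterministic plot identifier for a (management, warming, block) cell."""
    return f"{management}-{warming}-b{block}"


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    plot_id: str
    block: int
    management: str
    warming: str
    year: int


@dataclass
class StudyDesign:
    """Validated factorial sample layout.

    Invariants enforced at construction:

    * sample ids unique;
    * each (management, warming, block, year) combination occurs at most once;
    * years strictly increasing;
    * every sample's labels are members of the declared sets.
    """

    samples: list[SampleMetadata]
    managements: frozenset[str] = frozenset(MANAGEMENTS)
    warming_levels: frozenset[str] = frozenset(WARMING_LEVELS)
    years: tuple[int, ...] = ()
    blocks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.years:
            self.years = tuple(sorted({s.year for s in self.samples}))
        if not self.blocks:
            self.blocks = tuple(sorted({s.block for s in self.samples}))
        seen_ids: set[str] = set()
        seen_cells: set[tuple] = set()
        for s in self.samples:
            if s.sample_id in seen_ids:
                raise ValidationError(f"duplicate sample-id {s.sample_id!r}")
            seen_ids.add(s.sample_id)
            cell = (s.management, s.warming, s.block, s.year)
            if cell in seen_cells:
                raise ValidationError(
                    f"duplicate design cell (management={s.management}, "
                    f"warming={s.warming}, block={s.block}, year={s.year})"
                )
            seen_cells.add(cell)
            if s.management not in self.managements:
                raise ValidationError(
                    f"unknown management {s.management!r}; allowed: "
                    f"{sorted(self.managements)}"
                )
            if s.warming not in self.warming_levels:
                raise ValidationError(
                    f"unknown warming level {s.warming!r}; allowed: "
                    f"{sorted(self.warming_levels)}"
                )
            if s.year not in self.years:
                raise ValidationError(f"year {s.year} not in declared years")
        if any(b - a <= 0 for a, b in zip(self.years, self.years[1:])):
            raise ValidationError("years must be strictly increasing")

    # -- lookup helpers -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def by_id(self, sample_id: str) -> SampleMetadata:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset(
        self,
        management: str | None = None,
        warming: str | None = None,
        block: int | None = None,
        year: int | None = None,
    ) -> list[SampleMetadata]:
        out = []
        for s in self.samples:
            if management is not None and s.management != management:
                continue
            if warming is not None and s.warming != warming:
                continue
            if block is not None and s.block != block:
                continue
            if year is not None and s.year != year:
                continue
            out.append(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample-id": [s.sample_id for s in self.samples],
                "plot": [s.plot_id for s in self.samples],
                "block": [s.block for s in self.samples],
                "management": [s.management for s in self.samples],
                "warming": [s.warming for s in self.samples],
                "year": [s.year for s in self.samples],
            }
        )


class FeatureTable:
    """Dense taxon x sample count table.

    ``counts`` is taxa x samples. Counts must be non-negative integers unless
    ``relative=True``, in which case columns hold relative abundances (used by
    the infinite-depth path of the synthetic generator and by lineage
    renormalization).
    """

    def __init__(
        self,
        taxon_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
        relative: bool = False,
    ) -> None:
        self.taxon_ids = list(taxon_ids)
        self.sample_ids = list(sample_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        if np.any(counts < 0):
            t, s = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[t]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if not relative:
            if not np.issubdtype(counts.dtype, np.integer):
                if not np.allclose(counts, np.round(counts)):
                    t, s = np.argwhere(counts != np.round(counts))[0]
                    raise ValidationError(
                        f"non-integer count at taxon {self.taxon_ids[t]!r}, "
                        f"sample {self.sample_ids[s]!r}"
                    )
                counts = counts.astype(np.int64)
        self.counts = counts
        self.relative = relative

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(
            self.taxon_ids, list(sample_ids), self.counts[:, idx], self.relative
        )

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return FeatureTable(
            list(taxon_ids), self.sample_ids, self.counts[idx, :], self.relative
        )

    def relative_abundance(self) -> "FeatureTable":
        sums = self.column_sums().astype(float)
        if np.any(sums <= 0):
            bad = self.sample_ids[int(np.argmax(sums <= 0))]
            raise ValidationError(f"zero-sum sample {bad!r}")
        return FeatureTable(
            self.taxon_ids, self.sample_ids, self.counts / sums, relative=True
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.taxon_ids, columns=self.sample_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class Lineage:
    domain: str = UNCLASSIFIED
    phylum: str = UNCLASSIFIED
    class_: str = UNCLASSIFIED
    order: str = UNCLASSIFIED
    family: str = UNCLASSIFIED
    genus: str = UNCLASSIFIED

    def at_rank(self, rank: str) -> str:
        key = "class_" if rank == "class" else rank
        return getattr(self, key)

    def to_string(self) -> str:
        prefixes = ("d__", "p__", "c__", "o__", "f__", "g__")
        values = (
            self.domain,
            self.phylum,
            self.class_,
            self.order,
            self.family,
            self.genus,
        )
        return ";".join(p + v for p, v in zip(prefixes, values))

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        parts = [p.strip() for p in text.split(";")]
        values = [UNCLASSIFIED] * 6
        for i, part in enumerate(parts[:6]):
            # strip greengenes/silva-style rank prefixes if present
            if len(part) > 2 and part[1:3] == "__":
                part = part[3:]
            values[i] = part if part else UNCLASSIFIED
        return cls(*values)


class TaxonomyMap:
    """taxon_id -> ranked lineage mapping."""

    def __init__(self, lineages: Mapping[str, Lineage]) -> None:
        self._lineages = dict(lineages)

    def __getitem__(self, taxon_id: str) -> Lineage:
        return self._lineages[taxon_id]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def items(self):
        return self._lineages.items()

    def taxa_at(self, rank: str, label: str) -> list[str]:
        """All taxon ids whose lineage at ``rank`` equals ``label``."""
        label = label.lower()
        return [
            t
            for t, lin in self._lineages.items()
            if lin.at_rank(rank).lower() == label
        ]

    def uncovered(self, table: FeatureTable) -> list[str]:
        return [t for t in table.taxon_ids if t not in self._lineages]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyMap):
            return NotImplemented
        return self._lineages == other._lineages


class MeasurementTable:
    """Sample-keyed numeric measurements with per-column units.

    Missing values are NaN, never silent zeros. Downstream operations drop
    NA rows and log the count.
    """

    def __init__(self, data: pd.DataFrame, units: Mapping[str, str]) -> None:
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample-id {dup!r}")
        missing_units = [c for c in data.columns if c not in units]
        if missing_units:
            raise ValidationError(f"columns without declared units: {missing_units}")
        self.data = data.astype(float)
        self.data.index.name = "sample_id"
        self.units = {c: units[c] for c in data.columns}

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def value(self, sample_id: str, column: str) -> float:
        return float(self.data.at[sample_id, column])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        if self.units != other.units:
            return False
        if list(self.data.index) != list(other.data.index):
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        a, b = self.data.to_numpy(), other.data.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        return bool(np.all((a == b) | both_nan))
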