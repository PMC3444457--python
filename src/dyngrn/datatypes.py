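"""Shared data model for the network-inference pipeline.

Three containers travel through every stage: an :class:`ExpressionMatrix`
(genes × samples with a time/replicate design), a :class:`GeneSetCollection`
(GO/KEGG-style categories), and an :class:`InteractionCatalog` (prior
directed interactions with a typed vocabulary).  All gene identifiers are
matched case-sensitively and exactly; silent case-folding corrupts
enrichment universes and is deliberately not performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary for interaction types.  Anything else read from a file
#: is mapped to "other" with a warning.
INTERACTION_TYPES = ("activation", "inhibition", "binding/association", "other")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values with a per-sample time/replicate design.

    Parameters
    ----------
    values
        genes × samples DataFrame of finite floats; the index holds unique
        gene identifiers, the columns sample names.
    design
        DataFrame indexed by sample name with columns ``time_hours``
        (non-negative float) and ``replicate`` (positive int).  The sample
        set must coincide exactly with the columns of ``values``.

    Values are assumed already log-transformed and normalised; irregular
    time grids such as (0, 0.5, 1, 3, 6, 9) hours are first-class.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        for col in ("time_hours", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design is missing required column {col!r}")
        matrix_samples = set(self.values.columns)
        design_samples = set(self.design.index)
        missing = matrix_samples - design_samples
        if missing:
            raise ValueError(
                f"no design entry for sample column {sorted(missing)[0]!r}"
            )
        extra = design_samples - matrix_samples
        if extra:
            raise ValueError(
                f"design lists sample {sorted(extra)[0]!r} absent from the matrix"
            )
        if (self.design["time_hours"] < 0).any():
            raise ValueError("time_hours must be non-negative")
        # align design row order with the matrix columns
        self.design = self.design.loc[list(self.values.columns)]

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted unique time points in hours."""
        return np.sort(self.design["time_hours"].unique())

    def samples_at(self, time_hours: float) -> list[str]:
        mask = self.design["time_hours"] == time_hours
        return list(self.design.index[mask])

    def mean_by_time(self) -> pd.DataFrame:
        """Per-gene replicate means, genes × sorted time points."""
        cols = {t: self.values[self.samples_at(t)].mean(axis=1) for t in self.timepoints}
        return pd.DataFrame(cols)

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"unknown gene id {missing[0]!r}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.design.copy())


@dataclass
class GeneSetCollection:
    """Named gene categories (GO terms, KEGG pathways, ...) from a GMT file."""

    categories: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            if not members:
                raise ValueError(f"category {name!r} is empty")
            self.categories[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self) -> Iterator[str]:
        return iter(self.categories)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.categories[name]

    def description(self, name: str) -> str:
        return self.descriptions.get(name, "")


@dataclass(frozen=True)
class Interaction:
    source: str
    target: str
    type: str

    def __post_init__(self) -> None:
        if self.type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.type!r}")


@dataclass
class InteractionCatalog:
    """Prior catalog of typed directed interactions (e.g. from KEGG).

    Duplicate typed pairs are collapsed with a warning; the catalog is a set
    of distinct (source, target, type) records.
    """

    records: list[Interaction]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], None] = {}
        deduped = []
        for rec in self.records:
            key = (rec.source, rec.target, rec.type)
            if key in seen:
                warnings.warn(f"duplicate interaction record dropped: {key}")
                continue
            seen[key] = None
            deduped.append(rec)
        self.records = deduped
        self._index: dict[tuple[str, str], str] = {
            (r.source, r.target): r.type for r in self.records
        }

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Interaction]:
        return iter(self.records)

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self._index

    def type_of(self, source: str, target: str) -> str | None:
        return self._index.get((source, target))


@dataclass(frozen=True, order=True)
class NetworkEdge:
    """A signed, weighted, provenance-tagged regulatory edge.

    ``provenance`` records whether the interaction was already present in the
    prior catalog ("database") or emerged from the model fit ("computed").
    """

    source: str
    target: str
    weight: float
    interaction: str
    provenance: str

    def __post_init__(self) -> None:
        if self.weight == 0:
            raise ValueError("edge weight must be nonzero")
        if self.interaction not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction!r}")
        if self.provenance not in ("database", "computed"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
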