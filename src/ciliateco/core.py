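"""Domain containers and basic community transformations.

The study design samples a shelf-to-basin marine domain at fixed nominal
depths in two seasons.  Samples are classified into three spatial zones by
the 200 m bottom-depth / sample-depth thresholds:

* ``neritic`` — bottom depth of the site < 200 m;
* ``upper_oceanic`` — bottom depth >= 200 m and sample depth < 200 m;
* ``deep_oceanic`` — bottom depth >= 200 m and sample depth >= 200 m.

Abundance tables are sample x taxon matrices of non-negative densities
(cells per litre) or counts; no integer constraint is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZONES = ("neritic", "upper_oceanic", "deep_oceanic")
SEASONS = ("summer", "winter")

FEEDING_HABITS = ("detritivore", "bacterivore", "algivore", "raptor", "non-selective")
TROPHIC_TYPES = ("heterotrophic", "mixotrophic")

#: Environmental variables and their grouping used throughout the analyses.
#: Total chlorophyll (Chla) takes part in correlation/Mantel screens but is
#: excluded from the "food" predictor set (its size fractions already are in).
ENV_GROUP_MAP: dict[str, str] = {
    "Sal": "physical",
    "Tem": "physical",
    "pH": "physical",
    "DO": "physical",
    "Nox": "chemical",
    "SRP": "chemical",
    "Si": "chemical",
    "MChla": "food",
    "NChla": "food",
    "PChla": "food",
    "Syn": "food",
    "Peuk": "food",
    "Pro": "food",
}
ENV_VARIABLES = ("Tem", "Sal", "pH", "DO", "Nox", "SRP", "Si",
                 "Chla", "MChla", "NChla", "PChla", "Syn", "Peuk", "Pro")


class InvalidSampleError(ValueError):
    """A sample violates a structural precondition (e.g. depth ordering)."""


class UndefinedProportionsError(ValueError):
    """Proportions requested for an all-zero unit."""


class AnnotationGapError(KeyError):
    """Taxa lack the annotation required by an operation."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups}")


@dataclass
class AbundanceTable:
    """Sample x taxon abundance matrix.

    Wraps a DataFrame whose index holds sample ids and whose columns hold
    taxon ids.  Values must be finite and non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "taxon")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("abundance table contains non-finite values")
        if (values < 0).any():
            raise ValueError("abundance table contains negative values")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def taxa(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def require_multivariate(self) -> None:
        if len(self.samples) < 2 or len(self.taxa) < 2:
            raise ValueError(
                "multivariate operations need at least 2 samples and 2 taxa"
            )

    def subset_taxa(self, taxa) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[:, list(taxa)])

    def subset_samples(self, samples) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(samples)])


def assign_zone(bottom_depth: float, sample_depth: float) -> str:
    """Classify a sample into the neritic / upper-oceanic / deep-oceanic zone.

    Strict readings of the 200 m thresholds: a site with bottom depth of
    exactly 200 m is oceanic, and an oceanic sample taken at exactly 200 m
    is deep.
    """
    if sample_depth < 0 or bottom_depth < 0:
        raise InvalidSampleError("depths must be non-negative")
    if sample_depth > bottom_depth:
        raise InvalidSampleError(
            f"sample depth {sample_depth} m exceeds bottom depth {bottom_depth} m"
        )
    if bottom_depth < 200:
        return "neritic"
    if sample_depth < 200:
        return "upper_oceanic"
    return "deep_oceanic"


@dataclass
class SampleFrame:
    """Per-sample metadata: station, position, season, depths and zone."""

    data: pd.DataFrame

    REQUIRED = ("station_id", "longitude", "latitude", "season",
                "sample_depth", "bottom_depth")

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample frame missing columns: {missing}")
        bad_season = set(self.data["season"]) - set(SEASONS)
        if bad_season:
            raise ValueError(f"unknown season levels: {sorted(bad_season)}")
        if "zone" not in self.data.columns:
            self.data = self.data.copy()
            self.data["zone"] = [
                assign_zone(b, s)
                for b, s in zip(self.data["bottom_depth"], self.data["sample_depth"])
            ]
        else:
            for sid, row in self.data.iterrows():
                expect = assign_zone(row["bottom_depth"], row["sample_depth"])
                if row["zone"] != expect:
                    raise InvalidSampleError(
                        f"sample {sid}: zone {row['zone']!r} inconsistent with "
                        f"depths (expected {expect!r})"
                    )

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    def grouping(self, field_name: str) -> pd.Series:
        if field_name not in self.data.columns:
            raise KeyError(f"no such sample field: {field_name}")
        return self.data[field_name]


@dataclass
class EnvFrame:
    """Per-sample environmental variables with the physical/chemical/food grouping."""

    data: pd.DataFrame
    group_map: dict[str, str] = field(default_factory=lambda: dict(ENV_GROUP_MAP))

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        missing = [v for v in self.group_map if v not in self.data.columns]
        if missing:
            raise ValueError(f"environment table missing variables: {missing}")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def group(self, name: str) -> pd.DataFrame:
        cols = [v for v, g in self.group_map.items() if g == name]
        if not cols:
            raise KeyError(f"no variables in environment group {name!r}")
        return self.data[cols]


@dataclass
class TraitFrame:
    """Per-taxon annotations: taxonomy, feeding habit, trophic type."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "taxon")
        if "feeding_habit" in self.data.columns:
            bad = set(self.data["feeding_habit"].dropna()) - set(FEEDING_HABITS)
            if bad:
                raise ValueError(f"unknown feeding habits: {sorted(bad)}")
        if "trophy" in self.data.columns:
            bad = set(self.data["trophy"].dropna()) - set(TROPHIC_TYPES)
            if bad:
                raise ValueError(f"unknown trophic types: {sorted(bad)}")

    @property
    def taxa(self) -> pd.Index:
        return self.data.index


def relative_abundance(table: AbundanceTable, axis: str = "per_sample"):
    """Proportions per sample (rows sum to 1) or global taxon proportions.

    Raises :class:`UndefinedProportionsError` on all-zero samples
    (per-sample mode) or an all-zero table (global mode).
    """
    values = table.values
    if axis == "per_sample":
        totals = values.sum(axis=1)
        zero = totals == 0
        if zero.any():
            bad = list(table.samples[zero])
            raise UndefinedProportionsError(
                f"all-zero samples have undefined proportions: {bad}"
            )
        return pd.DataFrame(values / totals[:, None],
                            index=table.samples, columns=table.taxa)
    if axis == "global":
        total = values.sum()
        if total == 0:
            raise UndefinedProportionsError("all-zero table")
        return pd.Series(values.sum(axis=0) / total, index=table.taxa)
    raise ValueError(f"unknown axis {axis!r}")


def composition_by_group(
    table: AbundanceTable,
    grouping: pd.Series,
    key: pd.Series,
) -> pd.DataFrame:
    """Proportional composition of summed abundance, per sample group.

    ``grouping`` maps sample -> group (e.g. season or zone); ``key`` maps
    taxon -> level (e.g. class/subclass, feeding habit, trophic type).
    Returns a group x level table of proportions summing to 1 per row.
    """
    unmapped = [t for t in table.taxa if t not in key.index or pd.isna(key.loc[t])]
    if unmapped:
        raise AnnotationGapError(f"taxa lacking annotation: {unmapped}")
    groups = grouping.reindex(table.samples)
    if groups.isna().any():
        missing = list(table.samples[groups.isna()])
        raise ValueError(f"samples missing from grouping: {missing}")
    long = table.data.T.groupby(key.reindex(table.taxa)).sum().T  # sample x level
    summed = long.groupby(groups).sum()  # group x level
    totals = summed.sum(axis=1)
    if (totals == 0).any():
        raise UndefinedProportionsError(
            f"groups with zero total abundance: {list(summed.index[totals == 0])}"
        )
    return summed.div(totals, axis=0)
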