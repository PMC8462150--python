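"""Species catalog: domain types, I/O and per-species predictor derivation.

The catalog is one row per accepted species: first valid description year
(1753 onward, the start of Linnaean binomial nomenclature), genus, a
genus-level growth form (fern / herb / tree-shrub / vine-liana) and the set
of provinces the species occupies.  Provinces carry the covariates used
downstream (area, population density, coastal flag, centroid coordinates)
plus a contiguity adjacency list.

From these two tables the module derives the per-species predictors of
discovery probability: range size (occupied-province count, log-transformed),
coastal occupancy, the bounding latitudes/longitudes of the occupied-province
centroids, and growth-form indicators with tree/shrub as baseline.  All
continuous predictors are min-max standardized to [0, 1] over the analysis
subset so coefficients are comparable effect sizes.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EPOCH_YEAR = 1753  # Species Plantarum; discovery_time = year - EPOCH_YEAR


class GrowthForm(enum.Enum):
    """Coarse plant habit, assigned at genus level."""

    FERN = "fern"
    HERB = "herb"
    TREE_SHRUB = "tree_shrub"
    VINE_LIANA = "vine_liana"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Baseline category for growth-form indicator coding.
BASELINE_FORM = GrowthForm.TREE_SHRUB

#: Continuous predictor columns (min-max standardized to [0, 1]).
CONTINUOUS_COLUMNS = ("range_size", "max_lat", "min_lat", "max_lon", "min_lon")


@dataclass(frozen=True)
class SpeciesRecord:
    """One accepted species with its description year and distribution."""

    species_id: str
    genus: str
    description_year: int
    growth_form: GrowthForm
    provinces: frozenset
    endemic: bool = True

    def __post_init__(self):
        if self.description_year < EPOCH_YEAR:
            raise ValueError(
                f"{self.species_id}: description year {self.description_year} "
                f"precedes {EPOCH_YEAR}"
            )
        if not self.provinces:
            raise ValueError(f"{self.species_id}: empty province set")

    @property
    def discovery_time(self) -> int:
        """Years elapsed since 1753 at first valid description."""
        return self.description_year - EPOCH_YEAR


class ProvinceTable:
    """Province covariates plus symmetric contiguity adjacency.

    Parameters
    ----------
    frame
        Indexed by province code with columns ``area_km2``, ``pop_density``,
        ``coastal`` (bool), ``centroid_lat``, ``centroid_lon``.
    neighbors
        Mapping code -> set of neighboring codes; symmetrized on input,
        self-loops rejected.
    """

    REQUIRED = ("area_km2", "pop_density", "coastal", "centroid_lat", "centroid_lon")

    def __init__(self, frame: pd.DataFrame, neighbors: Mapping[str, set]):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"province table missing columns: {missing}")
        if frame.index.has_duplicates:
            raise ValueError("duplicate province codes")
        if (frame["area_km2"] <= 0).any():
            raise ValueError("province area must be positive")
        if (frame["pop_density"] < 0).any():
            raise ValueError("population density must be non-negative")
        self.frame = frame.copy()
        self.frame["coastal"] = self.frame["coastal"].astype(bool)
        codes = set(frame.index)
        nb = {c: set() for c in codes}
        for a, bs in neighbors.items():
            if a not in codes:
                raise ValueError(f"adjacency references unknown province {a!r}")
            for b in bs:
                if b not in codes:
                    raise ValueError(f"adjacency references unknown province {b!r}")
                if a == b:
                    raise ValueError(f"self-adjacency for province {a!r}")
                nb[a].add(b)
                nb[b].add(a)
        self.neighbors = nb

    @property
    def codes(self) -> list:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, code: str) -> bool:
        return code in self.frame.index

    @classmethod
    def from_csv(cls, province_path, adjacency_path=None) -> "ProvinceTable":
        """Read ``code,area_km2,pop_density,coastal,centroid_lat,centroid_lon``
        plus an optional undirected edge list ``code_a,code_b``."""
        frame = pd.read_csv(province_path, dtype={"code": str}).set_index("code")
        frame["coastal"] = frame["coastal"].astype(int).astype(bool)
        neighbors: dict = {c: set() for c in frame.index}
        if adjacency_path is not None:
            edges = pd.read_csv(adjacency_path, dtype=str)
            for _, row in edges.iterrows():
                neighbors.setdefault(row["code_a"], set()).add(row["code_b"])
        return cls(frame, neighbors)

    def to_csv(self, province_path, adjacency_path=None) -> None:
        self.frame.assign(coastal=self.frame["coastal"].astype(int)).to_csv(
            province_path, index_label="code"
        )
        if adjacency_path is not None:
            seen = set()
            rows = []
            for a in sorted(self.neighbors):
                for b in sorted(self.neighbors[a]):
                    if (b, a) not in seen:
                        seen.add((a, b))
                        rows.append({"code_a": a, "code_b": b})
            pd.DataFrame(rows, columns=["code_a", "code_b"]).to_csv(
                adjacency_path, index=False
            )


@dataclass
class CleaningLog:
    """Row-indexed diagnostics from catalog ingestion."""

    n_read: int = 0
    n_retained: int = 0
    dropped: list = field(default_factory=list)  # (row_index, species_id, reason)

    def drop(self, row: int, species_id: str, reason: str) -> None:
        self.dropped.append((row, species_id, reason))

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def summary(self) -> str:
        reasons = Counter(r for _, _, r in self.dropped)
        lines = [f"read {self.n_read} rows, retained {self.n_retained}, dropped {self.n_dropped}"]
        lines += [f"  {reason}: {n}" for reason, n in sorted(reasons.items())]
        return "\n".join(lines)


class CatalogSchemaError(ValueError):
    pass


class EmptyCatalogError(ValueError):
    pass


_CATALOG_COLUMNS = ("species_id", "genus", "year", "growth_form", "provinces")


def read_catalog(path, province_table: ProvinceTable):
    """Read a species catalog CSV, validating against the province table.

    Expected columns: ``species_id,genus,year,growth_form,provinces,endemic``
    with provinces pipe-separated and endemic 0/1 (defaults to 1 if absent).
    Rows with unknown province codes, pre-1753 years, or unknown growth forms
    are rejected and logged, not fatal.

    Returns
    -------
    (records, log) : (list of SpeciesRecord, CleaningLog)
    """
    df = pd.read_csv(path, dtype={"species_id": str, "genus": str, "provinces": str})
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogSchemaError(f"catalog {path} missing required columns: {missing}")
    if df.empty:
        raise EmptyCatalogError(f"catalog {path} contains no rows")

    valid_forms = {f.value: f for f in GrowthForm}
    log = CleaningLog(n_read=len(df))
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        sid = row.species_id
        try:
            year = int(row.year)
        except (TypeError, ValueError):
            log.drop(i, sid, "unparseable year")
            continue
        if year < EPOCH_YEAR:
            log.drop(i, sid, "pre-Linnaean year")
            continue
        form = valid_forms.get(str(row.growth_form))
        if form is None:
            log.drop(i, sid, "unknown growth form")
            continue
        raw_provs = "" if pd.isna(row.provinces) else str(row.provinces)
        provs = frozenset(p for p in raw_provs.split("|") if p)
        if not provs:
            log.drop(i, sid, "empty province set")
            continue
        unknown = [p for p in provs if p not in province_table]
        if unknown:
            log.drop(i, sid, f"unknown province code(s): {sorted(unknown)}")
            continue
        endemic = bool(int(getattr(row, "endemic", 1)))
        records.append(
            SpeciesRecord(sid, row.genus, year, form, provs, endemic=endemic)
        )
    log.n_retained = len(records)
    return records, log


def write_catalog(records: Sequence[SpeciesRecord], path) -> None:
    """Inverse of :func:`read_catalog`; provinces sorted for determinism."""
    rows = [
        {
            "species_id": r.species_id,
            "genus": r.genus,
            "year": r.description_year,
            "growth_form": r.growth_form.value,
            "provinces": "|".join(sorted(r.provinces)),
            "endemic": int(r.endemic),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=[*_CATALOG_COLUMNS, "endemic"]).to_csv(path, index=False)


def primary_growth_form(genus_members: Sequence) -> GrowthForm:
    """Modal growth form among a genus' species.

    Ties break lexicographically on the form value
    (fern < herb < tree_shrub < vine_liana) so assignment is deterministic.
    ``genus_members`` is an iterable of ``(species_id, raw_form)`` pairs where
    ``raw_form`` is a :class:`GrowthForm` or its string value.
    """
    members = list(genus_members)
    if not members:
        raise ValueError("empty genus member list")
    counts = Counter(
        f if isinstance(f, GrowthForm) else GrowthForm(str(f)) for _, f in members
    )
    # max count, then lexicographically smallest enum value
    top = max(counts.values())
    tied = sorted((f for f, n in counts.items() if n == top), key=lambda f: f.value)
    return tied[0]


class StandardizationError(ValueError):
    pass


@dataclass
class PredictorMatrix:
    """Design matrix for the discovery-probability model.

    ``X`` holds [0,1]-standardized continuous predictors, the 0/1 ``coast``
    flag, and growth-form indicators (tree/shrub baseline).  ``time`` is
    discovery time in years since 1753.  ``raw`` keeps the unstandardized
    continuous values for reporting.
    """

    X: pd.DataFrame
    time: pd.Series
    species_ids: list
    raw: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.X)


def _minmax(col: pd.Series, name: str) -> pd.Series:
    lo, hi = float(col.min()), float(col.max())
    if hi == lo:
        raise StandardizationError(
            f"column {name!r} is constant ({lo}); cannot min-max standardize"
        )
    return (col - lo) / (hi - lo)


def derive_predictors(
    catalog: Sequence[SpeciesRecord],
    provinces: ProvinceTable,
    range_metric: str = "count",
) -> PredictorMatrix:
    """Derive per-species predictors from province-level occupancy.

    range size = number of occupied provinces (default) or summed occupied
    area (``range_metric="area"``), log-transformed then min-max standardized;
    coast = 1 iff any occupied province is coastal; max/min lat/lon are the
    extremes of occupied-province centroids, each min-max standardized over
    the catalog actually passed in (so an endemic-only subset re-standardizes).
    """
    if not catalog:
        raise EmptyCatalogError("cannot derive predictors from an empty catalog")
    pf = provinces.frame
    lat = pf["centroid_lat"]
    lon = pf["centroid_lon"]
    coastal = pf["coastal"]
    area = pf["area_km2"]

    rows = []
    for r in catalog:
        occ = sorted(r.provinces)
        if range_metric == "count":
            size = float(len(occ))
        elif range_metric == "area":
            size = float(area.loc[occ].sum())
        else:
            raise ValueError(f"unknown range metric {range_metric!r}")
        rows.append(
            {
                "range_size_raw": size,
                "coast": int(coastal.loc[occ].any()),
                "max_lat": lat.loc[occ].max(),
                "min_lat": lat.loc[occ].min(),
                "max_lon": lon.loc[occ].max(),
                "min_lon": lon.loc[occ].min(),
            }
        )
    raw = pd.DataFrame(rows, index=[r.species_id for r in catalog])

    X = pd.DataFrame(index=raw.index)
    X["range_size"] = _minmax(np.log(raw["range_size_raw"]), "range_size")
    X["coast"] = raw["coast"]
    for c in ("max_lat", "min_lat", "max_lon", "min_lon"):
        X[c] = _minmax(raw[c], c)
    for form in GrowthForm:
        if form is BASELINE_FORM:
            continue
        X[f"gf_{form.value}"] = [int(r.growth_form is form) for r in catalog]

    time = pd.Series([r.discovery_time for r in catalog], index=raw.index, name="discovery_time")
    return PredictorMatrix(
        X=X, time=time, species_ids=[r.species_id for r in catalog], raw=raw
    )


def collinearity_check(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column, VIF_j = 1/(1 - R^2_j).

    R^2_j comes from regressing column j (with intercept) on all others.
    Exact linear dependence raises a rank-deficiency error.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    arr = np.asarray(X, dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need at least two columns for a collinearity check")
    design = np.column_stack([np.ones(len(arr)), arr])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    vifs = [variance_inflation_factor(design, j + 1) for j in range(arr.shape[1])]
    return pd.Series(vifs, index=list(X.columns), name="VIF")
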