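"""Synthetic species catalogs with known ground truth.

Two generators live here:

* :func:`simulate_logistic_discovery` runs the logistic discovery-count model
  dS_t = (a + b S_t)(S_tot - S_t) forward in time as a counting process,
  for testing the richness estimator against known totals.

* :func:`simulate_catalog` builds a full catalog + province table whose
  discovery years follow a proportional-hazards law: species i is described
  with hazard h0(t) exp(beta . x_i), where h0 is a piecewise-constant pulse
  over 5-year blocks (description effort rose through the 19th century and
  peaked around 1900) and x_i are the standardized range/coast/bounding-box/
  growth-form predictors.  Species still undescribed at the horizon are
  dropped from the catalog but counted in the truth record: they are the
  "undiscovered" pool that the downstream richness estimator should infer.

Provinces sit on a lon x lat grid with rook contiguity; the easternmost
column is coastal, and a log-linear richness gradient makes the southwest
corner the most species-rich, mirroring a flora whose diversity is
concentrated in its southwestern mountains.

Default sizes and coefficients are the study conditions the rest of the
package is tested against; tests pass scaled-down configs explicitly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import (
    EPOCH_YEAR,
    GrowthForm,
    BASELINE_FORM,
    ProvinceTable,
    SpeciesRecord,
)

#: Species-pool sizes per growth form (estimated totals for the flora).
DEFAULT_S_TOT = {
    GrowthForm.FERN: 2712,
    GrowthForm.HERB: 23867,
    GrowthForm.TREE_SHRUB: 12998,
    GrowthForm.VINE_LIANA: 1710,
}

#: Log-hazard effect sizes on the [0,1]-standardized predictors.
DEFAULT_HAZARD = {
    "range_size": 0.51,
    "coast": 0.13,
    "max_lon": 0.90,
    "min_lon": -0.46,
    "max_lat": 0.67,
    "min_lat": -0.73,
    "gf_fern": -0.82,
    "gf_herb": -0.13,
    "gf_vine_liana": -0.13,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic catalog generator."""

    seed: int = 0
    s_tot: dict = field(default_factory=lambda: dict(DEFAULT_S_TOT))
    hazard: dict = field(default_factory=lambda: dict(DEFAULT_HAZARD))
    n_lat: int = 4
    n_lon: int = 7
    lat0: float = 21.0
    lon0: float = 98.0
    lat_step: float = 5.0
    lon_step: float = 4.0
    #: log-weights per degree for a species' home province; negative values
    #: concentrate richness toward the south-west corner.
    richness_gradient_lat: float = -0.12
    richness_gradient_lon: float = -0.04
    mean_range: float = 3.0  # mean occupied-province count (geometric)
    endemic_fraction: float = 0.42
    horizon: int = 2013
    #: overall scale of the piecewise-constant baseline hazard; the default
    #: describes roughly three quarters of the pool by the horizon.
    baseline_scale: float = 1.0
    baseline_peak_year: float = 1900.0
    baseline_sd_years: float = 55.0
    block_years: int = 5
    noise: str = "poisson"  # for simulate_logistic_discovery defaults
    species_per_genus: int = 6

    def __post_init__(self):
        self.s_tot = {
            (GrowthForm(k) if not isinstance(k, GrowthForm) else k): int(v)
            for k, v in self.s_tot.items()
        }
        if any(v < 0 for v in self.s_tot.values()):
            raise ValueError("species pools must be non-negative")
        if self.horizon < EPOCH_YEAR:
            raise ValueError("horizon precedes 1753")
        if not 0 <= self.endemic_fraction <= 1:
            raise ValueError("endemic_fraction outside [0, 1]")

    @property
    def n_provinces(self) -> int:
        return self.n_lat * self.n_lon


@dataclass
class TruthRecord:
    """Everything the generator knows, for parameter-recovery tests."""

    seed: int
    s_tot: dict  # form value -> pool size
    n_discovered: dict  # form value -> described by horizon
    n_undiscovered: dict
    hazard: dict  # generating betas, pool-standardized scale
    hazard_analysis_scale: dict  # betas on the discovered-catalog scale
    horizon: int
    baseline_scale: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_logistic_discovery(
    s_tot: int,
    a: float,
    b: float,
    horizon: int = 2013,
    seed: int | None = None,
    noise: str = "poisson",
    interval: int = 1,
) -> list:
    """Run dS = (a + bS)(S_tot - S) forward from 1753, one step per
    ``interval`` years, and return the description year of each species.

    ``noise="none"`` keeps the deterministic real-valued trajectory and emits
    integer counts by rounding the cumulative curve; ``"poisson"`` draws each
    increment from a Poisson with the deterministic mean; ``"gaussian"``
    rounds a normal draw with matching mean and variance.  The cumulative
    count never exceeds ``s_tot``.
    """
    if s_tot < 0:
        raise ValueError("s_tot must be non-negative")
    if s_tot == 0:
        return []
    if a < 0 or min(a, a + b * s_tot) < 0:
        raise ValueError(
            "parameters imply a negative expected increment over [0, S_tot]"
        )
    if noise not in ("none", "poisson", "gaussian"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    years: list = []
    s_real = 0.0  # deterministic trajectory (noiseless mode)
    emitted = 0
    count = 0  # integer cumulative (stochastic modes)
    for year in range(EPOCH_YEAR, horizon + 1, interval):
        if noise == "none":
            mu = (a + b * s_real) * (s_tot - s_real)
            s_real = min(s_real + mu, float(s_tot))
            new = int(round(s_real)) - emitted
            emitted += new
        else:
            mu = max((a + b * count) * (s_tot - count), 0.0)
            if noise == "poisson":
                new = int(rng.poisson(mu))
            else:
                new = int(round(rng.normal(mu, np.sqrt(mu)))) if mu > 0 else 0
            new = int(np.clip(new, 0, s_tot - count))
            count += new
        years.extend([year] * new)
        if (noise == "none" and emitted >= s_tot) or (noise != "none" and count >= s_tot):
            break
    return years


def _province_grid(config: SimulationConfig) -> ProvinceTable:
    rng = np.random.default_rng(config.seed + 101)
    rows = []
    neighbors: dict = {}
    code = lambda r, c: f"P{r * config.n_lon + c + 1:02d}"
    for r in range(config.n_lat):
        for c in range(config.n_lon):
            lat = config.lat0 + r * config.lat_step
            lon = config.lon0 + c * config.lon_step
            coastal = c == config.n_lon - 1
            # larger provinces inland/west, denser population toward the coast
            area = float(np.exp(rng.normal(11.8, 0.4)) * (1.3 - 0.06 * c))
            pop = float(np.exp(rng.normal(4.0, 0.5) + 0.25 * c))
            rows.append(
                {
                    "code": code(r, c),
                    "area_km2": area,
                    "pop_density": pop,
                    "coastal": coastal,
                    "centroid_lat": lat,
                    "centroid_lon": lon,
                }
            )
            nb = set()
            if r > 0:
                nb.add(code(r - 1, c))
            if c > 0:
                nb.add(code(r, c - 1))
            neighbors[code(r, c)] = nb
    frame = pd.DataFrame(rows).set_index("code")
    return ProvinceTable(frame, neighbors)


def _sample_occupancy(rng, provinces: ProvinceTable, home_weights, mean_range, n):
    """Contiguous ranges: geometric size, random spread from a gradient-
    weighted home province."""
    codes = provinces.codes
    n_prov = len(codes)
    p_geom = min(1.0, 1.0 / mean_range)
    homes = rng.choice(n_prov, size=n, p=home_weights)
    sizes = np.minimum(rng.geometric(p_geom, size=n), n_prov)
    nbrs = {c: sorted(provinces.neighbors[c]) for c in codes}
    out = []
    for h, size in zip(homes, sizes):
        occ = [codes[h]]
        frontier = list(nbrs[codes[h]])
        while len(occ) < size and frontier:
            k = rng.integers(len(frontier))
            nxt = frontier.pop(k)
            if nxt in occ:
                continue
            occ.append(nxt)
            frontier.extend(c for c in nbrs[nxt] if c not in occ)
        out.append(frozenset(occ))
    return out


def _minmax_scale(v: np.ndarray):
    lo, hi = float(v.min()), float(v.max())
    span = hi - lo if hi > lo else 1.0
    return (v - lo) / span, lo, span


def _baseline_blocks(config: SimulationConfig):
    """Piecewise-constant yearly hazard over 5-year blocks: a bell-shaped
    description-effort pulse."""
    starts = np.arange(EPOCH_YEAR, config.horizon + 1, config.block_years)
    mids = starts + config.block_years / 2.0
    shape = np.exp(-0.5 * ((mids - config.baseline_peak_year) / config.baseline_sd_years) ** 2)
    # normalized so the integrated baseline hazard over the horizon is ~1.05
    # at scale 1; with the default covariate mix that describes roughly three
    # quarters of the pool by the horizon
    widths = np.minimum(starts + config.block_years, config.horizon + 1) - starts
    total = float((shape * widths).sum())
    h0 = config.baseline_scale * 1.05 * shape / total
    return starts, widths, h0


def _sample_discovery_years(rng, eta: np.ndarray, config: SimulationConfig):
    """Inverse-CDF sampling from the piecewise-constant PH hazard; returns
    float years (np.inf = undiscovered by horizon)."""
    starts, widths, h0 = _baseline_blocks(config)
    cumH = np.concatenate([[0.0], np.cumsum(h0 * widths)])
    targets = rng.exponential(size=len(eta)) * np.exp(-eta)  # H0(T) target
    idx = np.searchsorted(cumH, targets, side="right") - 1
    years = np.full(len(eta), np.inf)
    inside = idx < len(h0)
    i = idx[inside]
    years[inside] = starts[i] + (targets[inside] - cumH[i]) / h0[i]
    years[years > config.horizon] = np.inf
    return years


def simulate_catalog(config: SimulationConfig):
    """Generate ``(records, provinces, truth)`` under the configured
    proportional-hazards discovery law.

    The hazard is log-linear in the pool-standardized predictors; the truth
    record additionally reports the generating coefficients mapped onto the
    scale of the *discovered* catalog (the min-max standardization any
    downstream fit will actually use), so recovery tests compare like with
    like.
    """
    rng = np.random.default_rng(config.seed)
    provinces = _province_grid(config)
    pf = provinces.frame
    glat, glon = config.richness_gradient_lat, config.richness_gradient_lon
    logw = glat * (pf["centroid_lat"] - config.lat0) + glon * (
        pf["centroid_lon"] - config.lon0
    )
    home_weights = np.exp(logw.to_numpy())
    home_weights /= home_weights.sum()

    forms, genera, occs = [], [], []
    for form in GrowthForm:
        pool = config.s_tot.get(form, 0)
        if pool == 0:
            continue
        occs.extend(
            _sample_occupancy(rng, provinces, home_weights, config.mean_range, pool)
        )
        forms.extend([form] * pool)
        genera.extend(
            f"{form.value}_g{k // config.species_per_genus + 1:04d}" for k in range(pool)
        )
    n = len(forms)
    if n == 0:
        truth = TruthRecord(
            seed=config.seed,
            s_tot={f.value: 0 for f in GrowthForm},
            n_discovered={f.value: 0 for f in GrowthForm},
            n_undiscovered={f.value: 0 for f in GrowthForm},
            hazard=dict(config.hazard),
            hazard_analysis_scale={},
            horizon=config.horizon,
            baseline_scale=config.baseline_scale,
        )
        return [], provinces, truth

    lat = pf["centroid_lat"]
    lon = pf["centroid_lon"]
    coastal = pf["coastal"]
    occ_lists = [sorted(o) for o in occs]
    raw = pd.DataFrame(
        {
            "range_size": np.log([len(o) for o in occ_lists]),
            "max_lat": [lat.loc[o].max() for o in occ_lists],
            "min_lat": [lat.loc[o].min() for o in occ_lists],
            "max_lon": [lon.loc[o].max() for o in occ_lists],
            "min_lon": [lon.loc[o].min() for o in occ_lists],
        }
    )
    scaled = {}
    scale_info = {}
    for col in raw.columns:
        scaled[col], lo, span = _minmax_scale(raw[col].to_numpy())
        scale_info[col] = (lo, span)
    coast = np.array([int(coastal.loc[o].any()) for o in occ_lists])

    eta = np.zeros(n)
    beta = config.hazard
    for col in raw.columns:
        eta += beta.get(col, 0.0) * scaled[col]
    eta += beta.get("coast", 0.0) * coast
    for form in GrowthForm:
        if form is BASELINE_FORM:
            continue
        key = f"gf_{form.value}"
        eta += beta.get(key, 0.0) * np.array([int(f is form) for f in forms])

    years = _sample_discovery_years(rng, eta, config)
    endemic = rng.random(n) < config.endemic_fraction

    records = []
    discovered = np.isfinite(years)
    for i in np.flatnonzero(discovered):
        records.append(
            SpeciesRecord(
                species_id=f"sp{i + 1:06d}",
                genus=genera[i],
                description_year=int(np.floor(years[i])),
                growth_form=forms[i],
                provinces=occs[i],
                endemic=bool(endemic[i]),
            )
        )

    # map generating betas onto the standardization the discovered catalog
    # will induce (affine rescale; the shift is absorbed by the baseline)
    hazard_analysis = dict(beta)
    for col in raw.columns:
        sub = raw[col].to_numpy()[discovered]
        if len(sub) and sub.max() > sub.min():
            _, span_pool = scale_info[col]
            hazard_analysis[col] = beta.get(col, 0.0) * (
                (sub.max() - sub.min()) / span_pool
            )

    n_disc = {f.value: 0 for f in GrowthForm}
    n_tot = {f.value: config.s_tot.get(f, 0) for f in GrowthForm}
    for i, f in enumerate(forms):
        if discovered[i]:
            n_disc[f.value] += 1
    truth = TruthRecord(
        seed=config.seed,
        s_tot=n_tot,
        n_discovered=n_disc,
        n_undiscovered={k: n_tot[k] - n_disc[k] for k in n_tot},
        hazard={k: float(v) for k, v in beta.items()},
        hazard_analysis_scale={k: float(v) for k, v in hazard_analysis.items()},
        horizon=config.horizon,
        baseline_scale=config.baseline_scale,
    )
    return records, provinces, truth
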