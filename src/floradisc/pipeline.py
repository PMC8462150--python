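"""End-to-end orchestration: catalog -> survival -> discovery -> spatial.

One :class:`RunConfig` (YAML-serializable) drives a full reproducible run.
Every stochastic stage gets its own seed derived from the master seed by a
fixed offset, all recorded in the JSON manifest together with input
checksums and per-stage row counts, so a rerun with the same config is
byte-identical and any stage can be re-entered from its CSV outputs.

The ``endemic_only`` subset flag repeats every stage on the species whose
distribution lies entirely within the study region; there is no separate
code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import discovery as disc
from . import spatial as spa
from . import survival as surv

log = logging.getLogger("floradisc")

# fixed per-stage seed offsets from the master seed
SEED_OFFSETS = {"shuffle": 11, "morans": 23, "bootstrap": 37, "simulate": 53}


@dataclass
class RunConfig:
    catalog_path: str = "catalog.csv"
    province_path: str = "provinces.csv"
    adjacency_path: str = "adjacency.csv"
    out_dir: str = "out"
    subset: str = "all"  # all | endemic_only
    cutoff: int = 2000
    bin_width: int = 5
    tie_method: str = "efron"
    error_structure: str = "iid"
    range_metric: str = "count"
    n_shuffles: int = 1000
    morans_permutations: int = 999
    sig_threshold: float = 1.96
    seed: int = 0
    min_province_species: int = 30  # below this, skip the province richness fit

    def __post_init__(self):
        if self.subset not in ("all", "endemic_only"):
            raise ValueError(f"unknown subset {self.subset!r}")

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "versions": _versions(),
        "seeds": {s: config.stage_seed(s) for s in SEED_OFFSETS},
        "inputs": {},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    current = "load"
    try:
        for key in ("catalog_path", "province_path", "adjacency_path"):
            p = getattr(config, key)
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

        provinces = cat.ProvinceTable.from_csv(config.province_path, config.adjacency_path)
        records, clean_log = cat.read_catalog(config.catalog_path, provinces)
        log.info("catalog: %s", clean_log.summary().replace("\n", "; "))
        if config.subset == "endemic_only":
            records = [r for r in records if r.endemic]
            log.info("endemic-only subset: %d species", len(records))
        manifest["stages"]["load"] = {
            "n_read": clean_log.n_read,
            "n_retained": clean_log.n_retained,
            "n_dropped": clean_log.n_dropped,
            "n_analyzed": len(records),
            "n_provinces": len(provinces),
        }

        current = "survival"
        manifest["stages"]["survival"] = _survival_stage(config, records, provinces, out)

        current = "discovery"
        manifest["stages"]["discovery"] = _discovery_stage(config, records, out)

        current = "spatial"
        manifest["stages"]["spatial"] = _spatial_stage(config, records, provinces, out)

        manifest["status"] = "ok"
    except Exception as e:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current
        manifest["error"] = str(e)
        _write_manifest(manifest, out)
        log.removeHandler(handler)
        handler.close()
        raise StageError(current, e) from e
    _write_manifest(manifest, out)
    log.removeHandler(handler)
    handler.close()
    return manifest


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "floradisc": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_manifest(manifest: dict, out: Path) -> None:
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _survival_stage(config, records, provinces, out: Path) -> dict:
    pm = cat.derive_predictors(records, provinces, range_metric=config.range_metric)
    vif = cat.collinearity_check(pm.X)
    vif.to_csv(out / "vif.csv", header=["VIF"])

    fit = surv.fit_cox(pm.X, pm.time, tie_method=config.tie_method)
    fit.summary.to_csv(out / "cox_summary.csv", index_label="term")

    sch = surv.schoenfeld_check(fit, pm.X, pm.time)
    pd.DataFrame({"slope": sch.slope, "p": sch.p_values}).to_csv(
        out / "schoenfeld.csv", index_label="term"
    )

    forms = [r.growth_form.value for r in records]
    curves_gf = surv.strata_survival(forms, pm.time)
    coast = ["coastal" if c else "inland" for c in pm.X["coast"]]
    curves_coast = surv.strata_survival(coast, pm.time)
    rows = []
    for name, sc in (("growth_form", curves_gf), ("coast", curves_coast)):
        for level, df in sc.curves.items():
            d = df.copy()
            d.insert(0, "stratum", level)
            d.insert(0, "variable", name)
            rows.append(d)
    pd.concat(rows, ignore_index=True).to_csv(out / "strata_survival.csv", index=False)

    groups = {}
    for r in records:
        groups.setdefault(r.growth_form.value, []).append(r.discovery_time)
    tukey = surv.tukey_range_test(groups)
    tukey.to_csv(out / "tukey.csv", index=False)

    C, C_se = fit.concordance_
    return {
        "n": fit.n_used,
        "tie_method": fit.tie_method,
        "concordance": C,
        "concordance_se": C_se,
        "aic": fit.aic,
        "max_vif": float(vif.max()),
        "flags": fit.flags,
    }


def _fit_group(years, config, seed):
    curve = disc.bin_discoveries(years, interval=config.bin_width, cutoff=config.cutoff)
    fit = disc.fit_logistic_discovery(
        curve, error_structure=config.error_structure, seed=seed
    )
    rep = disc.completeness_report(curve, fit)
    return {
        "discovered_cutoff": curve.total,
        "discovered_total": curve.total + curve.post_cutoff,
        "s_tot": fit.s_tot,
        "ci_lower": fit.ci_lower,
        "ci_upper": fit.ci_upper,
        "a": fit.a,
        "b": fit.b,
        **rep,
        "flags": "; ".join(fit.flags),
    }


def _discovery_stage(config, records, out: Path) -> dict:
    seed = config.stage_seed("bootstrap")
    by_form: dict = {}
    for r in records:
        by_form.setdefault(r.growth_form.value, []).append(r.description_year)
    rows = []
    for form in sorted(by_form):
        try:
            row = _fit_group(by_form[form], config, seed)
        except (ValueError, RuntimeError) as e:
            log.warning("richness fit failed for growth form %s: %s", form, e)
            row = {"flags": f"fit failed: {e}"}
        rows.append({"group": form, **row})
    gf = pd.DataFrame(rows)
    gf.to_csv(out / "richness_by_growth_form.csv", index=False)

    by_prov: dict = {}
    for r in records:
        for p in r.provinces:
            by_prov.setdefault(p, []).append(r.description_year)
    prows, failed = [], 0
    for code in sorted(by_prov):
        years = by_prov[code]
        if len(years) < config.min_province_species:
            failed += 1
            prows.append({"code": code, "n_species": len(years),
                          "flags": "too few species; skipped"})
            continue
        try:
            row = _fit_group(years, config, seed)
        except (ValueError, RuntimeError) as e:
            failed += 1
            row = {"flags": f"fit failed: {e}"}
        prows.append({"code": code, "n_species": len(years), **row})
    pr = pd.DataFrame(prows)
    pr.to_csv(out / "richness_by_province.csv", index=False)
    if failed:
        log.warning("province richness fits skipped/failed: %d", failed)
    return {
        "n_growth_forms": len(by_form),
        "n_provinces_fit": int(len(prows) - failed),
        "n_provinces_failed": failed,
    }


def _spatial_stage(config, records, provinces, out: Path) -> dict:
    comp = None
    prov_csv = out / "richness_by_province.csv"
    if prov_csv.exists():
        prov_fits = pd.read_csv(prov_csv, index_col="code")
        if "completeness_horizon" in prov_fits:
            comp = prov_fits["completeness_horizon"]
    else:
        log.warning("no province richness fits found; completeness omitted")
    summary = spa.summarize_provinces(records, provinces, completeness=comp)
    summary.to_csv(out / "province_summary.csv")

    perm = spa.standardized_discovery_time(
        records, provinces, n_shuffles=config.n_shuffles,
        seed=config.stage_seed("shuffle"), threshold=config.sig_threshold,
    )
    perm.to_csv(out / "standardized_discovery_time.csv")

    mi = spa.morans_i(
        summary["mean_discovery_year"], provinces,
        permutations=config.morans_permutations, seed=config.stage_seed("morans"),
    )

    ols = spa.fit_ols_step(summary)
    ols.summary.to_csv(out / "ols_mean_discovery_time.csv", index_label="term")
    mi_resid = spa.morans_i(
        ols.residuals, provinces,
        permutations=config.morans_permutations, seed=config.stage_seed("morans"),
    )

    result: dict = {
        "morans_I_mean_year": mi.I,
        "morans_p": mi.p_permutation,
        "morans_I_ols_residuals": mi_resid.I,
        "morans_resid_p": mi_resid.p_permutation,
        "ols_terms": ols.selected_terms,
        "ols_adj_r2": ols.fit_statistic,
        "n_significant_z": int(perm["significant"].sum()),
    }
    if comp is not None and summary["completeness"].notna().sum() >= 8:
        beta = spa.fit_beta_step(summary)
        beta.summary.to_csv(out / "beta_completeness.csv", index_label="term")
        result["beta_terms"] = beta.selected_terms
        result["beta_pseudo_r2"] = beta.fit_statistic
        result["beta_phi"] = beta.phi
    else:
        log.warning("too few provinces with completeness; beta regression skipped")
        result["beta_terms"] = None
    return result
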