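# floradisc

Discovery-pattern analysis for a vascular-plant species catalog.

Most of the world's undescribed plant species will be found where floras are
least complete, and the history of *when* each known species was first
described carries the signal of *where* and *what kind* of species remain
undiscovered (the Linnean shortfall).  Starting from a catalog with one row
per accepted species — first valid description year (1753 onward), genus,
genus-level growth form (fern / herb / tree-shrub / vine-liana) and the set
of provinces it occupies — this package answers three questions:

1. **What drives discovery probability?**  Description dates are
   time-to-event data with no censoring, modelled with a Cox proportional
   hazards regression `h_i(t) = h0(t) exp(β·x_i)` on standardized
   range size, coastal occupancy, bounding latitudes/longitudes and growth
   form, with Efron tie handling (description years are heavily tied),
   scaled-Schoenfeld diagnostics, Harrell's concordance, stratified survival
   curves and Tukey range tests among growth forms.

2. **How many species remain undescribed?**  Per group or region, 5-year
   binned discovery counts are fitted with the logistic discovery model
   `ΔS_t = (a + b S_t)(S_tot − S_t) + ε_t`, estimating total richness
   `S_tot` and inventory completeness = described / `S_tot`.

3. **Where did discovery run early or late?**  Province-level mean
   discovery times, a permutation null (description years shuffled across
   species, occupancy held fixed) yielding standardized discovery-time
   z-scores, Moran's *I* over the contiguity graph, OLS for mean discovery
   year and logit-link beta regression for completeness, both with backward
   AIC selection.

A synthetic-catalog generator with a known proportional-hazards discovery
law, known per-form species pools and a southwest-to-northeast richness
gradient provides ground truth for every stage, so the whole pipeline is
testable without any data download.

## Worked example

```bash
floradisc simulate --seed 3 --scale 0.08 --out demo   # ~2,600 described species
python - <<'EOF'
from floradisc import RunConfig, run_pipeline
config = RunConfig(catalog_path="demo/catalog.csv",
                   province_path="demo/provinces.csv",
                   adjacency_path="demo/adjacency.csv",
                   out_dir="demo/out", seed=7)
manifest = run_pipeline(config)
s = manifest["stages"]
print(f"species analysed: {s['load']['n_analyzed']}")
print(f"Cox concordance:  {s['survival']['concordance']:.3f}")
print(f"Moran's I (mean discovery year): {s['spatial']['morans_I_mean_year']:.3f}")
print(f"OLS adjusted R2:  {s['spatial']['ols_adj_r2']:.3f}")
EOF
```

The `simulate` step reports `wrote 2597 species to demo/catalog.csv (706
undiscovered in truth)`, and the pipeline prints:

```
species analysed: 2597
Cox concordance:  0.573
Moran's I (mean discovery year): 0.776
OLS adjusted R2:  0.834
```

Concordance 0.57 says the fitted hazard ranks a randomly chosen pair of
species by description date correctly 58% of the time (0.5 = no
discrimination).  The strongly positive Moran's I says neighboring
provinces have similar mean discovery years — here induced by the
generator's richness gradient — and the OLS `R²` says province covariates
(species count, coast, longitude/latitude) explain most of that spatial
pattern.  `demo/out/` then holds one CSV per result table: Cox effect
sizes with 95% CIs, per-growth-form richness estimates `S_tot` with
completeness, per-province standardized discovery-time z-scores (|z| > 1.96
flags provinces described significantly earlier/later than expected), and
the two selected regressions.

Every run writes a `manifest.json` with per-stage seeds, input checksums
and row counts; rerunning the same config reproduces every output
byte-for-byte.

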