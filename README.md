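# migflow

Internal-migration and daily-mobility analytics from mobile-phone XDR
streams, with a synthetic-data generator that plants a recoverable ground
truth for every stage.

## The problem

Mobile-network billing events (XDRs — tuples ⟨device *d*, time *t*,
antenna *a*⟩) are a high-frequency alternative to censuses for monitoring
how people move during a crisis. Two very different kinds of movement
matter: **long-term relocation** (a household changing its home region over
months) and **daily mobility** (routine short-range movement, sharply
curtailed under lockdowns). Both vary strongly with socioeconomic status.
`migflow` implements the full inference chain for a country organised into
*regions* and *comunas* (municipalities), with one focal metropolitan
region as the origin of emigration analyses:

1. **Home detection** — a device's weekly home antenna is its most used
   tower during night-time (22:00–06:00) on weekdays; its home comuna is
   that antenna's comuna.
2. **Migration call** — a device migrated if the statistical mode of its
   weekly home over the four November weeks lies in a different *region*
   than its baseline home in the second week of March.
3. **Flow analytics** — origin–destination (OD) matrices m(x, y), per-origin
   emigration percentages 100·M(x)/n(x), and the net migration rate
   per comuna, `per · (inflow − outflow) / population` (default per 1000).
4. **Destination choice** — year-over-year OD share differences with a
   z-score (>1.96) significance filter; the exact 1-Wasserstein divergence
   of each origin's destination distribution between years on a configurable
   ground coordinate (income decile by default); the emigrant-weighted mean
   destination rurality `R_x = (1/M(x)) Σ_y m(x,y) r(y)` and its change
   ΔR_x against a baseline year; weighted destination density and
   quality-of-life (ICVU) differences; a gravity ordering of host regions
   (population / distance to the focal centre); and arrivals as a
   percentage of each host region's population.
5. **Daily mobility** — any transition between two different antennas is a
   movement; internal if both antennas share a comuna, external otherwise.
   Per comuna and day the package reports the mean number of
   internal/external/total transitions per active homed device, its
   percentage-point reduction against the baseline-week mean, and the same
   split by quarantine status from a per-comuna quarantine calendar.
6. **Stratified statistics** — OLS of any outcome on the comuna income
   decile (Pearson r, R²), and a Welch two-sample t-test between the
   richest 20% of the decile distribution and the rest.

Because real national XDR feeds are proprietary, the package ships a
generator (`migflow.synth`) that emulates the relevant structure — night
anchoring, daytime excursions, income-stratified post-shock mobility
contraction, planted inter-region relocations — so every estimator can be
validated against known truth at desk scale.

## Worked example

Run the whole pipeline on a simulated study year (a pre-crisis comparison
year is generated automatically on the same geography):

```python
import migflow as mf
from migflow.pipeline import RunConfig, run_pipeline

cfg = RunConfig(out_dir="demo",
                scenario=mf.ScenarioConfig(n_devices=2000, rng_seed=42))
result = run_pipeline(cfg)
print(result["summary"])
```

prints (exactly reproducible under the same seed):

```json
{
  "emigration_recovery_r": 1.0,
  "emigration_vs_decile_r": 0.3556806524987313,
  "mean_wasserstein": 1.5721750509027002,
  "net_flow_balance": 0,
  "reduction_rich_poor_p": 7.601648526184834e-05,
  "reduction_vs_decile_r": 0.829371107050148,
  "retained_destinations": 5,
  "total_migrants": 181
}
```

Reading the numbers: 181 of 2000 devices relocated to another region;
inflows and outflows over all comunas balance exactly
(`net_flow_balance = 0`, the closed-system check); the recovered per-comuna
emigration fractions correlate perfectly with the planted ones at this
noise level (`emigration_recovery_r`); emigration rises with origin income
decile (r ≈ 0.36, the planted gradient); the post-shock mobility reduction
is strongly income-graded (r ≈ 0.83 on the reduction scale, rich–poor
Welch test p ≈ 8·10⁻⁵); and five destination comunas pass the z > 1.96
filter on the year-over-year OD difference. `demo/` holds every
intermediate artifact (homes, calls, OD matrices, rates, divergences,
mobility series) as CSV plus a manifest with row counts and content
hashes.

The same stages are available on the command line:

```bash
migflow simulate --config scenario.yaml --out data/
migflow homes --xdr data/xdr.csv --antennas data/antennas.csv \
        --out homes.csv --study-start 2020-03-01 --study-end 2020-11-30
migflow migrate --homes homes.csv --comunas data/comunas.csv \
        --out-prefix out/ --study-start 2020-03-01 --study-end 2020-11-30
migflow run --config run.yaml          # full pipeline from one file
```

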