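# corrshape

Correlogram shape quantification for multi-unit spike-train recordings.

Neuronal recordings (MEA, EEG-derived event streams, imaging-derived spike
trains) yield one *raster* — a list of firing times — per recorded signal.
Cross-correlation analysis compares rasters pairwise: the **correlogram**
of a comparison signal against a reference is the histogram of relative
timings `t = t_c − t_r`, which, normalized, is the conditional probability
`C(x)` of a comparison event at lag `x` given a reference event at 0.
Correlogram *shape* carries information that does not rely on assuming
functional connectivity, yet is rarely quantified automatically: with
`N` signals and many analysis windows there are far too many `N²`
correlograms to inspect by eye.

`corrshape` builds correlograms for all signal pairs in user-defined
*analysis regions* of a recording and quantifies three shape metrics per
correlogram:

* **Uniformity** — a chi-squared goodness-of-fit test of the bin counts
  against the flat distribution `C(x) = 1/L` (`L` bins, `L − 1` degrees of
  freedom): `χ² = Σ (O_x − E)² / E` with `E = S/L`, where `S` is the total
  pair count. A flat correlogram means the signals fire independently.
* **Peak count and peak times** — local maxima of the loess-smoothed
  correlogram whose prominence strictly exceeds `1/L`; more peaks indicate
  more diverse firing patterns, and peak times are classified into
  log-timescale decades or EEG-style frequency bands (`f = 1/|t|`).
* **Area left of zero** — `A = Σ_{x<0} C(x) + ½·C(0)`, the probability
  mass at negative lags. `A` far from 0.5 means one signal consistently
  leads the other; mirrored pairs satisfy `A(j,i) = 1 − A(i,j)` exactly
  and map to one of five leader/follower strength classes.

Each metric is classified per correlogram per region; the package then
tracks class fractions across regions, region-to-region (or
before/after-treatment) transition probabilities, and the combined
`uniformity × strength × peak-count` combination table — revealing how
population firing dynamics change under experimental treatments
(disinhibition, pH stress, injury, …).

A synthetic-raster module generates populations with known structure
(independent Poisson units, fixed-lag leader/follower pairs, periodic
population bursts with partial participation, and mid-recording regime
switches including unit death), so the whole pipeline is testable and
calibratable without any recording files.

## Worked example

Simulate a 28-minute recording of 8 units that fire independently
(3 Hz Poisson) for 14 minutes and then synchronize into 0.25-s periodic
population bursts, and analyze it in 7-minute regions:

```python
from corrshape import RunConfig, ScenarioSpec, generate, run_pipeline, write_raster_csv

spec = ScenarioSpec(
    "regime_switch", n_units=8, duration=28 * 60.0, rate=3.0,
    switch_time=14 * 60.0, base_scenario="poisson",
    after={"scenario": "periodic_bursts", "participation": 0.9,
           "in_burst_rate": 40.0, "baseline_rate": 1.0},
    seed=5,
)
write_raster_csv(generate(spec), "demo.csv")

cfg = RunConfig(
    input_path="demo.csv", output_dir="demo_out", duration=28 * 60.0,
    region_length_s=7 * 60.0, range_s=1.0, bin_width_s=0.001,
    treatments=((14 * 60.0, "synchronization"),),
)
run_pipeline(cfg)
```

`demo_out/fractions.csv` then contains, among the per-scheme rows, the
fraction of nonuniform cross-correlograms per region:

```
 region_index           scheme      class  fraction  n
            1 uniformity_class nonuniform  0.071429 56
            2 uniformity_class nonuniform  0.035714 56
            3 uniformity_class nonuniform  1.000000 56
            4 uniformity_class nonuniform  1.000000 56
```

While the units fire independently (regions 1–2) the nonuniform fraction
sits at the chi-squared test's false-positive level (≈ the 0.05
significance cutoff); after synchronization onset (regions 3–4) every
pair is flagged nonuniform. The other tables in `demo_out/` hold the raw
metrics (`metrics.csv`), per-correlogram classes, transition
probabilities grouped before/after the treatment, and the combined
classification combo table; `plots=True` renders heatmaps, violin/strip
distributions and transition matrices from those tables.

The same pipeline runs from a shell:

```sh
corrshape simulate --scenario poisson --seed 1 --n-units 20 --out raster.csv
corrshape analyze --config run.yaml
corrshape plot --tables out/
```

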