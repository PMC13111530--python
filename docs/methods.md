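# Methods

## Correlogram construction

For a reference train with events `t_r` and a comparison train with
events `t_c`, every ordered pair contributes a lag `t = t_c − t_r`. Lags
are binned on a symmetric grid of `2K + 1` bins of width `w` centered at
0, with `K = round(R/w)` for a requested half-range `R` (so ±1 s at 1 ms
gives 2,001 bins). A lag is assigned to the nearest bin center; a lag
sitting exactly on a bin edge (half-integer multiple of `w`) is resolved
toward zero, so +2.5 ms → bin 2 and −6.5 ms → bin −6 at `w` = 1 ms. Edge
detection is tolerant of floating-point division noise (relative
tolerance 1e−9), since the tie rule would otherwise be decided by the
rounding direction of `lag/w`.

A pair contributes iff its lag assigns to one of the `2K + 1` bins, i.e.
`|t| ≤ R + w/2`. This keeps the outermost bins full-width: restricting to
`|t| ≤ R` would give the two end bins only half their catchment, making
even independent Poisson pairs systematically non-flat (a noncentrality
of about `E/2` for expected bin count `E`, independent of the bin count)
and destroying the calibration of the uniformity test.

Pairing is restricted to events inside the half-open analysis region
`[start, end)`; pairs spanning a region boundary are not counted, so each
region is self-contained. For autocorrelograms the pairing of an event
with itself (which carries no timing information and would pin half the
mass at lag 0) is excluded; coincident events of *different* units are
counted. Empty correlograms (total 0) have undefined probabilities and
are flagged rather than analyzed; a user sparsity threshold additionally
excludes correlograms whose reference × comparison event-count product is
at most the threshold.

The builder is vectorized (per-reference window search on sorted arrays);
its contract is exact integer equality with the brute-force all-pairs
double loop, which the test suite enforces on random trains.

## Uniformity

With bin counts `O_x`, total `S` and `L` bins, the test statistic is
Pearson's `χ² = Σ (O_x − E)²/E`, `E = S/L`, referred to the upper tail of
the chi-squared distribution with `L − 1` degrees of freedom. A
correlogram is *uniform* iff `p > α` (default `α = 0.05`); `p` exactly at
`α` counts as nonuniform. A variant statistic `Σ (O_x − E)²` (the same
squared deviations without the `1/E` normalization) is available as
`chi2_variant="as_printed"` for comparison with software that computes it
that way, but it does not follow a chi-squared law and the Pearson form
is the default used for classification.

The chi-squared approximation needs `E ≳ 5`; below that the row is
flagged (`expected_count_warning`) rather than refused, since sparse
regions are themselves informative. Calibration is verified in the test
suite: on 500 independent Poisson pairs (5 Hz, 100 s, 21-bin ±50 ms
correlograms, `E ≈ 12`) the rejection fraction at `α = 0.05` must fall
in [0.03, 0.08]. These generation parameters keep the number of
comparison events per reference window low; strong pair-sharing between
overlapping reference windows inflates the statistic's variance beyond
the multinomial model, which is a property of the correlogram sampling
process, not of the test implementation.

## Peaks

Before peak detection the probability correlogram is smoothed by
loess-style local quadratic regression: each bin is replaced by the value
at that bin of a tricube-weighted degree-2 fit over a centered window of
`W` bins (truncated at the edges; `W = 1` disables smoothing). Interior
bins share one window geometry, so smoothing reduces to a precomputed
convolution kernel; the fit reproduces exactly quadratic input wherever
the window is untruncated. The default `W = 5` bins removes single-bin
shot noise while moving a 1-bin-resolved peak by less than a bin; users
analyzing very sharp structure should set `W = 1`.

Peaks are strict local maxima of the smoothed correlogram (plateaus
collapse to their middle bin; endpoints are never peaks) whose
prominence — height above the higher of the two flanking reference
minima — **strictly** exceeds `1/L`, i.e. peaks that stand out more than
the level of a uniform distribution. Peak count and signed peak lags are
recorded; peak lags are classified either into log-decade timescale
classes anchored at the range (for `R = 1` s: `|t| ≤ 1 ms`, (1, 10] ms,
(10, 100] ms, (100 ms, 1 s]; a lag of exactly 0 belongs to the smallest
class) or into frequency bands of `f = 1/|t|`. The bands are made
contiguous and half-open — delta [0, 4), theta [4, 8), alpha [8, 13),
beta [13, 32), gamma [32, ∞) Hz — so that every frequency maps to exactly
one band; the conventional EEG band edges leave gaps (7–8 Hz, 12–13 Hz,
30–32 Hz) that would otherwise drop peaks. Lag 0 has undefined `f` and is
skipped in frequency mode.

## Firing order

The area left of zero is `A = Σ_{x<0} C(x) + ½·C(0)`. Splitting the
center bin's mass equally between the two sides makes the mirror identity
`A(j,i) = 1 − A(i,j)` hold exactly (swapping reference and comparison
reverses the bin order, and the lag-0 bin is shared); the variant that
excludes the center bin entirely is available (`half_center=False`) but
breaks the identity whenever mass sits at lag 0. Autocorrelograms are
symmetric by construction and give `A = 0.5`.

`A` maps to five leader/follower strength classes symmetric about 0.5
(weak 0.4 < A < 0.6; fairly weak 0.6 ≤ A < 0.7 or 0.3 < A ≤ 0.4;
intermediate 0.7 ≤ A < 0.8 or 0.2 < A ≤ 0.3; fairly strong 0.8 ≤ A < 0.9
or 0.1 < A ≤ 0.2; strong A ≥ 0.9 or A ≤ 0.1), so a pair's two mirrored
correlograms always share a class. Values within 1e−9 of a class
boundary are snapped to it before classification so that the computed
mirror value `1 − A` cannot fall on the other side of the boundary
through floating-point rounding.

Note that `A` is informative on the timescale of the lag window: with a
wide window relative to the firing rate, background coincidences pull `A`
toward 0.5 regardless of a genuine fixed-lag relationship. The lag range
should be chosen on the timescale of the interaction of interest.

## Regions, periods and tracking

Automatic segmentation tiles `[0, duration)` with fixed-length regions
and drops a trailing remainder shorter than one region
(count = `floor(duration/length)`); manual labelled regions are
supported. A region belongs to the "after" period of a treatment iff the
treatment time is strictly before the region's end — the region
containing the treatment is grouped with the response. Class fractions
are computed per region over non-sparse cross-correlograms
(autocorrelograms can be included by a switch); transition probabilities
tally, for each correlogram identity, its class in consecutive regions
and normalize rows to conditional distributions, either per step or
pooled by the period of the destination region. Steps with a sparse (or
absent) endpoint are skipped and the skip count reported, rather than
imputed. The combined table reports the percent of correlograms in each
`uniformity × strength × peak-count` cell — `2·5·(M+1)` cells for peak
ceiling `M` (110 at `M = 10`).

## Synthetic scenarios

The generators emulate the qualitative regimes of cultured-network
recordings: stationary independent firing (homogeneous Poisson), a
fixed-lag follower with Gaussian jitter (leader/follower pair), periodic
population bursts with per-burst Bernoulli participation over a Poisson
baseline (rhythmic synchronization), and a regime switch that swaps
scenario or parameters mid-recording, including silencing a random unit
subset (death). Defaults (20 units, 600 s, 5 Hz baseline; 10 ms lag with
2 ms jitter; 0.25 s burst period with 50 ms bursts at 100 Hz and 0.8
participation) are on the scale of spontaneously active cortical
cultures. They do **not** model refractory periods, rate
non-stationarity within a regime, bursty single-unit ISI statistics, or
spike-sorting artifacts — so passing tests demonstrate correctness of
the measurement pipeline on known ground truth, not robustness to every
feature of real recordings.

Each generator draws from a single seeded NumPy generator; fixed seed
gives byte-identical CSV output. Jitter can reorder follower events;
sorting restores the train invariant.

## Pipeline and numerical choices

The pipeline stages run in a fixed order (load/clean → regions/periods →
raster metrics → correlograms → shape metrics → classifications →
transitions → combos), writing headed CSVs plus a manifest JSON with
config, per-file SHA-256 hashes and elapsed time; identical config and
input give byte-identical tables. Correlograms are cached keyed by a
hash of the inputs that determine them (raster identity, cleaning,
region definitions, binning geometry), so re-runs changing only metric
or classification settings skip the expensive stage; any geometry change
misses the cache and recomputes.

Cleaning drops events in excluded half-open windows and removes listed
units without re-basing the clock; duplicate timestamps within a unit
are retained (zero ISIs are clipped into the lowest histogram bin
downstream). ISI histograms default to 50 log10-spaced bins over
[0.1 ms, 1000 s] with out-of-range intervals clipped into the end bins.
Rate traces use 1-minute windows (trailing partial window kept), sample
SD with denominator `N − 1`, and 0 for a single unit.

Test problem sizes (hundreds of Poisson pairs at ~500 events per train,
two- to four-region synthetic recordings of 10–20 units) were chosen so
the statistical contracts are well-powered while the default suite stays
fast on a single CPU.

## Known limitations

* Shift-predictor/jitter-corrected correlograms, per-bin significance
  bands, and functional-connectivity or transfer-entropy estimation are
  out of scope.
* Rhythm fundamental-frequency extraction from harmonic peak spacing is
  not implemented; peak-time band labels are per-peak only.
* Refractory-period estimation from autocorrelograms is not performed.
* The `.plx` vendor format is not parsed; `register_adapter` lets users
  attach an external reader returning the standard `Recording`.
* Heat-map sequences are exported as static per-region images; no video
  encoding.
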