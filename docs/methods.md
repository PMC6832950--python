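# Methods

## Histogram tensorization

The unit of analysis is the county-year.  Rather than feeding imagery
to the network, every (composite period, band) pair is reduced to a
normalized histogram of the crop-masked pixel values inside the county.
This preserves sub-county heterogeneity that a zonal mean discards,
while making the input size independent of county area, and it lets
bands of different native resolution coexist without co-registration:
each band is masked and histogrammed on its own grid.

Conventions, stated exactly because the test oracle depends on them:

* **Composite calendar.** 8-day periods anchored at day-of-year
  {1, 9, …, 361} in every year, leap or not; a seasonal calendar keeps
  periods whose *start date* lies inside the season window.  An
  April 1 – December 31 season therefore has exactly 34 periods (start
  DOYs 97…361); truncating at JUN-2 leaves 8, at AUG-21 leaves 18.
* **Masking.** A cell of a band raster is kept if its center lies
  inside the county polygon *and* the crop mask, sampled at that center
  by nearest cell, is positive.  Band values are never resampled.
* **Weather alignment.** Daily series are averaged (arithmetic mean)
  over each 8-day window, for precipitation as well as vapour pressure;
  days missing from a window are excluded from its mean, and an
  all-missing window propagates as "no pixels" for that period.
* **Histograms.** n_bins (default 32) equal-width bins over fixed band
  limits; intervals are half-open [e_i, e_{i+1}) with the last bin
  closed; values outside the limits are clamped into the boundary bins
  so no mass is discarded; counts are divided by the pixel count; an
  empty pixel set yields the all-zero vector, which is the "no data"
  marker downstream.
* **Band limits.** Defaults are the empirical limits of the original
  CONUS soybean study: reflectance 1–5000, surface temperature
  12400–15600 (scaled Kelvin), precipitation 0–35 mm/day, vapour
  pressure 0–3200 Pa.  `estimate_limits` re-derives limits from pooled
  pixels (all counties, periods and years of a band pooled together) at
  the (0.005, 0.995) quantiles when users prefer data-driven limits.
* **Labels.** Yields are converted to kg/ha on ingestion; bu/ac uses
  the 60 lb soybean test weight, 67.25 kg/ha per bu/ac.  County-years
  with zero crop pixels everywhere, or without a yield record, are
  dropped, with per-rule counts reported.

## Model

The CNN-LSTM treats each per-step slice as an 11-band x 32-bin image.
Convolutions and max-pools use 1x2 kernels acting along the *bin* axis
only — band order is arbitrary, so mixing adjacent bands would be
meaningless — with "same" padding, so the bin axis reduces 32 → 16 → 8
under the two pools and the per-step feature vector has length
bands x 8 x 64.  The stack (conv 32 → ReLU → batch norm → pool →
conv 64 → ReLU → batch norm → pool → flatten → batch norm) is applied
identically at every time step; a 256-unit LSTM consumes the sequence
and emits an output per step; a shared dense(64) with ReLU, a flatten
over time, dropout 0.5 and a linear unit produce the yield.  The output
is linear (non-negativity is not enforced).  Batch-norm statistics are
frozen at inference, per standard practice.

The baselines are minimal ablations sharing all widths: the CNN
baseline replaces the recurrence by concatenating all per-step features
into one dense layer; the LSTM baseline feeds raw flattened slices to
the recurrent layer.  A consequence worth knowing: at the published
widths the CNN baseline is the *largest* network (its concatenated
dense layer holds 34x5632x64 ≈ 12M weights), larger than the full
CNN-LSTM (~6.6M).

Training minimises mean squared error with Adam (step size 1e-3,
standard moment decays), batch 16, up to 100 epochs, early stopping
when the validation loss fails to improve for 10 consecutive epochs on
a uniformly random 20% validation split, with the best-validation
weights restored afterwards.  Yields are z-scored from the training
fold for optimisation and de-standardised at prediction: raw kg/ha
targets (~1000–4000) destabilise small-batch training.  One integer
seed drives the split, the initialisation, batch order and dropout
masks; runs are bit-reproducible on a fixed platform.  An optional
global gradient-norm clip is available but off by default.

Because no deep-learning framework is part of the dependency set, the
layers (1x2 convolution, batch normalization, 1x2 max-pool, LSTM with
full backpropagation through time, dense, dropout) are implemented
directly over numpy with hand-derived backward passes; the test suite
verifies every parameter gradient of all three architectures against
central finite differences, and the early-stopping rule against a
scripted loss sequence.

## Evaluation protocol

Rolling origin: for evaluation year y and time node d, train only on
years < y with tensors truncated at d (periods starting on or before
d), predict year y, and report RMSE, per-county signed percent error
and R².  Each evaluation year trains its own model from scratch — no
warm starting.  R² is the squared Pearson correlation between predicted
and observed yields (the "how well does the prediction reconstruct the
spatial variation" reading); the 1 − SSE/SST definition is available as
an option.  Multi-seed evaluation reports mean ± sd because a single
run of a stochastic procedure is not a stable estimate.

Time nodes are keyed by calendar date, not step index, and map to steps
8, 12, 16, 17, 18, 19, 21, 25, 29 and 34 of the 34-step season.  The
published benchmark tables shipped in `histoyield.reference` include a
five-year average row; note the printed averages were computed before
the per-year values were rounded, so re-averaging the printed values
reproduces them only to ~0.3 kg/ha.

## Synthetic regions

The simulator emulates the *structure* of the real inputs, not their
radiometry.  Counties are axis-aligned rectangles (8–12 fine cells per
side) tiled on a shared grid — polygon complexity is irrelevant to
every algorithm under test, and real polygons are supported by the
GeoJSON reader.  Reflectance bands live on a fine grid, temperature and
weather on a 2x coarser grid, so the multi-resolution contract is
always exercised.  Per county-year, a latent greenness g ~ N(1, 0.15²)
scales a double-logistic phenology curve (green-up day 165, senescence
day 270, slopes 0.09/0.08, ±3-day county jitter) seen by all seven
reflectance bands with band-specific baselines and signs (NIR up, red
and SWIR down); a latent heat anomaly h ~ N(0, 1) raises surface
temperature, lowers vapour pressure and dries the intermittent
exponential rain process.  Yield is

    yield = 400 + 200·G − 250·S + ε,   ε ~ N(0, 120²) kg/ha,

with G = g·Σ_p dl(mid-DOY_p) (integrated greenness, ~14 at g = 1) and
S = max(h, 0).  These defaults give realistic county soybean yields
(~3100 ± 460 kg/ha) in which spectral signal dominates but environment
bands still carry real information — the regime the feature-group
ablation probes.  The truth table records G, S and ε per county-year,
so tests can verify the generating link exactly and recover its
coefficients by OLS.

What the simulator does *not* emulate: cloud/aerosol artifacts and
compositing QA, classification error in the crop mask, spatial
autocorrelation of weather across counties, trends or technology gains
across years, and nonlinear yield responses.  Passing tests therefore
demonstrate that the pipeline and models are implemented correctly and
can extract a known signal — not that the published real-data accuracy
transfers.

## Problem sizes and the fast profile

The published layer widths (32/64 filters, 256 LSTM units) train
comfortably on GPUs; the package's own experiments run on one CPU, so
the evaluation scripts use a reduced "fast profile" — 4/8 filters,
24 LSTM units, dense 12, learning rate 3e-3 — with the architecture
topology, batch size, loss, split and stopping rule unchanged, and cap
training at ≤30 epochs.  Synthetic experiments use 150 counties x
8 years (1200 county-years, ~45 crop pixels per county) with the last
year held out for rolling-origin evaluation and three seeds per
condition.  These sizes are stated here as the package's defaults for
its own reported numbers; they are command-line arguments, not limits.

## Known limitations

* Shapefile input is not supported; convert county boundaries to
  GeoJSON first.
* GeoTIFF support covers north-up rasters with square cells
  (ModelPixelScale/ModelTiepoint tags) — sufficient for regridded
  archive exports, not for arbitrary projections.
* The LSTM-family models at small widths are sensitive to
  initialisation on near-linear problems; multi-seed averaging is the
  supported way to report results (single-seed numbers can swing by
  ±100 kg/ha on the synthetic benchmark).
* R² as squared correlation is affine-invariant: a model with a
  systematic bias can still score high; read it together with RMSE.
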