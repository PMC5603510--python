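# Methods

This package is a desk-scale emulation of a kinase-inhibitor
cardiotoxicity screen on cardiomyocyte monolayers: a synthetic
384-well screen with planted ground truth, endpoint extraction from
calcium-flux and tissue-force traces, blank-normalized screen
statistics, a from-scratch multilayer perceptron trained with
Levenberg–Marquardt, and a design-grid compound ranking. This note
records the scientific and numerical choices, their defaults, and the
known limitations.

## Synthetic screen generator (`kinotox.synth`)

**Registry.** 80 blinded compounds mapped onto 23 kinase targets
(every target covered, assignment seeded). Targets are encoded as
integer indices throughout.

**Plate layout.** Three 384-well plates. Columns 1–2 of each plate
hold the reference wells: 6 blanks and 3 replicates each of vehicle,
positive chronotrope (1.5× beat frequency), negative chronotrope
(0.2× magnitude, 0.5× frequency) and lethal control (no beating,
zero viability). Test compounds occupy columns 3–24 row-major: 80
compounds × 3 concentrations (0.1, 1, 10 µM) × 3 replicates = 720
test wells split across the plates.

**Effect model.** Each compound acts multiplicatively on four
endpoints: calcium peak magnitude, beat frequency, viability fraction
and live-cell count. Per-target effect profiles are smooth low-order
Fourier series over the target index, so compounds on nearby targets
behave similarly — this is what makes the target index learnable.
Dose scaling uses h = log10(c/c_min)/2. The magnitude potency and the
side-channel (viability/frequency) potency are drawn *independently*
per compound: with a shared potency the network can identify
compounds through the side inputs alone, and the constrained-grid
ranking degenerates. Each compound's planted magnitude score (mean
magnitude multiplier − 1 across doses) is written to
`planted_truth.csv` for validation.

**Traces.** Calcium traces are 40 s at dt = 0.1 s (401 samples):
a flat baseline (100 units) plus Gaussian transients (amplitude 25,
width 0.1 s, truncated at 4σ) at 1 Hz, with additive white noise
(sd 0.5 by default). Truncation makes zero-noise recovery exact.
Force traces are piecewise-linear beats (rise at the contraction
slope, fall at the relaxation slope, baseline 0 µN); values within
1e-12 of the resting level are snapped to exactly 0 to remove
floating-point dust from the fall-segment arithmetic.

**Counts.** live = 8000 × 0.9 × viability multiplier (with
log-normal noise); total = live / viability, so the zero-noise
default gives total 8000, dead 800.

## Endpoint extraction (`kinotox.traces`)

**Noise floor.** The minimum contraction amplitude is `multiplier ×
pooled SD` of linearly detrended non-beating control wells
(default multiplier 3). Blank wells in this pipeline carry cells and
beat, so the *lethal-control* wells supply the background-noise pool.
A pooled SD below 1e-12 of the signal scale is returned as exactly 0
(scipy's detrend leaves ~1e-14 residue on constant traces).

**Peak detection.** A peak is a local maximum whose prominence clears
the noise floor; its magnitude is the raw maximum minus the minimum
of the preceding inter-peak valley. Peak *locations* are found on a
3-sample centered moving average; magnitudes are always measured on
the raw samples. Rationale: with the 3σ default floor, isolated noise
excursions occasionally clear a raw-prominence threshold (blank wells
counted 40–42 beats); the short centered average suppresses them
while a symmetric transient keeps its maximum position, so zero-noise
recovery stays exact. After this change blank wells count exactly 40
beats and lethal controls ≈ 0.

**Contractility.** Per paced beat: active tension = max − min; beat
duration = time above baseline + 10% of active tension (linear
interpolation at the crossings); slopes = extreme central-difference
derivatives on the rise and fall (an endpoint-secant variant is
available). Metrics are averaged over beats.

## Screen statistics (`kinotox.stats`)

Endpoints are normalized per plate as (raw − blank mean)/blank mean.
Effects are banded as sign(z) × min(ceil(|z|), 3) where z is the
normalized deviation from control in control-SD units. Dose series
are tested with one-way ANOVA followed by *protected* Fisher LSD
(pairwise t with pooled within-group variance, flagged only when the
omnibus test is significant). The ANOVA F/p match
`scipy.stats.f_oneway` to 1e-10 in tests.

## Network and training (`kinotox.ann`)

A fully-connected MLP with tansig/logsig/purelin transfers and affine
input/output scaling to [−1, 1] stored on the network. Training is
Levenberg–Marquardt on the sum of squared residuals: solve
(JᵀJ + λI)δ = Jᵀr with the Jacobian from vectorized backpropagation;
λ ×10 on a rejected step, ×0.1 on an accepted one; accepted RMSE is
strictly decreasing. A linear network reproduces ordinary least
squares to < 1e-8, and the Jacobian matches central finite
differences to 1e-5 (relative, with 1e-8 absolute cushion for
near-zero entries — finite differences themselves carry ~1e-11
absolute truncation noise).

Model inputs: concentration, kinase target index, normalized
frequency, normalized viability, normalized live cells; output:
normalized peak magnitude (one record per compound × concentration).
Data are split 90/10; candidate architectures are trained with
multiple restarts and ranked by held-out R² (squared Pearson
correlation), then RMSE; diverged fits rank last. Three
per-concentration control networks map (normalized live cells, target
index) → normalized viability.

## Ranking (`kinotox.ranking`)

The design grid crosses 13 log-spaced concentrations in [0.1, 10] µM,
11 normalized-frequency levels in [−0.05, 0.05] and 11
normalized-viability levels in [0, 0.1] (live cells tied to
viability): 1,573 rows per compound, 125,840 for the full registry.
Compounds are ranked by mean predicted normalized peak magnitude
(descending; ties broken by compound id): the maximum is the least
detrimental compound, the minimum the most detrimental. Because the
only compound-specific grid input is the kinase target index,
compounds sharing a target receive identical predictions and tie.

## Validation with planted ground truth (`kinotox.recovery`)

1. **Planted surface.** 240 records drawn from a known smooth
   surface over the model inputs plus Gaussian noise (sd 0.1); the
   surface amplitudes are chosen so the response SD (~0.7) matches
   the screen's normalized-magnitude dynamic range (noise ceiling
   R² ≈ 0.98). The selected network reaches held-out R² ≈ 0.97.
2. **Ranking recovery.** A dose-rich screen — 10 compounds on 10
   targets at 24 log-spaced concentrations in triplicate (240 model
   records) — is run through the full pipeline and the predicted
   ranking is compared with the planted magnitude scores. At seed 1:
   Spearman 0.891, held-out R² 0.990.

## Known limitations

- Ranking recovery depends on the luck of the planted draw: across
  seeds 1–8 the Spearman median is ~0.92, but draws with a flat or
  unfavourable planted score distribution (e.g. planted-score SD
  ~0.29) can fall below 0.8. The default 3-concentration screen
  (30 records for 10 compounds) is far too small; the dose-rich
  design is required.
- Normalized viability/frequency inputs can act as partial
  compound-identity proxies when magnitude and side-channel effects
  are correlated; the generator draws them independently, but real
  screens may not.
- The design grid constrains the side inputs to narrow intervals; a
  network trained on wells far outside those intervals extrapolates
  there.
- All cross-stage well references use plate-qualified keys
  ("P01:A1"); bare well ids repeat across plates and silently merge
  wells if used as keys.
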