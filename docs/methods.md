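# Methods

This note documents the models, algorithms and numerical choices behind
`cagescale`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Signal model

A recording is a 1 Hz log of load-cell mass (g), light-sensor reading
(arbitrary units), and two binary switches, with real-time-clock
timestamps.  The observed mass decomposes as

    observed(t) = true_mass(t) + transients(t) + chips(t) + drift(t) + ε(t)

where `true_mass` is a non-increasing staircase (pieces of pellet leave
the holder and do not come back), `transients` are zero-net push/pull
excursions from animal-device interaction, `chips` are spike-then-dip
artifacts from debris, `drift` is slow sensor wander, and `ε` is Gaussian
sensor noise plus 1 mg ADC quantisation.  The pipeline's job is to
recover `true_mass` (→ intake), count the transients (→ activity), and
segment the light channel.

## Filtering

**Band-pass (`mass_filter`).**  The output holds the last accepted level
until the input departs by more than `buffer` grams for at least
`plateau_min_duration` seconds.  Two passes: an online state machine
locates change-points (a departure run resets whenever a sample returns
inside the buffer), then every inter-change segment level is re-estimated
as the median of the raw samples it spans.  The re-estimation is what
makes long plateaus accurate to ≪ the noise floor (a 30 min plateau is
recovered to ~0.5 mg), which the benchtop step protocol needs: pellet
masses are manually weighed to 10 mg and the recovered increments must
match at that precision.

* `buffer` default **0.1 g**: twice the ±0.045 g fluctuation a static
  drift test shows (`recommended_buffer`), configurable.
* `plateau_min_duration` default **5 s**: spans chew-induced
  oscillations at 1 Hz without delaying genuine steps noticeably.

**Plateau reduction (`plateau_filter`).**  Segments at or above the
running plateau (pushes) are dropped.  A candidate drop is classified by
the median of the filtered series over the `pull_window` (default 120 s)
after its onset: if the median lies closer to the running plateau than to
the dropped level, the drop is a transient pull and is discarded;
otherwise it is committed.  The window median is robust to clusters of
several transients, which defeat any "first recovery" look-ahead rule.
Pulls sustained beyond roughly half the window are misclassified as
feeding; at the simulator's transient durations (seconds) this is
vanishingly rare, but recordings of animals that hang on the holder for
minutes would need a larger window.

**Terminal settle.**  Daily intake is defined as calibrated mass minus
the final *stable* reading.  A pure threshold filter leaves an O(buffer)
dead-band at the end of the recording (sub-buffer feeding since the last
committed step is invisible), and a pull in progress at the recording
boundary cannot be classified by a forward-looking window.  When the raw
trace is supplied, the final plateau is therefore re-anchored on the
median of the trailing `settle_window` (120 s) whenever that stretch is
quiet (median absolute deviation < buffer/2), capped at the preceding
plateau level so the staircase stays non-increasing.  This brings the
end-of-recording intake error from O(0.1 g) to O(1 mg).

**Chip filter.**  Automatic detection needs the band-passed series as a
reference, because a non-increasing staircase cannot retain the upward
spike: a chip is a reference excursion ≥ `chip_spike_min` (0.5 g) above
the plateau followed within `chip_window` (300 s) by the plateau settling
≥ `chip_dip_min` (0.3 g) below its pre-spike value.  Attenuation raises
all later levels so the net drop across the chip interval is zero; real
feeding inside the interval is sacrificed (and logged).  Manual intervals
force attenuation regardless of detection, reproducing the
identify-by-eye workflow; every attenuation is recorded in the metadata.
The thresholds are declared defaults — chips are described qualitatively
in the field and are usually confirmed by eye.

**Interaction detection.**  `|raw − plateau|` is thresholded
bidirectionally (default threshold = buffer, making the event count
noise-referenced); crossings within `refractory` (10 s) of the previous
bout start merge.  Because the plateau can sit up to one buffer above the
true mass while sub-threshold feeding accumulates, the reference level is
first re-centered by a 60 s rolling median of the residual, clipped to at
most one dead-band downward — the rolling median follows the slow
dead-band drift but not genuine short excursions.  Counting is bout-based
(starts, not samples); with the refractory at 10 s, bout counts saturate
near 360/h, and recordings with denser true event trains are undercounted
by the merge fraction (~e^(−rate·refractory)).

**Rates.**  Centered finite differences of the cumulative series over
`rate_window` (default 3600 s for per-hour plotting), clamped one-sided
at the ends and rescaled to per-hour.  The trapezoidal integral of the
rate reproduces the final cumulative value up to boundary truncation of
O(window/duration): exact to <0.1% at narrow windows or day-length
recordings, ~0.5% for an hour-wide window on a 4 h fixture.

## Light channel and alignment

The LDR has no absolute calibration, so ON/OFF thresholds default to the
25%/75% points of the observed range; stretches between thresholds longer
than `debounce` (5 samples) are RAMP, shorter ones are absorbed.  A trace
whose samples mostly fall between the auto thresholds is unimodal
(constant light level + noise): it is returned as a single segment
flagged ambiguous, labelled OFF — correct for dark recordings, and
explicitly marked as unresolvable otherwise.  Schedule inference calls a
recording LD when ON onsets alternate with a stable 24 ± 1 h period,
reporting lights-on (first full onset) and the median full ON duration as
the photoperiod; no ON → DD, no OFF → LL, anything else → irregular.

Folding maps recording time to hours in [0, 24) anchored at lights-on
(ZT) or at a user-supplied projected lights-on (CT; the package cannot
know the animal's prior schedule).  Days are combined by per-bin mean
with per-bin counts retained — this uses all data and matches mean ± SEM
ribbon plotting; a single-day crop is available by cropping first.

## Rhythm fitting

`fit_sum_of_sines` fits `y = Σ aᵢ sin(bᵢx + cᵢ)` (x in hours) by
bound-constrained trust-region-reflective least squares
(`scipy.optimize.least_squares`, `xtol = ftol = 1e-12`) after removing
the series mean, making the fit invariant under constant offsets; `r²`
is computed about the mean.  Initialisation is deterministic: a
vectorised Lomb-Scargle scan of 1500 frequencies inside the period
bounds (default 4–48 h, spanning ultradian ≈10 h through free-running
≈24 h), block-averaged to ≤1500 samples for the scan only; the optimiser
starts from the top three periodogram peaks (amplitude/phase from a
linear fit at fixed frequency) and the best fit by SSE is kept, never
worse than its own start.  Amplitudes are normalised non-negative with
phases in [0, 2π), so the single-term identities `A = 2d` and
`T·ω = 2π` hold exactly.  A flat series returns a degenerate-flagged
fit rather than raising.  Multi-term fits peel periodogram peaks
greedily; intensity/period metrics are defined for `j = 1` only.
Intensities of rate timelines are reported per day (×24 rescale of
per-hour rates).

## Statistics

The origin-constrained slope is the closed form `Σxy/Σx²`.  Its primary
`r²` is taken about the origin (1 − RSS/Σy², guaranteed in [0, 1] for
the constrained fit); the conventional about-the-mean value is reported
alongside, since both conventions exist for through-origin fits.  The
slope-vs-unity test uses `F = [RSS(β=1) − RSS(β̂)] / [RSS(β̂)/(n−1)]`
with (1, n−1) degrees of freedom, which is exactly F-distributed under
Gaussian errors — the test suite verifies a 3–7% empirical type-I rate
at α = 0.05 over 1000 replicates.  Pearson matrices flag zero-variance
pairs as undefined instead of propagating NaN.  External activity traces
are ingested as plain two-column time,value CSVs and binned to match;
vendor export schemas are out of scope.  Repeated-measures ANOVA and
t tests on the exported summary tables are left to general statistics
software.

## The simulator

`simulate_recording` emulates the study conditions: 48 h at 1 Hz,
calibration 55 g (half-full holder), sensor noise sd 0.015 g (±3 sd
spans the ±0.045 g static fluctuation), 1 mg quantisation.  Bites are a
thinned Poisson process with sinusoidal intensity peaking mid-dark;
the modulation index is `m = π(dark_fraction − 0.5)` so a dark-phase
share of 0.75 maps to m ≈ 0.79.  Defaults: 4.4 g/d intake as 0.01 g
nibbles (nibble-scale gnawing rather than whole-pellet removal), crumb
fraction 0.05 of every bite (≈0.22 g/d, the scale sieving studies
report, ≤5% of intake), a 0.3 g × 2 s gnaw pull accompanying each bite,
zero-net push/pull transients at 60/h (exponential 3 s durations,
0.6 ± 0.3 g), chips off by default (they are injected explicitly where
under test), drift zero (static tests show none), optional battery
truncation.  Scenario presets (`wt_ld`, `wt_dd`, `cry_ld`, `cry_dd`)
echo the qualitative structure of entrained versus clock-deficient
animals: ~22.3–22.5 h feeding periods and ~6.5 g/d intensity for
controls, reduced light-cycle intake and an ultradian 12.76 h feeding
period in constant darkness for the clock-deficient scenario, with
dark fractions back-computed from the target intensities via A = 2mI.

What the simulator does **not** emulate: humidity-driven pellet mass
changes, hoarding, multi-animal cages, biomechanical chewing dynamics,
or load-cell hysteresis.  Passing tests therefore demonstrate that the
algorithms recover truth under the declared signal model at realistic
noise scales — not that every real-world artifact is handled.

## Problem sizes in tests

The test suite and the acceptance script scale simulations to what the
checks need: conservation and monotonicity sweeps use 8 h and 4 h
recordings (the dead-band and transient behaviour they probe is
duration-independent), rhythm recovery uses 48 h series at 1-minute
resolution (the device's native day-scale problem after light binning),
the synthetic crumbling cohort uses 19 × 48 h recordings, and preset
rhythm replication averages 3 seeds per scenario.
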