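# Methods

This note documents the models, estimators, parameter defaults and design
choices behind each `hippomap` stage, and what the synthetic-data tests do
and do not establish about real recordings.

## Probe lattice

The default map is 8 shanks at 300 µm pitch; each shank carries two
columns of 64 rows at 30 µm vertical pitch, 27 µm column-center
separation and 14 µm square contacts, grouped into 4 frontend modules of
32 channels. Channel ordering is shank-major, then row-major, then
column. y = 0 is the topmost row and increases toward the tip; x = 0 is
shank 0's left column. Columns are vertically aligned (not staggered).

The printed active recording length of this probe family (1924 µm) is not
exactly reconstructable from 64 rows at 30 µm pitch plus a 14 µm contact,
which gives 1904 µm. The map keeps the stated 30 µm pitch and reports the
span derived from the geometry (2141 x 1904 µm = 4.08 mm²), about 1 %
below the printed 4.12 mm²; tests allow 2 % for this documented
discrepancy. The 27 µm column separation is itself back-derived so that
the lateral span 7x300 + 27 + 14 = 2141 µm reproduces the printed width.

## Synthetic recordings

The generator renders, on any lattice, the sum of independent components;
all injected parameters are recorded as ground truth.

**Noise.** Gaussian noise shaped in the frequency domain: a flat band
mask with 5 % raised-cosine edges confined to 0.1–300 Hz (LFP band) and
300–5000 Hz (AP band), each scaled so its standard deviation equals the
configured RMS (defaults 16.45 and 6.67 µV — the hardware's measured
values). Frequency-domain shaping keeps essentially all power inside the
nominal band, so the PSD-integrated band RMS matches the target to ~1 %.
The spectrum inside each band is white; real LFP is closer to 1/f, which
mainly affects detector SD estimates, not the pipeline logic.

**Sharp-wave ripples.** A carrier at `ripple_freq` (default 150 Hz) under
a Gaussian envelope whose ±2σ support is `ripple_duration_ms` (default
60 ms), weighted across depth by a Gaussian profile centred on the
pyramidal-layer rows, plus a concurrent negative sharp-wave deflection
(default 150 µV, twice the envelope width) on radiatum rows. Ripple
amplitude is specified as `ripple_snr` times the 80–250 Hz noise SD
(default 6) so detectability is controlled directly. Event peaks are
drawn uniformly with a non-overlap margin; the event count is
`round(rate x duration)` so stated study conditions ("20 ripples in
60 s") are met exactly.

**Dentate spikes.** A peaked (Gaussian) positive pulse on hilus rows
(default 0.4 mV) — giving a well-defined wide-band peak time — and a
flat-topped (Tukey) negative pulse on molecular-layer rows (default
0.3 mV), so the mean molecular deflection over the event tracks the
configured amplitude that the 0.19 mV inclusion criterion tests.

**Gamma.** Pure sinusoids confined to laminar row ranges with a seeded
random initial phase.

**Units.** Biphasic template (narrow negative Gaussian trough, broader
positive peak at the configured trough-to-peak latency, normalised to the
configured peak-to-peak amplitude, default 82 µV). Across channels of the
soma's shank, amplitude decays exponentially with Euclidean distance
(length constant default 150 µm) and the trough is delayed by
`slope_below` (`slope_above`) ms/mm of axial distance below (above) the
soma. Spike trains are Poisson with a 1.5 ms refractory; optional
multiplicative rate gain inside ripple events; units with κ > 0 place
spikes at von Mises-distributed phases of a designated gamma source
(exact inversion of the source's phase). Samples are stored float32 µV in
memory and quantised to int16 at 0.2 µV/bit on disk.

Not emulated: 1/f background structure, electrode impedance variation,
drift, spike-sorting errors, waveform heterogeneity beyond the template,
and compartmental biophysics. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
model, not robustness to every property of in vivo data.

## Ripple detection

Pipeline, in order: (1) difference-of-Gaussians band-pass (80–250 Hz),
built as the difference of two Gaussian low-pass FIR kernels with −3 dB
points at the band edges — symmetric, hence zero-phase/linear-phase; DC
gain exactly 0; normalised to unit gain at the band centre. (2) A copy
clipped at 4 SD of the band-passed signal is rectified and low-pass
filtered at `mean(band)/p` Hz with p = 3 cycles (55 Hz for 80–250 Hz);
its mean and SD define the normalisation — clipping makes these statistics
robust to the events themselves. (3) The non-clipped signal gets the
identical envelope. (4) Normalised-envelope excursions above 4 SD are
events; (5) each expands until the envelope falls below 1 SD; (6) events
shorter than 15 ms are discarded; (7) overlapping expansions merge. The
SD in step 2 is that of the band-passed signal (before rectification),
and envelope statistics are taken over the whole recording.

At 6x-SD events the envelope maximum — the reported peak — jitters by up
to ~20 ms on occasional events because the 55 Hz envelope smoothing
passes noise fluctuations of comparable width; median peak error on
synthetic data is ~4 ms. On the pure noise model the detector produces
~0.07 spurious events/s at these thresholds (Monte-Carlo, 60 s).

## Dentate-spike detection

Both channels are band-passed 2–50 Hz (same DoG filter); positive peaks
of the hilus-minus-molecular difference above 2 SD of the difference
trace (a configurable pre-screen; the criterion proper follows) and at
least 50 ms apart are candidates; the candidate window is the positive
lobe of the difference around the peak. A candidate passes only if the
wide-band molecular LFP averaged over the window is below that channel's
own mean over the −36 to −16 ms baseline by more than 0.19 mV. The
criterion uses the wide-band (unfiltered) molecular trace, since the
2 Hz high-pass would partially remove the slow deflection being measured.
Peak time is the wide-band hilus maximum within the window; candidates
whose baseline precedes the recording start are skipped with a warning.

## Triggered averages and CSD

Triggered averages are arithmetic means of aligned snippets; events whose
padded window leaves the recording are dropped and counted. CSD is the
negative second spatial difference along one electrode column divided by
the squared pitch, in arbitrary units (conductivity constant and
omitted); boundary rows duplicate the edge potentials (Vaknin padding) so
all 64 rows are reported; sinks are negative. No spatial smoothing by
default (optional 3-point Hamming). 1D column-wise CSD is used rather
than 2D kernel methods because maps are read per shank; inverse (kCSD)
methods are out of scope.

## Unit metrics

Footprints are spike-triggered means over a −1 to +2 ms window at
20 kHz. Trough-to-peak is measured on the peak-to-peak-maximal channel
(ties: lowest channel id) from the minimum to the subsequent maximum.

The autocorrelogram (0.5 ms bins, 50 ms span) is fitted with
`max(c(exp(−(t−t0)/τ_decay) − d·exp(−(t−t0)/τ_rise)) + h·exp(−(t−t0)/τ_burst) + r, 0)`
by bounded least squares from a small deterministic set of starts.
Because on a flat autocorrelogram the rise limb only chases noise (and
its τ is then unidentifiable), the full model is compared against a
reduced no-rise fit by BIC; when the rise limb is unsupported, τ_rise is
reported at the 0.1 ms floor ("no detectable suppression"). Fits require
≥ 500 spikes (configurable); non-convergence yields NaN τ_rise, which the
cascade sends to the pyramidal class.

Cell types: narrow interneuron if trough-to-peak < 0.425 ms; wide
interneuron if ≥ 0.425 ms and ACG rise time > 6 ms; otherwise pyramidal.
Bursts are maximal runs of ≥ 2 spikes with consecutive inter-spike
intervals < 9 ms. Peri-event histograms divide lag counts by
(events x bin width).

## Backpropagation

Same-shank channels within ±250 µm axially of the dominant channel whose
trough depth exceeds 12 % of the dominant trough are selected; each
channel's trough is searched within ±0.7 ms of the dominant trough (so a
weak channel's measurement tracks the same action potential, not a noise
dip) and timed to sub-sample precision by a 3-point parabola — at 20 kHz
the 50 µs sample period would otherwise quantise delays coarsely against
the 30 µm pitch.

Delays are re-referenced to the earliest trough; that channel is reported
as the putative initiation site (ties broken toward the soma, then lowest
id). Delay (ms) is regressed by OLS on |axial distance| (mm) separately
for channels above and below the *soma* row (each side needs ≥ 3
channels; the soma row anchors both). Splitting at the soma rather than
at the initiation site matters under noise: the earliest-trough channel
is an extreme-value pick among near-simultaneous channels, and measuring
distances from it biases slopes; the regression intercept absorbs the
re-referencing instead. A side counts as propagating only if its slope is
positive, statistically significant (one-sided t-test, p < 0.01), and
above 0.05 ms/mm — a quarter sample period across the 250 µm radius,
below which delays are indistinguishable from simultaneity. Simultaneous
sides are reported as slope 0 with a flag. Classes: ascending (above-side
propagation only), descending (below only), curved (both), otherwise
undetermined. Recovery on synthetic units at AP-band SNR 10 with ~500
averaged spikes is within ~6 % over slopes 0.2–2 ms/mm.

## Spike-LFP coupling

Instantaneous phase: a Gaussian frequency-domain weight (σ = bandwidth/4,
default 5 Hz bands) applied to positive frequencies only yields the
analytic signal of the zero-phase narrow-band trace directly; phase is
its angle. PLV is the resultant length of phases at spike samples
(nearest-sample lookup). Maps cover 30–200 Hz in 5 Hz steps (the step
matching the bandwidth) on every channel; units need ≥ 200 spikes (the
resultant is biased upward as ~sqrt(π/4n) at small n). Optional
smoothing averages each value over its 2x2 lattice block (both columns x
two adjacent rows of one shank — the only contiguous 4-neighbourhood on a
two-column lattice). For gamma-band maps the LFP can be decimated (e.g.
to 2 kHz) with an anti-aliased polyphase filter first; PLV is unaffected
since phases vary over tens of samples at these frequencies. The null
floor for an uncoupled unit is the Rayleigh quantile
`sqrt(−ln(α')/n)` with a Šidák-adjusted α' over map cells.

Coherence: channels are Gaussian band-pass filtered (30–90 Hz); each
analysis interval (≥ 2 required, default 100 ripple-centred 1 s windows,
non-overlapping, earliest first) is one estimation segment —
mean-subtracted, Hann-tapered — and cross-/auto-spectra are averaged over
intervals before forming magnitude-squared coherence, which is then
averaged across the band. Self-coherence is identically 1. The coherence
bias for independent signals is ~1/n_intervals (0.01 at 100). Per-
frequency coherence is invariant to the band filter; the band average is
therefore diluted at frequencies where a shared source has no power.

Brain-state splits (running vs immobility) enter as user-supplied
interval masks; state detection is out of scope. All spikes are used for
PLV (no rate-matched subsampling), with subsampling available upstream.

## Pipeline

`run_pipeline` executes enabled stages in dependency order (event
detection → triggered averages/CSD → unit metrics → backpropagation →
coupling maps), writes CSV/HDF5 artifacts and a manifest (package
version, parameter echo, SHA-256 input checksums, per-stage status,
wall time and counts). A failed stage aborts its dependents and is
recorded; independent stages complete. Outputs are deterministic given
inputs and seed; reruns produce byte-identical event tables. Recordings
are flat int16 binary (sample-major frames) with a JSON sidecar declaring
rate, channel count, gain and channel ids.

## Test problem sizes

Recovery suites run on scaled-down lattices (one or two shanks, 16–64
rows) and 20–60 s recordings: the detectors operate on single channels
and the estimators on per-unit footprints, so recovery behaviour is
governed by per-channel SNR and event/spike counts, not by the total
channel count. The full 1024-channel map is exercised by the geometry and
accounting tests.
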