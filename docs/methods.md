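# Methods

This note documents the models, parameter choices and numerical decisions
behind `duomeg`, and what the synthetic validation does and does not
establish about real recordings.

## The measurement model

Two subjects at separate MEG sites perform self-paced, mutually mirrored
finger movements. Three signal families are analysed:

* **3-axis accelerometry** (1 kHz) on each index finger. The movement has
  essentially one mechanical degree of freedom, so the 3-D trace is
  modelled as a 1-D movement waveform projected onto a fixed (unknown)
  orientation vector, plus sensor noise and 50-Hz line pickup. PCA of the
  3×3 axis covariance recovers the projection; PC1 is the movement
  summary. PCA is performed on mean-centred axes by default
  (`pca_reduce(center=...)` makes this explicit and switchable).
* **204-channel planar-gradiometer MEG**, assumed already
  interference-suppressed upstream (signal-space separation is external to
  this package; `GradiometerRecording.sss_applied` records it). Only
  descriptive sensor-space coherence is computed — no source modelling, no
  statistical thresholding.
* **Trigger channels** carrying serially encoded GPS timestamps, used to
  co-register the two sites' free-running sample clocks.

## Behavioral pipeline: parameters and conventions

| stage | parameter | default | rationale |
|---|---|---|---|
| notch | centre, −3 dB width | 50 Hz, 1 Hz | line frequency; width is the per-pass specification (the zero-phase double pass is effectively narrower) |
| low-pass | Chebyshev II order, stopband edge, attenuation | 6, 3 Hz, 30 dB | movement rhythm < 1 Hz; Chebyshev II keeps the passband monotone so waveform shape (and hence zero-crossing timing) is preserved; "3 Hz" is the stopband edge, the natural Chebyshev-II parameter |
| events | — | rising zero crossings of low-passed PC1 | an event fires at the first sample of a non-negative run preceded by a negative sample; a run starting at sample 0 never fires |
| block | length, scan step | 240 s, 0.1 s | earliest window with equal event counts at both sites and all matches valid; deterministic replacement for manual block placement |
| matching | — | greedy nearest-neighbour in time order, ties to the earlier partner event | with equal counts and lags ≪ cycle this coincides with the order-preserving pairing |
| validity | lag bound | ⅓ of local cycle | local cycle = the adjacent inter-event interval; the smaller of the two sites' values is used (conservative) |
| lag sign | — | second site (HUCH role) minus first site (Aalto role) | stated in every report |

Polarity alignment of PC1 across subjects (loadings are defined up to ±1)
is automated: the sign is that of the extremal cross-correlation between
the two low-passed summaries within ±1 s; a degenerate (all-zero)
correlation falls back to +1 with a warning.

**Zero-phase filtering and edge transients.** Both filters are applied
forward and backward (`filtfilt`) with odd-reflection padding. The pad
length is derived from the filter's actual settling length — the
99.9 % impulse-response decay of the slowest pole — rather than the filter
order: a 1-Hz-wide notch at 1 kHz settles over ≈ 2200 samples and the 3-Hz
Chebyshev II over ≈ 2900, so order-based padding would leave multi-second
transients. Transients *at* the trace boundaries are unavoidable for any
finite realization (the padded extension is not the true signal
continuation); they decay within ~3 s of each end, and the analysis block
never needs those regions because recordings are longer than the block.
Filter property tests therefore assert steady-state (interior) behaviour.
Signals shorter than one settling length are rejected explicitly.

The two reported synchrony figures differ on purpose: the across-pair
*mean* of the per-pair mean absolute lag summarizes the cohort, while the
*worst pair's* value is the guaranteed accuracy; reports carry both rather
than conflating them.

## Coherence estimation

Welch magnitude-squared coherence with 8096-sample windows (≈ 8 s at
1 kHz, ≈ 0.12-Hz resolution). The window length is deliberately 8096, not
8192; it is configurable. Taper and overlap are free choices here: Hann
with 50 % overlap (a 4-min block gives 58 overlapped segments), recorded
in every output's metadata. Detrending is constant (per-segment mean
removal) only — the 0.5-Hz lower band edge sits near the segment
fundamental, which linear detrending would distort. Band averaging over
0.5–2 Hz uses inclusive endpoints (bins 5–16, i.e. 12 bins, at the default
resolution).

The 204×204 matrix computes each channel's segment spectra once and forms
all cross-spectra from the cache; this is bit-equivalent (to ≈ 1e-12) to
the naive per-pair estimator, which the tests verify against
`scipy.signal.coherence` on channel subsets. With a single segment the MSC
estimator degenerates to exactly 1, so fewer than two segments is an
error, and the independent-signal bias floor is ≈ 1/K for K effective
segments — visible in all noise-only outputs.

Module topographies average the two gradiometers of each of the 102
Vectorview sensor modules; channel-to-module pairing and the
flattened-helmet layout come from the standard Vectorview gradiometer
layout (via `mne`), or can be supplied explicitly.

## Clock model and timestamp codec

Site clocks are modelled as affine: `t_common = offset + (1 + drift)·n/fs`.
GPS-disciplined clocks drift linearly at the few-minute timescales
involved, so higher-order drift is out of scope. Stamps failing the
checksum are excluded from the least-squares fit, never interpolated; the
fit centres the regressor so hour-scale offsets do not lose precision.

The wire format is this package's own convention (no standard exists):
a 10-sample marker at level 255, 48 payload bits (32-bit seconds, 16-bit
milliseconds, LSB first) and an 8-bit modular checksum, at 5 samples/bit —
290 samples, i.e. < 0.5 s at 1 kHz. Bit cells decode by majority vote with
a uniformity check, so any single corrupted sample inside a codeword flags
that stamp deterministically instead of silently flipping a bit. The
millisecond payload granularity bounds the per-stamp quantization error at
0.5 ms; averaging over ≈ 30 stamps in the fit brings the end-to-end
mapping error well under 1 ms (measured worst case ≈ 0.5 ms over 50 random
offset/drift conditions).

## The synthetic generator

`synthgen` produces pairs with known ground truth, emulating:

* **Quasi-periodic movement**: cycle durations are truncated-normal
  (mean 2.88 s ⇒ 0.35 Hz by default, coefficient of variation 0.15,
  truncated at ±50 % of the mean — the observed bound on cycle
  variability). Each cycle renders one biphasic pulse (a full sine period,
  the derivative of a raised-cosine displacement profile) whose rising
  zero crossing falls exactly on the event; stretched negative half-lobes
  close the trace at both ends so there are no flat noise-only regions
  that would spawn spurious low-pass zero crossings.
* **Follower structure**: subject B's k-th event is A's k-th event plus a
  normal lag (150 ± 40 ms by default — inside the sub-215-ms regime all
  real pairs attained). Configurations whose lag distribution (|mean| +
  4 σ) could breach the ⅓-cycle matching rule are rejected; individual
  draws are additionally clipped at the local bound so the invariant holds
  for every realization.
* **Sensor artefacts**: isotropic Gaussian axis noise (σ 0.05 of the unit
  movement amplitude) and a 50-Hz line component (amplitude 0.1).
* **Movement-locked MEG**: each site's 204 channels carry independent
  unit-variance noise; planted channels add the site's own acceleration
  band-limited to 0.5–2 Hz, scaled to the requested snr. The planted set
  is the ground-truth topography.
* **Site clocks**: trigger channels are laid down under the affine clock
  of the site, with the codeword payload carrying the true GPS time of its
  first sample.

Default recordings last 300 s (the 5-min task) and the analysis selects a
240-s block, mirroring the protocol and keeping the block away from filter
edge-settling regions. A single master seed spawns independent
per-stream substreams, so outputs are bit-reproducible and adding a stream
never perturbs the others.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: waveform shape (the pulse is a smooth stand-in;
real finger accelerations are sharper and asymmetric), amplitude drift and
pauses in task performance, polarity/scale differences between recording
front-ends, movement artefacts bleeding into MEG channels outside the
planted set, spatially correlated MEG noise, and residual environmental
interference. The real-data ingestion path (explicit column mapping)
exists precisely because none of these properties should be assumed.

## Problem sizes used in validation

Synthetic validation runs at the study's native scale: 300-s recordings at
1 kHz, full 204-channel arrays, 8096-sample Welch windows. The lag-recovery
suite uses 20 seeded pairs across follower lags of 50–300 ms (tolerance
±10 ms, comfortably met at ≈ 3 ms worst case); topography recovery uses 10
seeded pairs with 8 planted channels at snr 1 (exact top-8 set match
required); stream alignment uses 50 random clock conditions (residual
bound 1 ms). The nine-pair analysis cohort spans cycle rates 0.17–0.60 Hz.

## Known limitations

* Block selection and polarity alignment are automated, deterministic
  stand-ins for steps that are done by eye in practice; on pathological
  data (long task failures, polarity flips mid-recording) they will refuse
  or mis-resolve rather than emulate human judgement.
* The greedy event matcher assumes the ⅓-cycle regime; with lags
  approaching the cycle duration the pairing problem becomes ambiguous
  and the matcher's choice, while deterministic, is not unique.
* Coherence maps are descriptive; no inferential statistics are attached.
* The trigger codec is an original convention and does not interoperate
  with any existing acquisition software's format.
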