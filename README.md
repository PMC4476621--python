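# duomeg

Analysis pipeline for **dual-site MEG hyperscanning**: two subjects in two
magnetically shielded rooms, kilometres apart, interact over an audiovisual
link while each lies under a 306-channel neuromagnetometer. Validating such
a setup poses three signal-analysis problems, and this package implements
all three, together with a synthetic dual-subject generator so that every
stage is testable without access to original recordings:

1. **Behavioral synchrony** — each subject performs self-paced repetitive
   finger movements while mirroring the partner seen over the video link; a
   3-axis accelerometer on the index finger (1 kHz) quantifies how tightly
   the two movement streams lock together.
2. **Inter-subject sensor coherence** — if the movements synchronize, the
   movement-locked MEG activity of the two brains should be mutually
   coherent at the sensor level; a 204×204 cross-site coherence matrix over
   the planar gradiometers, band-averaged at the movement rhythm, maps
   where on the helmet that coupling lives.
3. **Stream synchronization** — the two sites record on free-running local
   clocks; GPS-derived timestamps serially encoded into a spare trigger
   channel let an affine clock model co-register both recordings on a
   common timeline with sub-millisecond error.

It is written for MEG/EEG methods researchers building or validating
multi-site ("two-person neuroimaging") setups.

## Methods

**Behavioral pipeline.** Per subject: 50-Hz notch (2nd-order IIR, 1-Hz
width at −3 dB, applied forward and backward for zero phase) → PCA of the
three axes, keeping PC1 (the movements have essentially one degree of
freedom) → cross-subject polarity alignment of PC1 (loadings are defined up
to ±1) → 3-Hz low-pass (Chebyshev II, order 6, 30 dB stopband, zero phase)
→ events at rising zero crossings of the low-passed PC1. A continuous
4-minute block in which both sites have equal event counts is selected
(scanned in 0.1-s steps), events are matched to the temporally closest
partner event, and the signed lag of pair *k* is

```
lag_k = t_B,k − t_A,k        (reported in ms)
```

with a pair valid when |lag| is below ⅓ of the local movement-cycle
duration. Summary statistics: median/quartiles of signed lags, mean
absolute lag, cycle durations and rates per subject.

**Coherence.** For channels *i* (site B) and *j* (site A), Welch's method
(8096-sample windows ≈ 8 s at 1 kHz, ≈ 0.12-Hz resolution; Hann taper, 50 %
overlap) estimates the magnitude-squared coherence

```
C_ij(f) = |S_ij(f)|² / (S_ii(f) S_jj(f)) ∈ [0, 1]
```

averaged over 0.5–2 Hz (inclusive). Row/column means of the 204×204 matrix
give each site's per-channel topography; averaging the two gradiometers of
each of the 102 sensor modules gives the flattened-helmet map. Per-channel
segment spectra are computed once and reused — the result is identical to
the naive pairwise computation.

**Clock mapping.** Decoded trigger timestamps (48-bit payload: 32-bit
seconds + 16-bit milliseconds, checksum-protected; see
`duomeg.streamsync`) are fitted by least squares as

```
t_common = offset + (1 + drift) · n / fs
```

and recordings/event times are re-expressed on the common timeline.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
nine-pair cohort spanning movement rates 0.17–0.60 Hz (cohort definition in
`analysis/cohort.py`; `01_simulate.py` writes the raw dataset under
`scratch/`). `python analysis/02_behavior.py` prints:

```
pair   cycles  rate Hz  mean |lag| ms  truth ms  err ms
pair1      94     0.40          123.8     123.1    0.70
pair2      71     0.30          155.6     156.1   -0.51
pair3     138     0.58           71.5      71.4    0.04
pair4     113     0.47          105.8     106.0   -0.21
pair5      54     0.23          181.4     182.8   -1.43
pair6      82     0.35          150.6     149.1    1.44
pair7      39     0.17          196.6     199.5   -2.83
pair8      79     0.33          126.8     127.3   -0.56
pair9      99     0.42          136.3     136.3   -0.00

all pairs mean |lag| <= 197 ms; best pair 71 ms
mean cycles/pair 85.4; cycle rates 0.17-0.58 Hz
worst pipeline-vs-truth lag recovery error 2.83 ms
```

Each row is one subject pair: the number of movement cycles in its
selected 4-min block, the movement rate, the pipeline's mean absolute
inter-site lag, the generator's ground-truth value, and their difference —
the pipeline recovers the planted synchrony to within ~3 ms everywhere.
`03_coherence.py` plants eight coherent gradiometer channels (snr 1) and
recovers exactly those modules as the topography maxima with a 28×
planted-to-background contrast; `04_streamsync.py` sweeps 50 clock
conditions (offsets to 1 h, drifts to 100 ppm) and reports a worst-case
post-alignment residual of 0.500 ms.

Real accelerometer exports can be ingested through an explicit
column-mapping config (`duomeg.io.read_accel_mapped`) — axis order, units
and polarity are declared, never guessed. A `duomeg` CLI exposes
`simulate`, `behavior`, `coherence` and `sync` subcommands.

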