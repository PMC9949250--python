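# Methods

`swrlab` implements the analysis chain used to characterize hippocampal
CA1 recordings around a novel-maze exposure — sharp-wave ripple (SWR)
detection, sleep-state scoring, firing-rate summaries, explained-variance
(EV) reactivation, and Bayesian trajectory-replay classification — together
with a synthetic session generator that provides ground truth for every
stage.  This note records the models, the parameters that matter, the
numerical choices, and what validation on synthetic sessions does and does
not establish.

## Session model and time base

All timestamps are seconds (float64) from session start; intervals are
half-open `[start, stop)` so that partitions are exact.  A session holds
per-unit spike trains, multichannel LFP at the 1250 Hz analysis rate,
a position trace, and a block schedule (PRE ≈ 2.5 h rest, MAZE ≈ 1 h
linear-track running, POST).  POST is split into consecutive 2.5 h blocks:
NS1, NS2, … for naturally sleeping (NSD) sessions; SD1, SD2 during the 5 h
enforced-wakefulness period and RS (recovery sleep) afterwards for
sleep-deprived (SD) sessions.  A trailing partial block is kept and
flagged.  Zeitgeber time 0 is stored as an offset and coincides with POST
onset in synthetic sessions.

Animal speed is derived by central differences on a uniform grid at the
native position rate, then Gaussian-smoothed (σ = 0.25 s).  The speed
estimator is a package choice; the width trades lag against jitter at the
60–120 Hz sampling rates typical of tracking systems.

## Sharp-wave ripple detection

One channel per shank is selected by highest mean 125–250 Hz power.  The
per-channel magnitude of the analytic signal in that band (4th-order
Butterworth, zero-phase forward–backward) is averaged across selected
channels, Gaussian-smoothed (σ = 12.5 ms), and z-scored against the whole
recording.  Events require a peak above 2.5 s.d., extend to the 0.5 s.d.
crossings, merge across gaps < 30 ms, and must last 50–450 ms.

Numerical notes:

- The z-scoring baseline is the whole recording, not per-state, so block
  comparisons share one scale and detection runs before sleep scoring.
- On a *purely Gaussian* background the 2.5 s.d. threshold yields noise
  crossings at a nontrivial rate; detection is precise in practice because
  real (and synthetic) sessions contain events at high amplitude and duty
  cycle, which inflate the session s.d. and push the effective threshold
  far into the background tail.  This is a property of the published
  thresholding scheme, not of this implementation.
- Sharp-wave amplitude is max-minus-min of the 2–30 Hz band-passed LFP over
  *all* channels within the event, reported in mV.  The band-pass is
  evaluated on a 10-fold decimated copy (content is far below the reduced
  Nyquist).  The measure includes whatever low-frequency background falls
  inside the event window; on quiet backgrounds it recovers injected
  peak-to-trough amplitudes within a few percent.
- Peak ripple frequency uses complex Morlet wavelets (7 cycles) on a 2 Hz
  grid over 100–250 Hz after a > 100 Hz high-pass; per event the grid
  frequency with the largest integrated |response|² wins.  Wavelets are
  normalized to unit response at their centre frequency; an energy
  normalization would bias tone estimates a few Hz downward because
  bandwidth grows with frequency.

Population bursts: all-unit counts in 1 ms bins, Gaussian-smoothed
(σ = 20 ms), z-scored over the recording; peak > 3 s.d., boundaries at the
mean crossing, events within 10 ms merged, duration 80–500 ms.

## Sleep scoring

Wake vs sleep comes from a "correlation EMG": the sum over channel pairs of
Pearson correlations of > 300 Hz high-passed signals in 10 s windows
stepped 1 s.  Muscle artifact is broadband and shared across the array, so
wake windows are strongly correlated while sleep windows hover near zero.
A two-component Gaussian mixture (quantile-initialized, deterministic)
separates the two; if the mixture is effectively unimodal (component means
closer than 2.5 pooled s.d.) the session is treated as all-wake or
all-sleep using the absolute scale of the summed correlation (threshold
0.5), which is meaningful because independent channels sum to ≈ 0.

Within sleep, REM vs NREM — and within wake, active vs quiet — come from
the log theta ratio (5–10 Hz power over (1–4) + (10–14) Hz power, periodogram
per window) smoothed by a two-state Gaussian-emission chain with sticky
transitions (self-transition 0.99) and Viterbi decoding; emission
parameters come from the same deterministic mixture machinery.  A 10 s
minimum state duration replaces manual inspection; an override table can be
supplied through the CLI.  For a flat spectrum the theta ratio tends to the
bandwidth ratio 5/7 under this band convention.

## Firing dynamics

Stability: the session is cut into 5 equal bins and a unit is kept only if
every bin's rate reaches 25% of its overall mean; zero-spike units fail
(otherwise 0 ≥ 0 would retain them vacuously).  Putative classification
uses trough-to-peak width on the largest-amplitude channel (PN ≥ 0.4 ms
with rate < 5 Hz; IN < 0.4 ms with rate > 10 Hz), with the fraction of
inter-spike intervals below 10 ms breaking ties towards PN for broad,
bursty, sub-10 Hz units.  The width and rate cut-offs are package defaults;
the literature names the features but not single values.

## Explained-variance reactivation

Spike counts of stable putative pyramidal cells in 250 ms bins give, per
15 min window (5 min step), a vector of pairwise Pearson correlations over
admissible pairs (same-shank pairs with waveform similarity ≥ 0.8 are
excluded; similarity is the peak normalized cross-correlation of mean
waveforms over shared channels and is defined 0 across shanks).  With
R[A,B] the correlation between two such vectors, EV for POST window WIN
given PRE window k is the squared partial correlation of MAZE and WIN
controlling PRE(k), and REV swaps the roles of PRE(k) and WIN; both are
averaged over PRE windows.  Missing pair entries (zero count variance in a
window) are dropped pairwise-complete per evaluation, with at least 10
complete pairs required; degenerate windows (|R| = 1) are skipped.

The reactivation timescale is the half-maximum lag of the EV series'
autocorrelation, computed **without mean subtraction** and normalized at
lag 0, with linear interpolation between lags.  The mean-subtracted ACF of
a monotonically decaying trace saturates near one sixth of the series span
regardless of the decay constant, which cannot produce multi-hour
timescales from a 9 h POST; the raw normalization is the only convention
under which such values are attainable, and it reduces to the same answer
as the standard ACF for stationary zero-mean series (an AR(1) with
coefficient φ crosses one half at log 0.5 / log φ lags).  Constant or empty
series are returned censored at the series span.

## Bayesian decoding and trajectory replay

Rate maps: per running direction, Gaussian-smoothed (σ = 4 cm) spike counts
divided by equally smoothed occupancy in 2 cm bins, using samples above
8 cm/s; both numerator and denominator are smoothed before division.  Bins
with raw occupancy under 0.1 s are zeroed — near the reward wells the
animal is below the speed threshold and the count/occupancy ratio in
barely-sampled bins is unstable, which otherwise plants spurious
high-rate islands at the track ends that attract the decoder.  Units whose
peak over both directions is below 0.5 Hz are excluded from decoding; all
stable units passing that floor participate regardless of putative type
(flat interneuron maps are effectively neutral in the likelihood).

Candidate events (population bursts) require ≥ 5 active included units,
mean interpolated speed < 8 cm/s, and peak ripple-envelope z > 1 during
the event.  Decoding evaluates, per 20 ms bin with counts nᵢ,

    P(x | n) ∝ ∏ᵢ λᵢ[x]^{nᵢ} · exp(−τ Σᵢ λᵢ[x])

in log space (rates floored at 0.01 Hz inside the log only), normalized per
bin.  The two directional maps are concatenated as 2 × n_bins states; the
decoded location is the arc-length of the winning state (ties to the lowest
index) and jumps are measured on arc-length regardless of direction state.

Replay rule: a candidate is a trajectory replay iff its decoded path
contains ≥ 4 consecutive spike-occupied bins (three adjacent jumps,
spanning 80 ms) whose jumps are all < 40 cm and whose net traversal within
some qualifying window reaches ≥ 35 cm.  Two choices here are deliberate:

- "at least three consecutive time bins" is read as three consecutive
  *jumps* (4 bins).  With the two-jump reading, the chance rate of the rule
  on a 200 cm track is enormous: ~36% of independent position pairs lie
  within 40 cm, so 5–7-bin events pass by chance roughly half the time.
- the traversal clause implements "a continuous trajectory *across space*":
  a decoded point parked in one location (for example when one cell
  dominates several bins) is not a trajectory.  Without it, stationary
  decodes pass the jump rule trivially.

With these settings, embedded fidelity-1.0 replays are recovered at
0.8–0.95 sensitivity (depending on the generator seed) while per-event
identity shuffles pass at ≤ 0.1 (three seeds × 200 events), and the rule
agrees exactly with an exhaustive run-scan oracle.

## The synthetic session generator

The generator is first-class, tested code; its defaults are the study
conditions and every draw comes from a named substream of one seed, so
sessions are byte-reproducible and adding draws to one component does not
perturb another.

**Behaviour.** Back-and-forth traversals at 50 cm/s on a 200 cm track with
12 cm acceleration/deceleration ramps and ~10 s reward-well pauses; home-cage
epochs are a jittering stationary point.  The ramps matter: with
instantaneous stops, the smoothed speed estimate bleeds stationary
(SWR-rich) well time into the > 8 cm/s samples and corrupts rate-map end
bins.

**States.** NSD: rodent-like cycling (brief quiet wake, 5–10 min NREM,
1–3 min REM) giving ≥ 80% sleep in POST.  SD: alternating active/quiet
enforced wake for 5 h, then the same sleep cycling.

**SWRs.** A renewal process per permissive state segment (NREM 0.75/s,
quiet wake 0.85/s; dead time 0.35 s plus an exponential gap whose mean is
reduced so the realized rate matches the nominal one).  Per event, a
ripple frequency and sharp-wave amplitude are drawn around per-block
medians that echo the recorded ranges (ripple ~150–171 Hz, sharp waves
~4.1–5.1 mV), and a target envelope z is drawn log-normally (median 5).
Ripple tones are placed on the pyramidal-layer channel of each shank and
sharp waves across all channels with polarity flipping from superficial to
deep.  Because the detection z-score is self-normalizing, target z values
are calibrated in two stages: a closed-form model of the smoothed envelope
of a Hann tone over the noise floor, then one empirical correction pass
through the actual detection path.  At a realistic duty cycle the
*population* of amplitudes fixes the session s.d., so the realized median z
sits slightly below an ambitious target — which is exactly the regime the
published thresholds operate in.

**Spikes.** Inhomogeneous Poisson throughout: log-normal baseline rates
(PN median 0.5 Hz, IN 15 Hz) with mild state factors; place-tuned maze
firing by thinning against Gaussian tuning curves (σ = 10 cm, log-normal
peaks, per-unit direction preference, stratified-uniform centres so the
population's summed rate is flat — iid centres leave seed-dependent valleys
that bias the decoder's occupancy term); an additive within-SWR response
(+1.5 Hz for PN with sparse 35% per-event participation, +30 Hz for IN),
chosen additive-uniform deliberately: a multiplicative gain imprints a
rate-product covariance pattern on every pair, shared between MAZE and
POST, which the PRE-partialing of EV cannot remove and which floors EV
permanently.

**Replay content.** A scheduled fraction of post-maze SWRs (never PRE:
the animal has not seen the track yet) contains a time-compressed sweep:
a start position and direction are drawn, the trajectory covers half the
track at 15× run speed, covered units participate with probability 0.4 and
emit ~2 spikes around their crossing time; spike-time jitter scales with
(1 − fidelity).  Baseline spikes of non-participating pyramidal cells are
suppressed (80%) inside replay events — sharp-wave bursts recruit a
specific assembly while others fall silent — which is what makes the
events decodable without inflating pairwise co-firing.  In SD sessions the
replay fraction during deprivation and recovery sleep is scaled by 0.55.

**Reactivation.** Pyramidal cells are grouped by adjacent place-field
centres into ensembles of 5.  In POST, each ensemble co-fires in 250 ms
bins with probability q₀ · strength · exp(−t/τ_lat); members emit ~0.8
extra spikes per active bin.  In SD sessions the probability is scaled to
0.12 × strength during enforced wake and rebounds to 0.6 × strength at
recovery-sleep onset.  The latent decay τ_lat is calibrated
(`REACT_DECAY_CALIBRATION = 0.40` applied to 2·react_tau/ln 2) so that
`react_tau` *is* the timescale the EV autocorrelation half-max reports at
the default operating point: the EV measure saturates mildly (the
across-pair correlation stays near its ceiling until the within-ensemble
signal sinks to pair-sampling noise), so the latent must decay faster than
the naively derived constant.  The calibration was fixed by measuring the
generator→estimator response surface across τ ∈ {1, 2.5, 4} h and POST
spans of 9–12 h, and holds across that range to within ~10%.

## Validation scales and what they show

The validation suite runs entirely on synthetic sessions, at these sizes:
ripple detection on a 1 h, 8-channel fixture with 200 scheduled events at
≥ 4 session-s.d. envelope power; τ recovery on 9 h-POST spikes-only
sessions with 80 pyramidal cells (5 seeds × 3 τ values, with replays
disabled to isolate the pairwise channel); replay operating characteristics
on 200 embedded events per session across 3 seeds; sleep scoring on five
~1.4 h sessions; and the NSD-vs-SD contrast on two full 12 h sessions with
4 LFP channels.  Passing these shows the *implementation* recovers what the
generator planted under the stated conditions.  It does not certify
performance on real recordings, where waveform drift, non-Poisson spiking,
theta sequences, movement artifacts, and non-stationary backgrounds all
exist and are deliberately absent from the generator.  Two known gaps are
documented rather than hidden: absolute EV−REV levels in full synthetic
sessions run above the recorded ranges (the replay channel built for
decoder validation contributes persistent pairwise correlation), so the
meaningful pipeline outputs at session scale are the block *contrasts* and
orderings; and awake "active" bouts shorter than the 10 s scoring window
(maze runs) are unresolvable by construction.

## Known limitations

- No theta-sequence generation during running; no current-source-density
  or phase analyses; no forward/reverse replay labelling.
- The EV time constant of full sessions (replays on) overestimates the
  configured reactivation decay because the replay channel does not decay;
  the recovery experiment therefore runs with replays off.
- Interneurons are a single homogeneous class.
- Bundle LFP is stored as int16 with a per-bundle scale, so save/load
  round-trips are exact only to one quantization step.
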