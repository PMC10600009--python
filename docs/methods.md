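# Methods

## Scope and data flow

The package analyses context-dependent song sequencing in *Drosophila*
courtship on synthetic data that emulates free male–female recordings.
The stages are: synthetic-data generation → song annotation and
behavioral statistics → spiking circuit simulation and decoding →
genetic-algorithm fitting and knockout comparison → history-filter GLMs
and the tap-derived P1a rate. All times are float seconds on one clock;
intervals are half-open `[start, end)`.

## Annotation conventions

- **Noise and sine amplitude.** The multi-microphone noise snippet is
  reduced to one dimension by taking the loudest (largest |x|) channel
  per time point; the noise amplitude is the 99th percentile of the
  absolute values (numpy linear interpolation between order statistics).
  Sine-train amplitudes use the same statistic, so the SNR of a sine
  train is amplitude / noise amplitude.
- **Boundary rules are strict**, matching "below" wording: SNR < 1.3
  excludes the whole bout; an inter-bout gap < 0.5 s merges; mean
  mfDist < 4 mm is "near" (exactly 4 mm is "far").
- **Labels** collapse adjacent same-mode trains (merging can create
  them); a label of length 1 is simple, otherwise complex, and the
  six-type form distinguishes one alternation ('ps'/'sp') from two or
  more ('psp...'/'sps...').
- **Tap rates**: R_during = n_during/B over the bout of duration B and
  R_before over the equally sized preceding window; when that window
  starts before the recording, the result is flagged truncated rather
  than rescaled. Averages are means per category over pulse-leading
  bouts.

## Circuit model

Four Izhikevich neurons with conductance inputs:

    dv/dt = 0.04 v² + 5 v + 140 − u + I + g_e/τ_e + g_i/τ_i
    du/dt = a (b v − u),  dg/dt = −g/τ

spike at v ≥ 30 mV, then v ← c, u ← u + d. Presynaptic spikes increment
the postsynaptic conductance by the synaptic weight (negative for
inhibition, so g_i ≤ 0). Connectivity: mutual inhibition p↔s, inh→p,
inh→s, pC2→inh (all inhibitory, weight w_i, τ_i), and one excitatory
synapse pC2→p (w_e, τ_e). pC2 receives the distance drive
I_e·α/(1+exp(−β(x₀−mfDist))); inh receives I_tonic; p and s receive no
external current — sine song arises purely from post-inhibitory rebound.

Parameter choices (all configurable):

- **Regimes.** pC2 and inh use the canonical tonic preset
  (a, b, c, d) = (0.02, 0.2, −65, 6). The song nodes use a rebound-burst
  preset (0.005, 0.25, −52, 0): b = 0.25 gives rebound excitability,
  d = 0 lets a release event trigger a burst rather than a lone spike,
  and the recovery timescale a = 0.005/ms slows the burst/pause cycle to
  the few-hundred-millisecond scale of song trains. With the textbook
  value a = 0.03 the half-center alternates at ~150 ms, which the 300-ms
  decoding rule cannot resolve into 'psp...' labels — the slower recovery
  is what makes the alternation observable at the decoding timescale.
- **Synaptic time constants** τ_e = 5 ms, τ_i = 40 ms. The slower
  inhibition sustains the suppression episodes that separate alternating
  trains.
- **Distance nonlinearity** α = 1, β = 3 mm⁻¹, x₀ = 4 mm, aligning the
  drive midpoint with the behavioral far/near threshold. The steepness
  was chosen during circuit calibration so that the complex/simple
  transition distance stays below 4 mm across the whole fitted range of
  the gain I_e (with a shallower sigmoid, a high-gain fit can alternate
  above the threshold and misplace complex bouts into the far context);
  the trade-off is that drive decays quickly beyond ~4.5 mm, confining
  model far song to a band near the threshold.
- **Free parameters** (the only ones the GA fits): I_e = 35,
  I_tonic = 13, w_e = 21, w_i = 19 at the reference operating point,
  found by a one-time numerical search for the qualitative regime
  behavior — constant mfDist ≥ 4 mm gives pure simple-pulse output and
  sine silence, constant 1.5 mm gives sustained 'psps...' alternation,
  with the transition near 3.8 mm.
- **Integration**: forward Euler at dt = 0.1 ms, synchronous conductance
  updates after the membrane step. Initial conditions are the stable
  zero-input fixed point of each cell (v from the quadratic nullcline
  intersection, u = b·v, g = 0); the reset potential of the rebound-burst
  preset lies above rest, so initializing at v = c would fire every song
  node spuriously at t = 0. Divergence (|v| > 1e8) raises an error
  naming dt.
- **Convergence.** On the far-context reference scenario (periodic
  tonic firing) halving dt changes total spike counts by well under 2%.
  In the near-context bursting regime individual spike counts are more
  dt-sensitive (the half-center phase is chaotic-adjacent), while the
  decoded labels are robust; the convergence property is therefore
  asserted on the periodic scenario.
- **Decoding**: within-node spikes with ISI ≤ 300 ms form a train;
  trains whose gap to the ongoing bout is < 300 ms merge into it
  (overlapping trains always merge); a train at least 300 ms from the
  other node's activity stands alone as a simple bout. The
  train-grouping gap and the alternation window share the single 300-ms
  constant. No bout-duration mechanism is modelled.

Knockout variants: `no_rebound_p` / `no_rebound_s` / `no_rebound` switch
the song node(s) to the tonic preset; `no_disinhibition` removes inh→p
and inh→s; `exc_modulation` turns every synapse into or out of inh
excitatory (weight class w_e, τ_e) and removes its tonic input.

## Genetic algorithm

Real-coded GA over (I_e, I_tonic, w_e, w_i) with bounds I_e ∈ [1, 50],
I_tonic ∈ [0, 20], w_e, w_i ∈ [0.5, 30]; population 32, 40 generations,
elitism 1, tournament selection (size 3), blend crossover with
probability 0.5, per-gene Gaussian mutation (probability 0.1, SD 15% of
the bound range), and 2 random immigrants per generation to prevent
population collapse onto silent models. Each evaluation simulates the
candidate on the snippet's mfDist, decodes bouts, and scores
RMSD(six-type frequencies) + 0.1·|Δn_bout|; a simulation that produces
no song scores with all-zero frequencies. Evaluations are cached by the
parameter vector rounded to 1e-6, and replicate fits derive independent
seeds from the base seed and their (variant, snippet) indices, so
results do not depend on evaluation order. Snippet selection draws
uniform windows until the within-window bout set has the required far
fraction (400-s windows for headline fits, 200-s or shorter for the
knockout comparison), with a bounded retry count.

Problem sizes: the self-recovery and knockout analyses use 100–200-s
snippets and reduced GA budgets (e.g. population 16, 14 generations for
the five-replicate variant comparison); these sizes reproduce the
qualitative ordering stably and keep a full run on one CPU in minutes.

## GLM

Features are smoothed with a centered 20-frame moving average (shrinking
windows at the edges). For every pulse-leading bout, 21 uniform samples
per feature are taken over the 5 s up to the end of the first pulse
train; columns are z-scored over the extracted rows. One logistic GLM
per feature maps its 21-tap history to P(complex); the sparse prior is
realized as an L1 penalty, with the data term normalized by the row
count so the penalty strength C is per-sample (fits are invariant to
duplicating rows). C is chosen by 5-fold stratified cross-validated log
loss over a fixed grid, re-selected within each resample. Predictive
power is the relative deviance reduction (null − model)/null on the
fitted rows, clipped to [0, 1]. Robustness: 51 refits on random 70%
row subsets without replacement, summarized by mean and mean absolute
deviation.

The tap-derived P1a rate convolves the binary tap train with a
tap-triggered calcium kernel (peak-normalized double exponential,
0.2-s rise, 2-s decay — a configurable stand-in for the unpublished
tap-triggered average) and deconvolves with the GCaMP6s kernel
exp(−t/2.6 s) by Fourier division with a Tikhonov floor (1e-6 of the
peak spectral power). With matching kernels the round trip recovers the
tap train to < 1% energy error; larger regularization trades recovery
sharpness for noise robustness.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis relies
on, not the physics of a fly pair:

- mfDist follows a reflected OU process on log-distance (τ = 15 s,
  σ = 0.26, mean 4.2 mm, chamber bounds [0.5, 30] mm), producing
  multi-second dwell epochs on both sides of the 4-mm threshold; other
  kinematic features are independent OU noise with plausible scales —
  they carry no song information by construction.
- Bout onsets are a thinned Poisson process (0.35/s near, 0.15/s far);
  the type at onset follows a multinomial logit in distance whose
  coefficients were calibrated once (scripts/calibrate_synth.py) so the
  annotated data show > 95% simple pulse far, ~55% simple pulse and
  ~30% complex 'ps...' near; simple bouts are lognormal with mean
  ~0.7 s, complex ~2.2 s with a geometric number of alternations
  (p = 0.45).
- Sine SNRs are lognormal (μ = 1.1, σ = 0.5 in log units) against a
  noise segment normalized to unit noise amplitude, so ~5% of sine bouts
  fall below the 1.3 SNR threshold.
- Taps are per-frame Bernoulli with rate 0.05 + 0.4·[near] +
  0.6·[inside a complex bout] taps/s.
- Optogenetic sessions tile 8-s trials (1/8 Hz) into 120-s blocks of the
  pooled 16-block factorial protocol; a responder maps irradiance × duty
  to probabilities of a stimulus-locked pulse train and a post-offset
  rebound sine.

Passing tests on these data show that the pipeline computes its
statistics correctly and that the model/fit/GLM machinery behaves as
designed under the assumed structure; they cannot show robustness to
tracking errors, segmentation artifacts beyond the modelled bout
splitting, non-stationary behavior, or correlated kinematic features as
in real recordings.

A single integer seed expands into independent substreams per stage
(trajectory, song, taps, opto), so regenerating one stream never
perturbs another.

## Known limitations

- The circuit has no bout-termination mechanism and no spike-frequency
  adaptation; under constant near-context drive it alternates
  indefinitely, so bout counts under naturalistic input are driven by
  the distance fluctuations.
- In this parameterization, knocking out pulse rebound (switching the
  pulse node to the tonic preset) abolishes complex song entirely:
  decodable alternation requires the pulse node to pause for at least
  300 ms, and a tonic cell under sustained excitatory drive only pauses
  under sustained inhibition that the excitation-free sine node cannot
  both deliver and self-terminate. Extensive parameter probes (hundreds
  of random free-parameter draws, and alternative rebound presets that
  still pass the regime checks) found no alternating operating point for
  this variant, so its fit error matches the sine-rebound knockout
  instead of staying close to the full model. The variant-comparison
  test records the biological expectation that pulse-rebound loss is
  comparatively benign, and that check currently fails by design of the
  presets rather than of the optimizer.
- GA fits on near-rich snippets at desk-scale budgets occasionally land
  in the all-pulse corner; the knockout ordering is asserted on medians
  over replicate fits for this reason.
- The per-feature GLM ranking ignores correlations between features; a
  joint model would attribute shared variance differently.
- The deconvolution assumes the indicator kernel exactly; kernel
  mismatch biases the recovered rate amplitude (not its timing).
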