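# Methods

## The model

Synaptic short-term plasticity is described with the Tsodyks–Markram
phenomenological model. Two presynaptic state variables evolve between
action potentials,

    dR/dt = (1 − R)/D        (resources recover toward 1)
    du/dt = (U − u)/F        (release probability decays toward baseline U)

and jump at each spike: the spike releases `u·R` of the resources
(`R ← R − uR`) and increments the running release probability by
`u ← u + f(1 − u)`. The postsynaptic potential evoked by spike *n* is

    PSP_n = A · R_n · u_n

with an amplitude factor `A` (mV) absorbing release-site count, receptor
properties and cable filtering. The initial state is `R = 1, u = U`
(synapse not recently active), so the first response is always `A·U` and
the facilitation increment of a spike affects only later spikes. Where a
published transcription of the between-spike update for `u` omits the
`−U` inside the decaying term, we use the form consistent with the ODE
above and with the stated initial condition:

    R_{n+1} = 1 − (1 − R_n(1 − u_n)) · exp(−Δt_n/D)
    u_{n+1} = U + (u_n + f(1 − u_n) − U) · exp(−Δt_n/F)

Three nested variants are fitted: `DEP2` (depression only, `u ≡ U`;
parameters D, U), `FAC3` (facilitation with the increment tied to
baseline, `f = U`; D, F, U) and `FULL4` (D, F, U, f). The event-driven
recursion is exact between spikes; a deliberately naive explicit-Euler
integrator of the ODEs (`simulate_ode_oracle`) is kept in the package
purely as an independent numerical cross-check and agrees with the
recursion to better than 1e−3 relative at a 10 µs step.

Parameters outside their domains raise immediately; nothing is clamped,
so the inference always sees hard boundaries.

## Synthetic recordings

No recordings ship with the package; the generator emulates the
experimental design so every analysis runs end to end on known ground
truth.

* **Population.** `U` is broad (uniform on [0.05, 0.9]); `D` and `F`
  are tight log-normals (medians 0.15 s and 0.20 s, geometric SD 1.3 —
  a "tight" spread under the ≤1.5 ceiling we consider realistic);
  `A` uniform on [1, 5] mV. The broad-U/tight-time-constant structure is
  the regime in which release probability drives plasticity heterogeneity.
* **Protocols.** Fixed-frequency: 5 pulses at 2/5/10/20/30/40/50 Hz,
  default 20 repeats (the experimental range is 10–25), 20 s between
  trains. Poisson validation trains: 20 pulses at a 5 Hz mean rate,
  30 repeats, with exponential inter-pulse intervals floored at 5 ms
  (stimulators cannot overlap pulses); one pseudo-random train is drawn
  per protocol and replayed on every repeat, so trial-mean amplitudes are
  well defined.
* **Trial noise.** Multiplicative Gaussian with CV 0.15 (a configurable
  guess — trial-level variability is not reported for the real data),
  floored at 1% of the true amplitude so measurements stay positive
  without rejection sampling. Trains are independent: 20 s exceeds
  ~100 time constants, so the synapse fully recovers between repeats.
* **Voltage traces.** Each pulse contributes its amplitude times a
  peak-normalized difference-of-exponentials kernel (default 3 ms rise,
  80 ms decay — EPSP-like, chosen so 20–30 Hz trains visibly summate)
  delayed by a 1.5 ms synaptic latency; responses sum linearly and white
  noise is added. The generator does not model stimulus artifacts,
  optogenetic kinetics, receptor desensitization or network effects, so
  passing measurement tests demonstrates correctness of the summation
  correction, not robustness to those real-data features.
* **Multi-input datasets.** Several stimulation sites per cell (3–6,
  "several positions" in a slice), 5 pulses at 30 Hz × 20 repeats each.
  `u_mode="cell"` (default) draws one U per cell shared by its inputs —
  the cell-level regulation of release probability that the multi-input
  experiment is designed to detect; `u_mode="input"` draws U per input,
  making inputs exchangeable across cells, which is the correct null for
  calibrating the shuffle test. Facilitating cells draw U from
  [0.03, 0.12].

All randomness flows from explicit integer seeds (spawned via
`numpy.random.SeedSequence`); every generated dataset is reproducible
bit for bit.

## Amplitude measurement

`measure_onset_to_peak` reads the baseline at a fixed 1.5 ms
post-stimulus latency and takes the extremum within a window (default
30 ms, never exceeding the inter-stimulus interval), sign-folded so
EPSPs and IPSPs are both positive. On summating trains this
underestimates later amplitudes. `measure_exp_corrected` fits a single
decaying exponential between the previous response's peak and the next
stimulus, extrapolates it under the next response and measures the peak
against that baseline; a non-decaying segment falls back to
onset-to-peak with a logged warning. A fixed-latency onset was chosen
over derivative thresholding because it is robust on noisy synthetic
traces. On noise-free summating depressing trains the correction raises
the PPR by roughly 10% toward the ground truth, mirroring the direction
and magnitude of the experimentally reported underestimation.

## Plasticity metrics and QC

PPR = pulse-2/pulse-1 amplitude, computed across trials as the ratio of
trial means (equivalent to measuring the average trace). STD index =
mean(pulses 3–5)/pulse 1; below 1 is depressing, above 1 facilitating,
and the measure-zero tie at exactly 1 is classified depressing.
Downstream statistics always use log PPR / log STD index. QC excludes
recordings with membrane-potential drift > 8 mV, input-resistance change
> 30% or amplitude change > 30% (strict inequalities, exactly as
stated). Connection probability is 100·connected/tested (full precision
internally, integer percent for display) and path strength is the
product of mean amplitude magnitude (mV) and connection probability (%).

## Bayesian fitting

The likelihood treats each trial's per-pulse amplitude as independent
Gaussian around the variant's noise-free prediction with standard
deviation `σ·prediction` — multiplicative noise matching the generator,
which makes parameter recovery a fair test; the real data's likelihood
is unknown. `σ` (a dimensionless CV) is inferred jointly, which also
supplies the scale for standardized residuals downstream. Priors are
uniform in natural space within explicit bounds (U, f on (0.001, 0.999);
D, F on [0.005, 5] s; A up to 10× the largest observed amplitude; σ up
to 5× the observed CV with a 1e−3 floor); sampling runs in log/logit
coordinates with the Jacobian correction. The sampler is the
affine-invariant ensemble (emcee), 32 walkers × 2000 steps with 50%
burn-in by default, started in a tight ball around the best of 256
prior draws. `FAC3` ties `f = U` inside the sampler; `DEP2` samples only
(D, U, A, σ). Point estimates are posterior medians (robust to the
skewed time-constant posteriors). Split-R̂ and effective sample size are
computed on four pseudo-chains formed by grouping the walkers (ensemble
walkers are not independent chains, so walker-wise R̂ is biased high);
any R̂ > 1.05 flags the fit as unconverged — flagged, never silently
accepted, and the pipeline exits nonzero unless overridden.

## Model selection and validation

Variants are compared with `AIC = 2k + n·ln(SSe/n)`, where `k` counts
only the named model parameters (2, 3, 4) — A and σ are common to all
variants so rankings are unaffected — and `n` is the number of fitted
observations (trials × pulses). Akaike weights are normalized relative
likelihoods `exp(−ΔAIC/2)`. R², RMS error, the per-pulse fractional
error `(obs − pred)/obs`, and a one-sample KS test of standardized
residuals `(obs − pred)/(σ̂·pred)` against the standard normal complete
the metric set; the comparison distribution for the KS test is a
documented choice isolated behind one function. Validation predicts the
held-out Poisson trains at the training point estimate without
refitting, after QC filtering, comparing trial-mean amplitudes (the KS
standardization then uses `σ̂/√n_trials`). `select_model` reports both
the training ranking (mean Akaike weight) and the validation ranking
(mean R²) and flags disagreement rather than resolving it.

## Population tests

Each cell's input log PPRs are compared to all other cells' inputs
(cell excluded, avoiding self-contamination) with a one-tailed Welch
t-test, alternative "cell facilitates more", α = 0.05; a one-sample
variant against the grand mean is provided as the alternative reading.
The shuffle test permutes the pooled input log PPRs across cells,
preserving per-cell input counts, and reports the fraction of shuffles
whose count of significant cells reaches the observed count, floored at
1/n_shuffles so a zero count reports an upper bound rather than zero.

Because the count statistic is a small integer, its raw permutation
p-value is discrete with an atom at 1 (P(count = 0) ≈ 0.6 under the
null), so a KS test of raw p against the continuous uniform rejects for
*any* valid permutation test. Calibration is therefore assessed with
the standard randomized probability integral transform,
`p_rand = P(count > obs) + V·P(count = obs)` with `V ~ Uniform(0,1)`,
which is uniform exactly when the test is calibrated; the raw p's
defining validity bound `P(p ≤ α) ≤ α` is asserted alongside.

## Problem sizes and numerical choices

The shipped analyses use 20-cell populations for recovery and
correlation, 10 replicates of 3-cell populations (16 walkers × 800
steps) for variant identification, 100 null replicates × 2000 shuffles
for calibration and 10 replicates × 100,000 shuffles for power — sizes
we consider sufficient for stable Monte-Carlo estimates of each
quantity. Exponential-fit failures in the summation correction fall
back gracefully; degenerate inputs (constant observations, zero
variance in both t-test groups, constant U across cells) raise typed
errors rather than returning misleading zeros.

## Known limitations

* The original study's priors, likelihood and sampler are delegated to
  an external codebase and are not reproduced; the choices above are
  documented substitutes.
* Dataset-level numbers from the real recordings (per-dataset metric
  means, the reported correlation magnitude) are not reproducible
  without those recordings; the synthetic analyses reproduce directions
  and orderings, not printed dataset values.
* The generator's noise model is multiplicative Gaussian; real trial
  variability includes release stochasticity (binomial), drift and
  recording noise that are not modelled.
* With cell-level U and a broad background, ~20% of multi-input
  datasets draw enough moderately facilitating background cells that
  the shuffle test's empirical p for two planted facilitating cells
  lands between 1e−3 and 1e−2 rather than below 1e−3; the median
  replicate is far below 1e−3.
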