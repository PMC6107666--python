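# Methods

`causaldecomp` implements a prediction-free causality measure for pairs of
uniformly sampled time series. Instead of asking whether one series helps
*predict* the other, it asks whether the instantaneous phase dependency
between the two collapses when the causally related oscillatory component is
removed from one of them — the covariation reading of causality: cause is
that which put, the effect follows; and removed, the effect is removed.

## Pipeline

1. **Decomposition.** Each series is decomposed into intrinsic mode
   functions (IMFs) by ensemble empirical mode decomposition (EEMD). Plain
   EMD sifts a signal by fitting natural cubic splines through its local
   maxima and minima, subtracting the mean envelope, and repeating; each
   extracted IMF is a narrow-band amplitude/frequency-modulated component,
   ordered fine to coarse, with a residual trend. EEMD decomposes many
   white-noise-perturbed copies of the signal and averages the IMFs
   index-wise; the added noise (amplitude `r`, a fraction of the signal's
   standard deviation) provides a uniform dyadic reference frame so that
   comparable scales land at equal indices across series.
2. **Phase coherence.** For each index-matched IMF pair, the instantaneous
   phase φ(t) comes from the discrete analytic signal (Hilbert transform);
   the coherence is the modulus of the time-averaged unit phasor of the
   phase difference, Coh = |⟨e^{iΔφ(t)}⟩| ∈ [0, 1]. It is 1 for phase-locked
   components at any fixed offset (hence insensitive to pure lag) and small
   for wandering phase differences. Amplitudes never enter.
3. **Remove and redecompose.** To probe direction at scale *i*, IMF *i* is
   subtracted from one series, the remainder is redecomposed with the same
   `r`, ensemble size and component count, and the coherence profile is
   recomputed against the *original* decomposition of the partner. The
   profile change is summarised by the variance-weighted Euclidean distance
   D over all paired indices, with weights W_j ∝ Var₁ⱼ·Var₂ⱼ (normalised to
   1). Doing this in both directions gives D(a→b), D(b→a), and the relative
   causal strength C(a→b) = D(a→b)/(D(a→b)+D(b→a)); C = 0.5 means no
   differential causality. When both distances fall below 0.05 — no causal
   change beyond the ensemble noise floor — each D is replaced by D + 1
   before forming the ratio, pinning C near 0.5 instead of amplifying a 0/0.
4. **Validation.** Leave-one-out resampling deletes one time point (the same
   index from both series, keeping alignment), reruns the whole procedure,
   and accumulates a distribution of C per removal index. One fixed set of
   EEMD noise streams is used across all deletion runs, so the spread
   reflects deletion sensitivity only. Records shorter than 100 points use
   every deletion point; longer records use a seeded random subset.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `noise_level` (r) | 0.15 (or grid-selected) | EEMD added-noise amplitude, fraction of series SD — the analysis' only tuned parameter |
| `ensemble_size` (N) | 1000 | EEMD trials; noise cancels as 1/√N. The experiment harness and acceptance script use 200 for desk-scale runtime |
| `max_imfs` | ⌊log₂ L⌋ − 1 | dyadic capacity of a length-L record, one scale reserved for the trend |
| `sift_iterations` | 10 | fixed-count sifting per IMF, after the classic ensemble-EMD implementation lineage |
| `flag_margin` | 0.1 | minimum departure of median C from 0.5 to call an interaction |
| `loo_runs` | 100 | cap on leave-one-out runs for records ≥ 100 points |

`r` is selected by scanning 0.05, 0.10, …, 1.00 and choosing the candidate
that minimises the RMS of pairwise IMF correlations (separability) among
those keeping the nonorthogonal leakage — normalised cross-term energy among
all components, residual included — below 0.05 (orthogonality). Ties go to
the smallest r; if no candidate passes, the minimal-leakage candidate is
used with a prominent warning. Large leakage at large r is real mode mixing
of the ensemble means, not estimation noise: it does not shrink with N.

## Numerical choices

* **Envelopes:** natural cubic splines; the two extrema nearest each record
  end are mirrored across the end point so envelopes are defined everywhere.
  The spline solver was cross-checked against SciPy's natural `CubicSpline`
  to machine precision.
* **Termination:** extraction stops when the working residual has fewer
  than three local extrema; a monotone or constant series yields zero IMFs.
  In EEMD every trial is forced to the common component count, zero-padding
  trials that terminate early, so the ensemble mean is well defined.
* **Phase:** four-quadrant arctangent of the analytic signal; instantaneous
  frequency is the central gradient of the unwrapped phase. All-zero IMFs
  get zero amplitude/phase and a `degenerate` flag.
* **Seeding:** every stochastic step (EEMD streams, deletion subsets,
  generators) is driven by explicit integer seeds; equal seeds give
  bitwise-equal results. Redecompositions use independently seeded streams
  by default; `reuse_noise_stream=True` reuses the original series' stream
  for strict-symmetry experiments (identical inputs then give C exactly 0.5).
* **Distance modes:** the default distance runs over the full profile while
  removal is of a single index (removal index and summation index are
  distinct); a `single_pair` mode restricting the distance to the removed
  index is available behind a switch.
* **Component numbering:** IMFs are numbered from 1 (standard). The classic
  Matlab ensemble-EMD lineage returns a matrix whose first column is the
  input signal, so analyses built on it label the first IMF as component 2;
  `legacy_component_index` converts to that published convention, and the
  acceptance script reports component indices in it.

## Benchmark systems

* **Coupled logistic map** — chaotic two-species difference system,
  x(1)=0.2, y(1)=0.4; x couples into y (0.1) five times more strongly than
  y into x (0.02). Its dominant dynamics are the period-≈2.3 alternation
  (87 % of variance), which any EMD necessarily places in the *first* IMF —
  the scale at which the x→y interaction is detected (C ≈ 0.9).
* **Stochastic AR pair** — x is an AR(2) oscillator (roots 0.95·e^{±iπ/4},
  period 8); y = 0.5·x(t−2) + independent noise, a pure lagged response.
  Default length 1000 after a 100-sample burn-in from standard-normal
  initial values. The x→y interaction appears at the first two IMFs
  (the period-8 main mode and its slower tail), strongest at IMF 1.
* **Lotka–Volterra** — dx/dt = αx − βxy, dy/dt = δxy − γy with α=1, β=0.05,
  δ=0.02, γ=0.5; classical RK4 at dt = 0.01, sampled every 1.0 model-time
  unit for 200 units from (x₀, y₀) = (30, 10), so several full cycles fit
  the record (the linearised period is 2π/√(αγ) ≈ 8.9 time units). The
  integrator conserves the first integral δx − γ ln x + βy − α ln y to
  1 × 10⁻⁴ over 50 time units.
* **White-noise pairs** — independent standard-Gaussian pairs for null
  calibration.
* **Manipulations** — decimation (keep every k-th sample) and temporal
  shift (trim to overlap by default; circular variant by flag).

These generators emulate the benchmark dynamics exactly as defined; they do
not emulate observational features of real ecological data (measurement
error, irregular sampling, short records, secular trends), so green
benchmark tests demonstrate correctness of the machinery and calibration of
the null, not field performance.

## Significance flagging: definition and measured calibration

"Significant causal interaction" is an interpretation, exposed as
configuration. The default rule flags removal index *i* when the central
95 % of its leave-one-out C distribution excludes 0.5 **and** the median
departs from 0.5 by at least `flag_margin`. With `loo_runs=0` the flag
falls back to the point estimate's margin. `CausalProfile` also exposes
`dominant` — the always-defined scale of maximal |C − 0.5| — alongside
`primary` (the strongest flagged scale); reports use primary-if-flagged,
else dominant.

Measured behaviour at desk scale (L = 200–400, r = 0.15, N = 200) that a
user must know:

* The *population* null is well calibrated: the mean of C over white-noise
  pairs is ≈ 0.5 (0.495 over 100 pairs).
* *Per-pair* flagging is not a calibrated test at these lengths. Individual
  white-noise pairs can carry strong realisation-specific asymmetries
  (|C − 0.5| up to ≈ 0.25) that are stable across EEMD seeds and survive
  single-point deletion, so they pass the leave-one-out criterion.
* Conversely, a genuine interaction living at the fastest scale can fail
  it: the coupled logistic map's Nyquist-scale phase difference drifts
  through several turns, making the baseline coherence a fragile, almost
  sinc-like quantity that single-point deletion legitimately flips — its
  C ≈ 0.9 point estimate is stable across ensembles but not
  deletion-robust, so the logistic interaction is identified via
  `dominant`, not formally flagged.

Treat flags as descriptive, not inferential; for inference, compare against
an explicit surrogate null for the record at hand.

## Known limitations

* Pairwise only; no multivariate extension.
* Coherence values for the coarsest IMFs of a short record (≈ 1–2 cycles)
  are chance-dominated and should be ignored.
* Down-sampling an intrinsically fast chaotic system by an odd factor can
  alias the fast alternation back into the first IMF, where this
  implementation still resolves genuine residual coupling (ensemble-mean
  C ≈ 0.65–0.72 for the decimated logistic pair) rather than collapsing to
  0.5; decimation null results therefore hold cleanly for the stochastic
  system but not for the logistic map.
* Problem sizes in the test suite and acceptance script (N = 200 ensemble
  trials, 10 leave-one-out runs, 100 null pairs) are desk-scale choices;
  production analyses should use the N = 1000 default and the full
  leave-one-out budget.
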