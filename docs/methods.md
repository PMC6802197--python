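# Methods

This note documents the models behind `plectokin`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices a user should know before trusting a number.

## DNA mechanics

**Supercoiling free energy.** For a covalently closed plasmid of N base
pairs carrying a linking difference ΔLk, the stored torsional free energy is
taken from the empirical quadratic relation ΔG_SC = (1100/N)·k_BT·ΔLk². The
relaxed linking number is Lk0 = round(N / 10.5); rounding to the nearest
integer turn is deliberate — it is the convention under which a 4361 bp
plasmid at |σ| = 0.05 carries ΔLk = 20.75 exactly (415.33 → 415 turns). The
relation is even in ΔLk and inversely proportional to N; both properties are
asserted by tests.

**Bending.** The harmonic (worm-like-chain) bending penalty over a short
segment is ΔG = A·k_BT·θ²/(2l), with persistence length A = 40 nm (assay
buffer), θ the total bend and l the segment contour length. Lengths given in
bp convert at 0.34 nm/bp, so a 60° bend over 14 bp (4.76 nm) costs 4.6 k_BT.
Supercoiling pre-bends DNA; the residual cost of reaching the active-site
geometry from a pre-bend θ_pre is ΔG(θ) − ΔG(θ_pre). The pre-bend angle
(10° over 14 bp at |σ| = 0.05) is an input constant from published
elastic-rod simulations, not computed here.

**Interface free energy.** A transiently binding interface that spends
exponential lifetimes τ_bound and τ_unbound in its two states has binding
free energy ΔG = k_BT·ln(τ_bound/τ_unbound). The unbound lifetime of the
apical interface during supercoil release is estimated as the turn-removal
time (~4 ms/turn) times the mean number of turns released per event.

**Bell model.** Force-dependent bond lifetimes follow
τ(F) = τ₀·exp(−F·Δx/k_BT), with Δx the distance to the transition state.
Temperatures are explicit everywhere: bulk reactions at 310 K, MT
measurements at 298 K. The MT temperature is not documented by the emulated
experiments; 298 K (room temperature) is the package default and a parameter,
so the sensitivity is testable (Δx scales linearly with the assumed T: a 5 K
error is 1.7%).

**Topology conversion.** In the plectonemic regime, extension changes
linearly with linking difference; Δz→ΔLk conversion divides by the slope c
(default 45 nm/turn at the 0.5 pN working force — a setup-dependent
calibration, exposed as a parameter).

**Tip convolution.** A conical AFM tip of half-cone angle α widens a
particle of true lateral size D and height h to FWHM = D + h·tan(α).

## Step finding

The step finder decomposes a uniformly sampled extension trace into
plateaus:

1. **Greedy placement.** Iteratively add the single step location that
   maximally reduces the squared residuals of the piecewise-constant fit
   (computed in O(1) per candidate from cumulative sums; ties break to the
   earliest sample). No plateau may be shorter than the minimum dwell
   (default 3 samples at 58 Hz).
2. **Noise-scaled stopping.** The per-sample noise SD is estimated robustly
   from the median absolute deviation of first differences (steps are sparse
   in the differenced signal). Growth stops when the best remaining gain
   falls below ~σ²·2·ln(n), the expected gain of optimally splitting pure
   noise — without this, continued growth inflates the counter-fit ratio on
   featureless traces.
3. **Counter-fit acceptance.** For each candidate step count k, a
   counter-fit places steps at the midpoints of the fitted plateaus. The
   ratio S(k) = SSE_counterfit/SSE_fit peaks well above 1 only when genuine
   steps exist; the candidate set is accepted when the peak reaches the
   acceptance threshold (default 1.3, configurable). A perfect
   (zero-residual) staircase is accepted outright.
4. **Per-step quality control.** Accepted steps are then pruned
   individually: a step whose removal raises the residual variance of its
   two flanking plateaus by less than the same threshold is discarded
   (weakest first, iteratively).

Samples recorded during commanded magnet rotation are masked by splitting
the trace at changes of the `magnet_turns` channel and fitting each constant
segment independently; commanded extension changes therefore never appear as
steps. σ_z is the sample SD in a centered 0.5 s sliding window, truncated at
the trace edges.

Verified behaviour: exact recovery on noiseless staircases, zero steps on
pure noise, ≥95% recovery of resolvable steps with ≤5% spurious detections
at step/noise ≥ 3, equivalence with exhaustive single-step search on toy
traces, idempotence on its own reconstruction, and scale equivariance.

## Dwell-time and step-size statistics

Exponential lifetimes are estimated by maximum likelihood (the sample mean,
after discarding and subtracting an optional detection cutoff — valid by
memorylessness). The 95% CI uses the exact chi-square pivot
2nτ̂/τ ~ χ²(2n); a percentile bootstrap is available as a cross-check. The
final, interrupted dwell of each trace is discarded rather than
right-censored — at the trace durations and lifetimes involved, the bias is
negligible compared with the CI width.

ΔLk step-size distributions are summarized by a Gaussian KDE with a fixed
0.2-turn bandwidth on a 0.05-turn grid padded by 4 bandwidths (3 bandwidths
would lose 2.7×10⁻³ of each kernel's mass, violating the unit-integral
contract at the 10⁻³ level). Integer quantization of released turns is
detected by normalizing the density to unit mass, fitting and subtracting a
single-exponential background, and taking the discrete Fourier transform of
the RMS-normalized residual: a 1 cycle/turn peak indicates integer steps.

Condition comparisons (torque sign, supercoil sign) use the two-sample
Kolmogorov–Smirnov test on event samples. The fraction of large release
steps (ΔLk > 10) is compared between conditions by a Welch t-test on
per-trace fractions — pooling events across tethers would fabricate
independence. With a single trace per condition the comparison refuses and
reports descriptive fractions only.

## Force spectroscopy

Rupture (and loop-release) times at each force are fitted by the exponential
MLE; rows labeled as handle detachments can be treated as right-censored
(they contribute observation time but no event). The Bell fit is a weighted
linear regression of ln τ on F with weights equal to the per-force event
counts: for an exponential MLE, Var[ln τ̂] = 1/n exactly, so the parameter
covariance is (XᵀWX)⁻¹ with no residual rescaling. This matters: with three
force levels and two parameters, a residual-scaled covariance would have one
degree of freedom and its ±2 SE intervals would cover the truth only ~70% of
the time instead of ~95%. An unweighted variant exists for sensitivity
analysis. Because the measured forces (30–50 pN) lie far above k_BT/Δx, the
zero-force lifetime is a long extrapolation; its relative standard error
always exceeds that of Δx (asserted by a test), which is why τ₀ should be
read as an order-of-magnitude lower limit.

## Ensemble kinetics

The productive pathway is a linear first-order chain

    T --(k_on·f_active)--> TCC --(k_hs)--> HS --(k_fs)--> FS,

with weak reversibility of capture (k_off, fixed at 10⁻¹⁰ min⁻¹ — profiling
shows the fit is flat in k_off below ~10⁻⁴ min⁻¹, which is why it is fixed
rather than fitted). The intasome is in excess, so its concentration is
absorbed into the pseudo-first-order capture rate. The measured observable
is FS/total DNA = f_active · F_chain(t): inactive intasomes capture and
sequester target essentially irreversibly, so the long-time full-site yield
plateaus at the active fraction — consistent with the ≤40% conversion seen
in such assays. The chain itself is solved by eigendecomposition of the 4×4
rate matrix (exact for a linear system), with a matrix-exponential fallback
when the matrix is near-defective (e.g. k_hs ≈ k_fs); agreement with the
closed-form three-exponential solution is asserted to 10⁻⁸ relative.

The global fit shares f_active, k_hs, k_fs across plasmid lengths, gives
each length its own k_on, and minimizes error-weighted least squares
(weights from replicate SDs; zero SDs are replaced by the per-dataset median
SD). Optimization uses bounded trust-region least squares from a
deterministic start (rates 0.1 min⁻¹, f_active 0.5) plus seeded multi-start
perturbations; non-convergence is flagged, never silent. Parameter SEs come
from the Jacobian covariance scaled by the reduced chi-square.

**Known limitation.** With SDs estimated from only three replicates, the
weighted residuals are heavy-tailed (t with 2 degrees of freedom), and Wald
CIs under-cover somewhat per parameter (~86–97% observed at 95% nominal).
Joint coverage of all seven parameters at once is therefore structurally
well below 90%; per-parameter inference is reliable, simultaneous inference
on all parameters is not, and would need profile-likelihood or bootstrap
intervals.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
the physics of bead tracking:

- **Target-capture traces** — piecewise-constant extension with exponential
  dwells (default lifetime 3 s), two-sided exponential step sizes (default
  decay 45 nm), a capture event that reduces the per-sample noise SD
  (bridging pinches off part of the plectoneme), 58 Hz sampling, and white
  Gaussian extension noise (default 8 nm SD — a knob, since real
  bead-fluctuation magnitudes depend on bead size, force and tether length).
- **Supercoil-release staircases** — exponential plateau dwells (apical
  interface lifetime) and geometric numbers of turns released per event (a
  fixed interface-reforming probability per turn), converted at 45 nm/turn
  and rendered as finite-speed ramps at 4 ms/turn so step-finder robustness
  to non-instantaneous steps is exercised. Torque asymmetry is modeled by
  letting the lifetime and rebinding probability depend on a condition
  label, not by computing torque from first principles.
- **Force-jump rupture tables** — exponential rupture times with Bell-model
  means per force; a configurable fraction of tethers carries a preceding
  loop-release event with its own Bell parameters (recorded only when it
  precedes rupture, a competing-risks structure), with loop-jump sizes drawn
  proportional to the tether's σ_z reduction so the observed jump/Δσ_z
  correlation is reproduced qualitatively.
- **Ensemble kinetics tables** — the chain ODE plus Gaussian gel-quantification
  noise, means ± SD over replicates.
- **AFM crossing counts** — rounded Gaussians (means 2.4 and 12.2, SD 1.7)
  clipped at zero. Clipping biases the open-circular mean up by ≈0.06; tests
  account for it, and the n ≤ 6 classification threshold is unaffected
  (expected misassignment 0.8% for OC, 0.04% for SC).

Every generator is a pure function of (config, seed) and bitwise
reproducible. What a green test establishes is recovery under the assumed
model (exponential dwells, white noise, linear Δz↔ΔLk); drift, tracking
artifacts, force calibration error and bead-size heterogeneity of real
instruments are out of scope.

## Numerical conventions

- Energies in k_BT at an explicit temperature; k_B = 1.380649×10⁻² pN·nm/K.
  Conversion to pN·nm or kJ/mol is available but never implicit.
- Angles in degrees at API boundaries, radians internally; AFM angle
  statistics use circular (vector) means and are invariant to adding 360°;
  angles can be folded to [0°, 180°) because the intasome long axis is
  orientation-free.
- Counting errors on category fractions are √k/n_tot (Poisson). Proportion
  comparisons use the pooled z-test, switching to Fisher's exact test when
  any expected cell is below 5.
- Trace TSV stores values at full double precision (`%.17g`) so read∘write
  is the identity; time must be strictly increasing and uniform, and parse
  errors name the offending line.
- Ties, degenerate inputs and insufficient data raise descriptive errors or
  flagged results (e.g. lifetime estimates from n < 5 are marked
  unreliable), never NaNs.
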