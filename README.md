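# plectokin

Single-molecule mechanics and kinetics of retroviral intasome–DNA complexes.

Retroviral integration proceeds through a nucleoprotein machine (the
intasome) that captures host target DNA, bends it into the active site, and
covalently joins viral and target DNA. Magnetic-tweezers (MT) experiments on
supercoiled DNA tethers and AFM imaging of plasmid–intasome particles resolve
this pathway one molecule at a time: target capture shows up as reduced
extension fluctuations and discrete repositioning steps, strand transfer
pins supercoils that are later released in integer-quantized steps, and the
strand-transfer complex (STC) resists forced disassembly for days. This
package implements the complete analysis chain for such experiments, plus
seeded synthetic-data generators that stand in for raw recordings.

## What it computes

**DNA mechanics (closed form).** Supercoiling free energy
ΔG<sub>SC</sub> = (1100/N)·k<sub>B</sub>T·ΔLk², harmonic bending penalty
ΔG = A·k<sub>B</sub>T·θ²/(2l), interface binding free energy
ΔG = k<sub>B</sub>T·ln(τ<sub>bound</sub>/τ<sub>unbound</sub>), the Bell model
τ(F) = τ₀·exp(−F·Δx/k<sub>B</sub>T), the plectonemic extension↔linking
conversion ΔLk = Δz/c, and the AFM tip-convolution model
FWHM = D + h·tan(α).

**Trace analysis.** An unbiased step finder (iterative chi-square placement
with counter-fit quality control), the sliding-window fluctuation statistic
σ_z, exponential dwell-time MLE with exact chi-square 95% CIs, kernel-density
and Fourier analysis of supercoil-release step sizes, two-sample
Kolmogorov–Smirnov comparisons, survival curves, and the weighted log-linear
Bell fit of force-dependent lifetimes.

**Ensemble kinetics.** A linear capture → half-site → full-site chain with a
shared active-intasome fraction, fitted globally across plasmid lengths by
error-weighted least squares, with profile-likelihood identifiability
diagnostics.

**AFM statistics.** Topology classification by DNA self-crossing number
(open-circular for n ≤ 6), Poisson counting errors √k/n, two-proportion
tests, and circular statistics of DNA entry/exit angles.

## Worked example

```python
import numpy as np
from plectokin import synthetic, stepfind, dwellstats, forcespec

# a 10-minute target-capture trace at 58 Hz with 8 nm extension noise
cfg = synthetic.SimulationConfig(seed=42, duration_s=600.0, noise_sd_nm=8.0)
trace, truth = synthetic.simulate_tcc_trace(cfg, tau_tcc_s=3.0, step_decay_nm=45.0)

fit = stepfind.find_steps(trace)
dwells = fit.dwell_times_s[fit.dwell_times_s > 0]
est = dwellstats.fit_exponential_mle(dwells)
print(f"steps found: {fit.n_steps} (simulated events: {len(truth)})")
print(f"tau_TCC = {est.tau:.2f} s  (95% CI {est.ci95_low:.2f}-{est.ci95_high:.2f}, n={est.n})")

# forced STC disassembly at 30/40/50 pN and the Bell-model fit
table = synthetic.simulate_force_jump(cfg, tau0_days=245.0, delta_x_nm=0.89,
                                      n_per_force=[55, 41, 36])
bell = forcespec.fit_bell(forcespec.fit_force_lifetimes(table), temperature_K=298.0)
print(f"Bell fit: tau0 = {bell.tau0/86400:.0f} d, "
      f"dx = {bell.delta_x_angstrom:.2f} +/- {bell.se_delta_x_angstrom:.2f} A")
```

Output:

```
steps found: 169 (simulated events: 188)
tau_TCC = 3.21 s  (95% CI 2.77-3.76, n=168)
Bell fit: tau0 = 138 d, dx = 8.31 +/- 0.44 A
```

The recovered dwell lifetime agrees with the generating 3.0 s within its CI
(events shorter than the step-finder's resolution merge, slightly thinning
the count). The Bell fit recovers the distance to the transition state
Δx ≈ 8.3 ± 0.4 Å against a generating 8.9 Å; the zero-force lifetime τ₀ is an
extrapolation far outside the measured force range, hence its much larger
relative uncertainty — the reason such estimates are quoted as lower limits.

A command-line surface wraps the same functions:

```bash
plectokin simulate tcc --seed 1 --out trace.tsv
plectokin analyze steps trace.tsv --out steps.tsv
plectokin analyze dwells steps.tsv
plectokin report --seed 1 --out results/
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch — the analytic free-energy and geometry values, exponential-lifetime
recovery at the experimental sample sizes (n = 724 and 750), and the
Bell-model Δx recovered from rupture times simulated at the 30/40/50 pN
design — and writes them to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/plectokin/mechanics.py` — closed-form energies and conversions
- `src/plectokin/synthetic.py` — seeded generators for every input type
- `src/plectokin/stepfind.py` — step finder and σ_z
- `src/plectokin/dwellstats.py` — dwell/step-size statistics
- `src/plectokin/forcespec.py` — survival analysis and Bell fits
- `src/plectokin/kinetics.py` — ensemble ODE model and global fit
- `src/plectokin/afm.py` — particle topology and angle statistics
- `src/plectokin/io.py`, `cli.py` — formats, config, pipeline, CLI
- `docs/methods.md` — models, assumptions, numerical choices
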