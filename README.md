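# ktnfpt

First-passage-time analysis of kinetic transition networks: reading the
organization of a multifunnel energy landscape out of its dynamics.

Molecular switches, bistable peptides, competing cluster morphologies —
multifunctional systems live on energy landscapes with several funnels, and
each competing funnel acts as a kinetic trap with its own escape time
scale. Those time scales are directly visible in the first-passage-time
(FPT) distribution between reactants and products: on a logarithmic time
axis, every trap contributes a peak to the density of y = ln t, and the
mean first passage time restricted to a finite observation window t_obs
climbs one plateau per trap as the window grows. This package computes and
cross-validates those signatures for networks of minima and transition
states (the standard output of discrete path sampling and related rare-event
methods), for people who build or analyze such networks.

## What it computes

Given a network with minimum/transition-state energies and a temperature
(k_B = 1), the package derives harmonic unit-prefactor rate constants and
provides four mutually checking routes to the kinetics:

- **Spectral** — with products absorbing, the master-equation generator M
  has real decay rates nu_l > 0 (reversibility), and
  `p(t) = Σ_l A_l e^(−nu_l t)` with `Σ_l A_l/nu_l = 1`. Moments
  `⟨t^n⟩ = n! Σ_l A_l/nu_l^(n+1)`, the log-time density
  `p~(y) = e^y p(e^y)`, and the window-restricted mean
  `⟨t⟩_obs = Σ_l (A_l/nu_l²)[1−(1+nu_l t_obs)e^(−nu_l t_obs)] / z(t_obs)`
  are evaluated per mode in closed form. An extended-precision Jacobi
  eigensolver plus stable inverse-iteration refinement keeps the slow decay
  rates accurate even when they sit ten orders below the fast ones.
- **Graph transformation** — deterministic node elimination with
  renormalized branching probabilities and waiting times; exact MFPTs,
  numerically stable at any temperature.
- **Standard kinetic Monte Carlo** — rejection-free sampling with Poisson
  waiting times, in a compiled per-walker kernel.
- **Leapfrog kMC** — flicker-free sampling: the geometric number of
  recrossings of a low barrier is drawn in one shot, allocated over
  neighbors (multinomial, or its Householder-constructed multinormal
  approximation at large counts), and the walker exits directly to second
  neighbors or adjacent absorbing states with renormalized probabilities
  that conserve the MFPT exactly. Trajectories representing >10^15
  conventional steps complete in microseconds.

A built-in generator emulates a multifunnel test landscape — a six-minimum
main path with four side traps of increasing depth (escape barriers
depth + 3) whose low internal barriers make trajectories flicker — plus
disconnectivity-tree construction (superbasin merges at descending energy
thresholds) and peak/step detectors connecting FPT features back to the
traps. PATHSAMPLE-style `min.data`/`ts.data` files are read and written.

## Worked example

```python
import numpy as np
import ktnfpt as kf

spec = kf.DEFAULT_LANDSCAPE                     # frozen 4-trap landscape
ktn = kf.generate_multifunnel(spec)             # 18 minima, 17 saddles
rm = kf.build_rate_model(ktn, temperature=1.0)
ap = kf.AbsorbingProblem(rm, A={spec.product}, B={spec.reactant})

sp = kf.spectral_decompose(ap)
print(f"modes: {sp.n_modes}, slowest rates: {sp.nus[:4]}")
print(f"MFPT (spectral): {kf.fpt_moments(sp, 1):.6e}")
print(f"MFPT (graph transformation): {kf.gt_mfpt(ap)[0]:.6e}")

y = kf.default_y_grid(sp)
peaks = kf.detect_peaks(np.asarray(kf.log_time_density(sp, y)), y)
print(f"peaks in p~(ln t): {peaks.count} at y = {np.round(peaks.positions, 2)}")

grid, curve, _ = kf.mfpt_vs_observation_time(sp)
steps = kf.detect_steps(curve, grid, sp)
print(f"steps in <t>_obs: {steps.count}, plateaus {steps.plateaus_after}")

ens = kf.run_leapfrog_kmc(ap, 200_000, rng=1)
print(f"leapfrog mean t: {ens.t.mean():.4e}  (KS vs spectral: "
      f"{kf.cdf_sup_distance(sp, ens.t):.4f})")
```

prints

```
modes: 17, slowest rates: [2.96486198e-11 1.82305401e-08 1.18126649e-05 3.25186406e-03]
MFPT (spectral): 1.126526e+10
MFPT (graph transformation): 1.126526e+10
peaks in p~(ln t): 4 at y = [ 4.45 11.36 17.83 24.25]
steps in <t>_obs: 4, plateaus [1.98562367e+02 3.40026291e+04 2.17186513e+07 1.12652596e+10]
leapfrog mean t: 1.1259e+10  (KS vs spectral: 0.0019)
```

Reading it: the four slowest decay rates are separated by factors of a few
hundred — one per trap. The four peaks of the log-time density sit at the
trap escape times (ln t ≈ depth + entry barrier at T = 1), and the
observation-time scan climbs through four plateaus; each plateau equals the
MFPT computed from the modes that are feasible on that time scale, the last
one being the full MFPT of 1.13 × 10^10. The 200 000 leapfrog trajectories
reproduce the exact distribution to a CDF sup-distance of 0.002 — each of
them implicitly performs ~10^8 conventional kMC steps.

The same analyses are available from the shell: `ktnfpt generate`,
`ktnfpt spectral`, `ktnfpt kmc`, `ktnfpt leapfrog`, `ktnfpt gt`,
`ktnfpt tree`, `ktnfpt report` (see `--help`; all output is JSON/TSV).

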