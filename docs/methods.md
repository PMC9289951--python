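# Methods

## The model and what the package computes

A kinetic transition network (KTN) represents an energy landscape as a
weighted multigraph: nodes are local minima, edges are the transition states
connecting them. At temperature T (k_B = 1, so T carries energy units) the
network defines a continuous-time, reversible Markov chain with directed
rate constants

    k(i <- j) = pg_j * exp(-(E_ts - E_j)/T - (lfp_ts - lfp_j)),

the harmonic form with unit prefactor: `lfp` is the log product of
normal-mode frequencies (zero on model landscapes) and `pg` the point-group
order. The equilibrium weights are pi_j ∝ exp(-E_j/T - lfp_j)/pg_j, and the
point-group factor in the rate is what makes detailed balance
k(i<-j) pi_j = k(j<-i) pi_i hold exactly for any pg assignment. Parallel
transition states add their rates. Waiting times are tau_j = 1/sum_i k(i<-j)
and branching probabilities P(i<-j) = k(i<-j) tau_j.

Making the product set A absorbing turns the first-passage problem into a
linear master equation dP/dt = M P on the non-absorbing nodes, with
off-diagonal entries the inter-node rates and diagonal entries minus each
node's total escape rate (including flow into A). Because the chain is
reversible, M is similar to a symmetric matrix via diag(pi^1/2), so its
spectrum is real: eigenvalues -nu_l with decay rates nu_l > 0. The
first-passage-time (FPT) density from initial distribution P0 is the flux
into A,

    p(t) = sum_l A_l exp(-nu_l t),
    A_l  = nu_l (1^T w_l^R)(w_l^L . P0),      sum_l A_l/nu_l = 1,

with left/right eigenvector pairs of M. Everything else follows in closed
form per mode: moments <t^n> = n! sum_l A_l/nu_l^(n+1) (n=1 is the MFPT),
the log-time density p~(y) = e^y p(e^y) for y = ln t, and the
observation-window-restricted MFPT

    <t>_obs = [sum_l (A_l/nu_l^2) f(nu_l t_obs)] / z(t_obs),
    z       = sum_l (A_l/nu_l)(1 - e^{-nu_l t_obs}),
    f(x)    = 1 - (1+x) e^{-x},

which is the mean over events completing within t_obs and converges to the
MFPT with z -> 1 as t_obs grows.

On a multifunnel landscape each kinetic trap contributes one slow mode;
well-separated trap escape times appear as separate peaks in p~(y) and as
separate plateaus in <t>_obs as a function of ln t_obs. The plateau with
the k fastest modes feasible equals the "partial-sum" MFPT
sum_k(A/nu^2)/sum_k(A/nu) — the restricted spectrum carries its own
normalization, which is also why the full sum (z = 1) gives the exact MFPT.

## Stochastic engines

**Standard kMC** is the rejection-free algorithm: draw the next node from
the branching probabilities, draw the residence time as -tau ln x with x
uniform on (0,1]. The ensemble runner is a compiled (numba) per-walker loop
with an inline xorshift128+ stream (seeded via splitmix64 from the caller's
seed); trajectories that exceed a conventional-step budget (default 10^9)
are flagged censored rather than truncated silently.

**Leapfrog kMC** removes "flickering" — the enormous number of recrossings
of a low internal barrier — analytically. From node i, the probability that
one more recrossing i->j->i happens before anything else is
beta_i = sum_{j not in A} P(j<-i)P(i<-j). The total recrossing count is
geometric, P(N=n) = (1-beta) beta^n, sampled by inverting the closed-form
CDF 1 - beta^(n+1): N = ceil(ln(1-x)/ln beta) - 1 (the continuous inverse
rounded up, which reproduces the CDF identity exactly including at its lattice
points). The N recrossings are allocated over neighbors j with conditional
probabilities q_j = P(j<-i)P(i<-j)/beta — exactly multinomially, or by the
multivariate-normal approximation (mean Nq, covariance N(diag q - q q^T),
realized with m-1 standard normals and a Householder reflection whose final
column is sqrt(q), then integerized by rounding with a largest-remainder
repair of the total) when beta_i > 0.95 *and* the sampled N exceeds 1000,
since the Gaussian picture is only accurate at large N. Their waiting time
is sum_j n_j (tau_i + tau_j) (a mean-waiting variant,
N * sum_j q_j(tau_i+tau_j), is available behind a flag; both conserve the
MFPT in expectation). The walker then exits through a renormalized channel —
any two-hop path i->j->k with k != i, or a direct hop to an adjacent
absorbing node — with probabilities divided by 1-beta_i, and Poisson
waiting per hop. The expected total move time is
tau_i^lf = (tau_i + sum_{j not in A} P(j<-i) tau_j)/(1-beta_i), so the MFPT
is conserved exactly; this is validated against graph transformation in the
tests. Each recrossing accounts for two implicit steps, so the dynamical
activity s is preserved in expectation.

Leapfrog moves are taken when beta_i exceeds a threshold (default 0.5;
anything in (0,1) gives statistically indistinguishable ensembles, which the
tests check at 0.1 vs 0.9); other nodes advance by standard steps. Tables
are cached per node — they depend only on the rate model and absorbing set.
The leapfrog step budget defaults to 10^15 conventional-equivalent steps:
its wall cost does not grow with the implicit step count, and deep-trap
trajectories at low temperature legitimately represent >10^9 conventional
steps, so the standard budget would censor the tail and bias the mean.

**Graph transformation (GT)** is the deterministic reference: eliminate
non-absorbing nodes one at a time, renormalizing survivors'
branching probabilities and waiting times
(P'_{ba} = P_{ba} + P_{bx}P_{xa}/(1-P_{xx}),
tau'_a = tau_a + P_{xa} tau_x/(1-P_{xx})), which preserves the MFPT exactly
and involves only additions of positive quantities — provided 1-P_xx is
computed as the sum of the other exit probabilities rather than by
subtraction. The MFPT per source is tau'_b/(1-P'_bb) once only that source
remains. Removal order is immaterial (tested to 1e-10); a greedy
minimum-degree order limits fill-in.

## Numerical choices

Three places would otherwise lose precision catastrophically:

- **Graded spectra.** LAPACK's symmetric eigensolvers deliver absolute
  accuracy eps*||M||, which destroys decay rates ten orders below the
  fastest one. For networks up to 150 nodes the symmetrized matrix is
  diagonalized by a cyclic Jacobi sweep in extended (80-bit long double)
  precision, cross-checked against LAPACK, and the slowest (<= 6) eigenpairs
  are then polished by inverse iteration against a subtraction-free LU of
  the absorbing generator. That LU keeps the M-matrix in its
  "off-diagonal rates + absorption surplus" representation and recomputes
  pivots from the column-sum invariant (the same idea as the GTH algorithm
  and as GT itself), so solves with nonnegative right-hand sides are
  componentwise accurate at any condition number; the slowest eigenvector is
  positive (Perron), so its iterates never cancel, and deflated iterations
  inherit the accuracy for the next few modes. With this, the spectral and
  GT MFPTs agree to ~1e-15 on the frozen landscape at both study
  temperatures. No arbitrary-precision arithmetic is used; below roughly
  T ~ 0.5 on the frozen landscape the decomposition's internal checks fail
  and it raises, pointing to GT/leapfrog, which remain valid at any
  temperature.
- **1 - beta near 1.** At flickering nodes beta_i is within one ulp of 1
  (or rounds to exactly 1.0); 1-beta_i is accumulated directly as
  absorption-plus-non-return path probabilities, and the geometric sampler
  takes ln(beta) as log1p(-(1-beta)). Without this the sampled N overflows
  and the walk never terminates.
- **Truncated-MFPT cancellation.** The per-mode integral f(x)=1-(1+x)e^{-x}
  is evaluated by series below x = 0.01 (it is ~x^2/2 against terms of size
  1), and window/normalization sums whose mixed-sign amplitude cancellation
  exceeds nine digits are reported as "no feasible events" — at such short
  windows the completing fraction is below numerical resolution anyway.

Degenerate eigenvalues (relative gap < 1e-10) have their amplitudes merged.
The initial condition is a delta on the named reactant by default (the
convention in all worked examples) or Boltzmann-restricted to the reactant
set; outputs record which, because the FPT features depend on it.

## Peak and step diagnostics

Peaks of the log-time density are local maxima with prominence at least 5%
of the global maximum (scipy `find_peaks`), on a 600-point grid spanning
[ln(1e-3/nu_max), ln(1e3/nu_min)]; edge maxima do not count. Steps of
<t>_obs are local maxima of d ln<t>_obs/d ln t_obs (median-filtered,
prominence-gated at 10% of the largest slope), plus the initial ramp from
zero — the fastest relaxation saturates rather than peaks in slope, so it is
prepended as the first step whenever the curve rises by more than a factor e
before the first interior slope peak; for a single-exponential curve this
places the one step near -ln nu. Plateau levels are read at the flattest
point between steps and compared with the partial-sum predictions; with
mode separations of ~e^6 the residual contamination from the neighboring
modes leaves the read-off 3-4% above the prediction, so the 5% agreement
band is close to intrinsic. At separations of only ~e^3 (the frozen
landscape at T=2) the curve never flattens between rises and plateau
read-offs are not meaningful at the 5% level — step/plateau analysis needs
roughly two orders of magnitude between consecutive slow rates.

## The model landscape

`ModelLandscapeSpec` freezes a 18-minimum / 17-transition-state landscape
built to show four cleanly separated trap signatures at both T=1 and T=2:

| parameter | value | role |
|---|---|---|
| main_path_length | 6 | reactant (node 1) to product (node 6) backbone |
| main_path_slope | 1.0 | downhill ramp toward the product |
| main_path_barrier | 3.0 | barrier above the higher endpoint of each backbone edge |
| n_branches | 4 | one kinetic trap per interior backbone node |
| trap_depths | 0.5, 7.0, 13.5, 20.0 | trap bottom below its attachment node |
| branch_entry_barrier | 3.0 | entry saddle above the attachment node |
| entry_bottleneck | 2.0 | entropic prefactor dividing every entry rate |
| minima_per_trap | 3 | ladder length inside each trap |
| trap_ladder | 2.0 | energy drop per rung descending to the bottom |
| internal_barrier | 2.9 | barrier above the higher rung of each trap edge |

Escape from trap j requires climbing trap_depths[j] + 3, strictly
increasing, so the slow relaxation rates are separated by factors of
e^{6.5/T} (>= 200 at T=1). The three structural choices beyond the obvious
ones exist for identifiable reasons. The downhill ramp biases the walk
forward so a trajectory does not revisit every trap many times; without it
the deepest trap dominates every trajectory's FPT and the three faster trap
peaks drown under its left tail. The entry bottleneck (a log-frequency
product of ln 2 on the entry saddles) suppresses trap entry by the same
factor at every temperature — a barrier could only do this at one
temperature — which balances the peak weights at T=1 and T=2
simultaneously. The trap ladder steepens the final descent so that the
flicker step count per escape, ~exp((depth+3-internal-ladder)/T), stays
small enough for standard kMC at T=2 to be a practical cross-check while
still flickering heavily (beta at trap interiors is 1 within double
precision at T=1, the regime leapfrog exists for). The shallowest trap
(0.5) relaxes on the direct-transit time scale by design: its signature
merges with the transit feature into the first peak/step, so exactly four
features appear.

What passing on this landscape does and does not show: the generator
produces reversible-by-construction, tree-structured networks with a
single product node and delta initial conditions. Real molecular databases
have cycles, parallel saddles, frequency and symmetry data, broad reactant
sets, and spectral gaps that are not engineered — agreement of the three
engines and GT here validates the machinery (exact identities, conserved
MFPTs, correct sampling laws), not the resolvability of peaks in any given
molecular system, which depends on that system's time-scale separation.

## Interfaces

PATHSAMPLE-style `min.data`/`ts.data` text files are read and written
(inertia fields ignored/zeroed, 1-based indices), alongside a native
tab-separated dialect with explicit headers and a JSON metadata sidecar.
The `ktnfpt` command line exposes `generate`, `spectral`, `kmc`,
`leapfrog`, `gt`, `tree` and `report`; all output is JSON or delimited
tables, seeds are echoed, usage errors exit 2 and computational failures
exit 1.

## Known limitations

- The spectral route is dense (O(n^3)) and the Jacobi/refinement path is
  engaged up to 150 nodes; larger networks fall back to LAPACK double
  precision, where the MFPT cross-check against GT degrades with the
  spectral spread.
- GT yields means only, no distributions.
- Ensemble reproducibility is per (seed, n_runs, engine) — trajectories are
  not assigned independent per-walker streams, so changing n_runs reshuffles
  the sample path.
- Censored trajectories are excluded from ensemble statistics; at
  parameters where censoring is common the reported means are biased low and
  the censoring count must be consulted.
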