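"""Exact first-passage-time distributions from the absorbing master equation.

With the product set A made absorbing, the occupation probabilities of the
remaining nodes evolve under dP/dt = M P with M = K - D, where K holds the
inter-node rates and D the total escape rates.  For a reversible chain M is
similar to a symmetric matrix via the equilibrium weights, so its spectrum is
real and negative: M has eigenvalues -nu_l with nu_l > 0.  The probability
flux into A then gives the first-passage-time density as a sum of decaying
exponentials,

    p(t) = sum_l A_l exp(-nu_l t),      A_l = nu_l (1^T w_l^R)(w_l^L . P0),

normalized so that sum_l A_l / nu_l = 1.  This module provides the
decomposition, the density (in t and in y = ln t), its moments, and the
mean first passage time restricted to a finite observation window t_obs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.sparse.csgraph import connected_components

from .ktn import RateModel

__all__ = [
    "AbsorbingProblem",
    "SpectralFPT",
    "SpectralInstabilityError",
    "NoFeasibleEventsError",
    "build_absorbing_generator",
    "spectral_decompose",
    "fpt_density",
    "log_time_density",
    "fpt_moments",
    "truncated_mfpt",
    "partial_sum_mfpt",
]

# relative imaginary part / non-positivity tolerance beyond which the
# eigendecomposition is declared numerically unstable
_INSTABILITY_TOL = 1e-8


class SpectralInstabilityError(RuntimeError):
    """Eigendecomposition lost precision (typically at low temperature).

    The deterministic graph-transformation MFPT and the leapfrog kMC sampler
    remain reliable in this regime; use those instead.
    """


class NoFeasibleEventsError(RuntimeError):
    """No first-passage events are observable within the requested window."""


@dataclass
class AbsorbingProblem:
    """A first-passage problem: rate model + absorbing products + reactants.

    ``A`` is the absorbing (product) set, ``B`` the reactant set, and every
    other node is an intervening state.  ``P0`` maps node id -> initial
    occupation probability over the non-absorbing nodes; by default it is a
    delta on the single reactant (the convention used for all worked
    examples), or pass ``P0="boltzmann"`` for an equilibrium distribution
    restricted to B.
    """

    rm: RateModel
    A: frozenset[int]
    B: frozenset[int]
    P0: Mapping[int, float] | str | None = None
    p0_vec: np.ndarray = field(init=False, repr=False)
    nonabs: list[int] = field(init=False, repr=False)

    def __init__(self, rm: RateModel, A, B, P0=None):
        self.rm = rm
        self.A = frozenset(A)
        self.B = frozenset(B)
        if not self.A or not self.B:
            raise ValueError("A and B must be nonempty")
        if self.A & self.B:
            raise ValueError(f"A and B overlap: {sorted(self.A & self.B)}")
        unknown = (self.A | self.B) - set(rm.index)
        if unknown:
            raise ValueError(f"unknown node ids: {sorted(unknown)}")
        self.nonabs = [nid for nid in rm.node_ids if nid not in self.A]
        self._check_reachability()
        self.p0_vec = self._build_p0(P0)
        self.P0 = P0

    def _check_reachability(self) -> None:
        # every non-absorbing node must reach A through the undirected skeleton
        n = len(self.rm.node_ids)
        adj = (self.rm.K > 0) | (self.rm.K.T > 0)
        ncomp, labels = connected_components(adj, directed=False)
        abs_labels = {labels[self.rm.index[a]] for a in self.A}
        for nid in self.nonabs:
            if labels[self.rm.index[nid]] not in abs_labels:
                raise ValueError(f"node {nid} is disconnected from products")

    def _build_p0(self, P0) -> np.ndarray:
        pos = {nid: i for i, nid in enumerate(self.nonabs)}
        vec = np.zeros(len(self.nonabs))
        if P0 is None:
            if len(self.B) != 1:
                raise ValueError(
                    "default delta initial condition needs a single reactant; "
                    "pass P0 explicitly or use 'boltzmann'"
                )
            vec[pos[next(iter(self.B))]] = 1.0
        elif isinstance(P0, str):
            if P0 != "boltzmann":
                raise ValueError(f"unknown initial condition {P0!r}")
            for b in self.B:
                vec[pos[b]] = self.rm.pi[self.rm.index[b]]
            vec /= vec.sum()
        else:
            for nid, p in P0.items():
                if nid in self.A:
                    raise ValueError(f"initial probability on absorbing node {nid}")
                if p < 0:
                    raise ValueError(f"negative initial probability on node {nid}")
                vec[pos[nid]] = p
            s = vec.sum()
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"initial distribution sums to {s}, not 1")
        return vec


@dataclass
class SpectralFPT:
    """Eigenvalue/amplitude pairs defining p(t) = sum_l A_l exp(-nu_l t).

    ``nus`` are sorted ascending (slowest relaxation first) and amplitudes of
    numerically degenerate eigenvalues are merged.  ``meta`` records the
    problem (temperature, A, B, initial-condition description).
    """

    nus: np.ndarray
    amps: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return len(self.nus)


def build_absorbing_generator(ap: AbsorbingProblem) -> np.ndarray:
    """Assemble M = K - D over the non-absorbing nodes.

    Off-diagonal entries are the inter-node rates; the diagonal carries minus
    the *total* escape rate of each node, including flow into A, so columns
    of M sum to minus the rate into the absorbing set.
    """
    rm = ap.rm
    sel = [rm.index[nid] for nid in ap.nonabs]
    M = rm.K[np.ix_(sel, sel)].astype(float).copy()
    np.fill_diagonal(M, 0.0)
    total_escape = rm.K[:, sel].sum(axis=0)  # includes rates into A
    M[np.diag_indices_from(M)] = -total_escape
    return M


# networks up to this size use the extended-precision Jacobi eigensolver;
# larger ones fall back to LAPACK in double precision
_JACOBI_MAX_N = 150


def _jacobi_eigh(A: np.ndarray, max_sweeps: int = 60):
    """Cyclic Jacobi eigensolver in extended (long double) precision.

    LAPACK's symmetric solvers compute eigenvalues with *absolute* accuracy
    eps * ||A||, which ruins the tiny decay rates of deep kinetic traps;
    running the rotations in long double pushes the precision floor down by
    roughly three orders of magnitude, extending the temperature range over
    which the spectral MFPT matches graph transformation.  O(n^3) per sweep:
    intended for the small networks this package analyses, not large
    databases.
    """
    A = A.astype(np.longdouble).copy()
    n = A.shape[0]
    V = np.eye(n, dtype=np.longdouble)
    for _ in range(max_sweeps):
        off = np.sqrt(np.sum(np.tril(A, -1) ** 2))
        if off <= np.finfo(np.longdouble).eps * np.sqrt(np.sum(np.diag(A) ** 2)):
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                apq = A[p, q]
                if apq == 0.0:
                    continue
                theta = (A[q, q] - A[p, p]) / (2.0 * apq)
                if theta == 0.0:
                    t = 1.0
                else:
                    t = np.sign(theta) / (abs(theta) + np.sqrt(theta * theta + 1.0))
                c = 1.0 / np.sqrt(t * t + 1.0)
                s = t * c
                Ap, Aq = A[:, p].copy(), A[:, q].copy()
                A[:, p] = c * Ap - s * Aq
                A[:, q] = s * Ap + c * Aq
                Ap, Aq = A[p, :].copy(), A[q, :].copy()
                A[p, :] = c * Ap - s * Aq
                A[q, :] = s * Ap + c * Aq
                Vp, Vq = V[:, p].copy(), V[:, q].copy()
                V[:, p] = c * Vp - s * Vq
                V[:, q] = s * Vp + c * Vq
    order = np.argsort(np.diag(A))
    return np.diag(A)[order].copy(), V[:, order]


class _GTHSolver:
    """Subtraction-free LU solver for the absorbing generator.

    A = -M is a column-diagonally-dominant M-matrix whose off-diagonals are
    the (negated) inter-node rates and whose diagonal surplus is the
    absorption rate of each node.  Keeping that representation explicit lets
    Gaussian elimination proceed with additions and multiplications of
    positive quantities only (the trick behind the GTH algorithm and graph
    transformation), so solves with nonnegative right-hand sides are
    accurate componentwise regardless of how ill-conditioned A is.  Used to
    refine the slowest relaxation modes, whose tiny decay rates a dense
    eigensolver cannot resolve relative to the fast ones.
    """

    def __init__(self, K_off: np.ndarray, absorb: np.ndarray):
        n = len(absorb)
        Kw = K_off.astype(np.longdouble).copy()
        np.fill_diagonal(Kw, 0.0)
        rw = absorb.astype(np.longdouble).copy()
        self.n = n
        self.Lrate = np.zeros((n, n), dtype=np.longdouble)
        self.Urow = np.zeros((n, n), dtype=np.longdouble)
        self.Udiag = np.zeros(n, dtype=np.longdouble)
        for k in range(n):
            # diagonal recomputed from the column-sum invariant: remaining
            # off-diagonal rates plus absorption (never by subtraction)
            diag = Kw[k + 1:, k].sum() + rw[k]
            if diag <= 0:
                raise SpectralInstabilityError(
                    "singular absorbing generator (node with no escape)"
                )
            self.Udiag[k] = diag
            self.Urow[k, k + 1:] = Kw[k, k + 1:]
            self.Lrate[k + 1:, k] = Kw[k + 1:, k] / diag
            if k + 1 < n:
                sub = slice(k + 1, n)
                # redirect flow through k: j -> k -> i becomes j -> i, and
                # j -> k -> A adds to j's absorption; the j -> k -> j
                # round trip is the discarded self-loop (the diagonal
                # invariant accounts for it exactly)
                fill = np.outer(Kw[sub, k], Kw[k, sub]) / diag
                block = Kw[sub, sub]
                block += fill
                np.fill_diagonal(block, 0.0)
                Kw[sub, sub] = block
                rw[sub] += Kw[k, sub] * rw[k] / diag

    def _solve_nonneg(self, x: np.ndarray) -> np.ndarray:
        z = x.astype(np.longdouble).copy()
        n = self.n
        for i in range(n):
            z[i] = z[i] + self.Lrate[i, :i] @ z[:i]
        y = np.zeros(n, dtype=np.longdouble)
        for i in range(n - 1, -1, -1):
            y[i] = (z[i] + self.Urow[i, i + 1:] @ y[i + 1:]) / self.Udiag[i]
        return y

    def solve(self, x: np.ndarray) -> np.ndarray:
        """Solve A y = x.

        Nonnegative right-hand sides are solved componentwise stably; a
        general x is split into positive and negative parts, each solved
        stably, and recombined.
        """
        x = np.asarray(x, dtype=np.longdouble)
        if np.all(x >= 0):
            return self._solve_nonneg(x)
        return self._solve_nonneg(np.clip(x, 0, None)) - self._solve_nonneg(
            np.clip(-x, 0, None)
        )


def _refine_slow_modes(
    solver: _GTHSolver,
    sqrt_pi: np.ndarray,
    nus: np.ndarray,
    U: np.ndarray,
    n_refine: int,
    iters: int = 4,
):
    """Inverse-iteration refinement of the slowest eigenpairs.

    ``nus``/``U`` come from the dense eigensolver with columns in descending
    nu order (slowest last).  Each slow mode is polished by inverse power
    iteration against the stable solver, deflating previously refined modes
    by orthogonalization in the symmetrized coordinates; the refined decay
    rate is the inverse Rayleigh quotient of A^-1.  The slowest mode is
    positive (Perron), so its iterates never suffer cancellation; higher
    modes inherit accuracy from the deflation.
    """
    n = len(nus)
    n_refine = min(n_refine, n)
    basis: list[np.ndarray] = []
    for idx in range(n - 1, n - 1 - n_refine, -1):
        v = U[:, idx].astype(np.longdouble).copy()
        nu = nus[idx]
        for _ in range(iters):
            for b in basis:
                v -= (b @ v) * b
            norm = np.sqrt(v @ v)
            if norm == 0:
                break
            v /= norm
            w = solver.solve(v * sqrt_pi) / sqrt_pi  # A_sym^-1 v
            lam = v @ w
            if lam <= 0:
                break
            nu = 1.0 / lam
            v = w
        for b in basis:
            v -= (b @ v) * b
        v /= np.sqrt(v @ v)
        basis.append(v)
        nus[idx] = nu
        U[:, idx] = v
    return nus, U


def spectral_decompose(ap: AbsorbingProblem) -> SpectralFPT:
    """Eigendecompose the absorbing generator into {nu_l, A_l}.

    M is conjugated by diag(pi^1/2) into a symmetric matrix (valid under
    detailed balance) and solved symmetrically: an extended-precision Jacobi
    sweep for small networks, LAPACK otherwise, with a cross-check between
    the two solver routes on the overlap.  Real positive decay rates are
    required; if the spectrum is not cleanly real/positive the decomposition
    raises ``SpectralInstabilityError`` (use graph transformation or
    leapfrog kMC at such temperatures).
    """
    rm = ap.rm
    M = build_absorbing_generator(ap)
    sel = [rm.index[nid] for nid in ap.nonabs]
    sqrt_pi = np.sqrt(rm.pi[sel]).astype(np.longdouble)
    S = M.astype(np.longdouble) / sqrt_pi[:, None] * sqrt_pi[None, :]
    asym = float(np.abs(S - S.T).max())
    scale = float(max(np.abs(S).max(), 1.0))
    if asym > 1e-8 * scale:
        # detailed balance violated beyond round-off: fall back to the
        # general solver on M itself
        evals, R = np.linalg.eig(M)
        if np.abs(evals.imag).max() > _INSTABILITY_TOL * np.abs(evals.real).max():
            raise SpectralInstabilityError(
                "complex eigenvalues: network is not reversible enough for "
                "spectral analysis; use graph transformation / leapfrog kMC"
            )
        evals = evals.real
        R = R.real
        L = np.linalg.inv(R)
        amps_hp = None
    else:
        S = 0.5 * (S + S.T)
        if len(S) <= _JACOBI_MAX_N:
            evals_hp, U = _jacobi_eigh(S)
            # consistency check against the LAPACK route (coarse: LAPACK
            # itself is the less accurate of the two for graded spectra)
            evals_lp = np.linalg.eigh(S.astype(float))[0]
            if not np.allclose(
                np.sort(evals_hp.astype(float)), np.sort(evals_lp),
                rtol=1e-6, atol=1e-9 * scale,
            ):
                raise SpectralInstabilityError(
                    "Jacobi and LAPACK eigenvalues disagree: decomposition "
                    "unstable at this temperature"
                )
        else:
            evals_hp, U = np.linalg.eigh(S.astype(float))
            evals_hp = evals_hp.astype(np.longdouble)
            U = U.astype(np.longdouble)
        nus_hp = -evals_hp  # descending: slowest mode in the last column
        if np.all(nus_hp > 0) and len(S) > 1:
            # polish the slow tail of the spectrum with the stable solver;
            # dense eigensolvers only resolve these rates to an absolute
            # accuracy set by the fastest ones
            abs_rows = [rm.index[a] for a in ap.A]
            absorb = rm.K[np.ix_(abs_rows, sel)].sum(axis=0)
            solver = _GTHSolver(np.where(np.eye(len(S), dtype=bool), 0.0, M), absorb)
            nus_hp, U = _refine_slow_modes(
                solver, sqrt_pi, nus_hp, U, n_refine=min(6, len(S))
            )
        # right eigenvectors of M: diag(sqrt_pi) u; left: u^T diag(1/sqrt_pi)
        amps_hp = nus_hp * (U * sqrt_pi[:, None]).sum(axis=0) * (
            (U / sqrt_pi[:, None]).T @ ap.p0_vec.astype(np.longdouble)
        )
        evals = -nus_hp
        R = None

    if amps_hp is None:
        nus = -evals
        if nus.min() <= 0 or not np.all(np.isfinite(nus)):
            raise SpectralInstabilityError(
                f"non-positive decay rate nu={nus.min():.3e}: eigendecomposition "
                "numerically unstable (low temperature); use graph transformation "
                "or leapfrog kMC"
            )
        amps = nus * (R.sum(axis=0)) * (L @ ap.p0_vec)
    else:
        nus = (-evals).astype(float)
        if nus.min() <= 0 or not np.all(np.isfinite(nus)):
            raise SpectralInstabilityError(
                f"non-positive decay rate nu={nus.min():.3e}: eigendecomposition "
                "numerically unstable (low temperature); use graph transformation "
                "or leapfrog kMC"
            )
        amps = amps_hp.astype(float)

    # merge amplitudes of numerically degenerate eigenvalues
    order = np.argsort(nus)
    nus, amps = nus[order], amps[order]
    merged_nus, merged_amps = [], []
    for nu, a in zip(nus, amps):
        if merged_nus and abs(nu - merged_nus[-1]) <= 1e-10 * abs(nu):
            merged_amps[-1] += a
        else:
            merged_nus.append(nu)
            merged_amps.append(a)
    nus = np.array(merged_nus)
    amps = np.array(merged_amps)

    norm = float(np.sum(amps / nus))
    if abs(norm - 1.0) > 1e-8:
        raise SpectralInstabilityError(
            f"amplitude normalization sum A_l/nu_l = {norm!r} deviates from 1; "
            "eigendecomposition unstable at this temperature"
        )

    meta = {
        "temperature": rm.temperature,
        "A": sorted(ap.A),
        "B": sorted(ap.B),
        "initial_condition": (
            "boltzmann(B)" if ap.P0 == "boltzmann"
            else "delta" if ap.P0 is None
            else "custom"
        ),
    }
    return SpectralFPT(nus, amps, meta)


def fpt_density(sp: SpectralFPT, t) -> np.ndarray | float:
    """p(t) = sum_l A_l exp(-nu_l t); vectorizes over a t grid."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    vals = np.exp(-np.outer(t_arr.ravel(), sp.nus)) @ sp.amps
    return float(vals[0]) if t_arr.ndim == 0 else vals.reshape(t_arr.shape)


def log_time_density(sp: SpectralFPT, y) -> np.ndarray | float:
    """Density of y = ln t: p~(y) = e^y p(e^y).

    The log-time form separates well-split relaxation time scales into
    distinct peaks, one per kinetic trap.
    """
    y_arr = np.asarray(y, dtype=float)
    t = np.exp(y_arr)
    vals = t.ravel() * (np.exp(-np.outer(t.ravel(), sp.nus)) @ sp.amps)
    return float(vals[0]) if y_arr.ndim == 0 else vals.reshape(y_arr.shape)


def fpt_moments(sp: SpectralFPT, n: int = 1) -> float:
    """<t^n> = n! sum_l A_l / nu_l^(n+1).  n=1 gives the MFPT."""
    if n < 1:
        raise ValueError("moment order must be >= 1")
    from math import factorial

    return float(factorial(n) * np.sum(sp.amps / sp.nus ** (n + 1)))


def truncated_mfpt(sp: SpectralFPT, t_obs: float, z_floor: float = 1e-300):
    """MFPT restricted to events completing within the observation window.

    Returns ``(<t>_obs, z)`` where z(t_obs) = sum_l (A_l/nu_l)(1 - e^{-nu_l
    t_obs}) is the fraction of feasible events and

        <t>_obs = (1/z) * sum_l A_l [1/nu_l^2 - e^{-nu_l t_obs}
                                     (t_obs/nu_l + 1/nu_l^2)].

    As t_obs -> inf this converges to the unrestricted MFPT with z -> 1.
    Raises ``NoFeasibleEventsError`` when z underflows (no transformation is
    observable on that time scale) instead of returning NaN.
    """
    if t_obs <= 0:
        raise ValueError("t_obs must be positive")
    nus, amps = sp.nus, sp.amps
    x = nus * t_obs
    # z per mode: (A/nu)(1 - e^-x), stable via expm1
    z_terms = amps / nus * (-np.expm1(-x))
    z = float(z_terms.sum())
    # integral of t p(t) per mode: (A/nu^2) f(x) with f(x) = 1 - (1+x)e^-x;
    # the direct form cancels catastrophically for x << 1 (f ~ x^2/2 against
    # terms of size 1), so switch to the series there
    f = np.where(
        x > 1e-2,
        1.0 - (1.0 + x) * np.exp(-x),
        x * x * (0.5 - x / 3.0 + x * x / 8.0 - x**3 / 30.0),
    )
    num_terms = amps / nus**2 * f
    num = float(num_terms.sum())
    # mixed-sign amplitudes cancel almost exactly at short observation
    # windows; once the surviving signal is below the round-off of the
    # cancelling terms, no events are resolvable in the window
    resolvable = (
        z > 1e-9 * np.abs(z_terms).sum()
        and num > 1e-9 * np.abs(num_terms).sum()
    )
    if z <= z_floor or not resolvable:
        raise NoFeasibleEventsError(
            f"z(t_obs={t_obs:g}) = {z:g}: no feasible events within window"
        )
    return num / z, z


def partial_sum_mfpt(sp: SpectralFPT, keep: int) -> float:
    """MFPT from the ``keep`` fastest relaxation modes only.

    Modes are dropped from the slow end first (the fastest mode is dropped
    last), and the restricted spectrum carries its own normalization:

        <t>_keep = sum_keep(A_l/nu_l^2) / sum_keep(A_l/nu_l).

    With keep = n_modes this is the exact MFPT.  The sequence keep = l_max,
    l_max-1, ... predicts the plateau heights of <t>_obs between successive
    relaxation times: each step in the observation-time scan corresponds to
    one more slow mode becoming feasible.
    """
    if not 1 <= keep <= sp.n_modes:
        raise ValueError(f"keep must be in [1, {sp.n_modes}]")
    # nus sorted ascending: the fastest `keep` modes are the trailing ones
    nus = sp.nus[sp.n_modes - keep:]
    amps = sp.amps[sp.n_modes - keep:]
    return float(np.sum(amps / nus**2) / np.sum(amps / nus))
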