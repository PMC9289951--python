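"""Stochastic first-passage-time sampling: standard and leapfrog kMC.

Standard rejection-free kMC draws the next node from the branching
probabilities and the residence time from the Poisson escape distribution
``-tau ln x``.  Low internal barriers make adjacent minima "flicker" — the
walker recrosses the same edge enormous numbers of times — which stalls the
standard algorithm.  Leapfrog kMC removes the flicker analytically: from the
current node i it samples the total number N of i<->j recrossings from a
geometric law with parameter

    beta_i = sum_{j not absorbing} P[j, i] P[i, j],

allocates the N recrossings over the neighbors j (multinomially, or by a
multivariate-normal approximation when N is large), accumulates their waiting
time ``sum_j n_j (tau_i + tau_j)``, and then exits directly to a second
neighbor or adjacent absorbing node with renormalized probabilities.  Each
recrossing accounts for two implicit kMC steps, so the dynamical activity s
is preserved in expectation, and the renormalized waiting time conserves the
mean first passage time exactly.

Ensemble runners are vectorized over walkers (synchronous stepping, grouped
by current node) so that hundreds of thousands of trajectories complete in
seconds; the scalar ``kmc_step`` / ``leapfrog_step`` operations are the
reference implementations the vectorized path is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .ktn import RateModel
from .spectral import AbsorbingProblem

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "FPTSample",
    "FPTEnsemble",
    "LeapfrogTable",
    "kmc_step",
    "run_standard_kmc",
    "compute_beta",
    "sample_recross_count",
    "allocate_recrossings",
    "leapfrog_step",
    "run_leapfrog_kmc",
]

# beta above which the multinomial allocation may switch to its
# multivariate-normal approximation, provided the sampled N is also large
MULTINORMAL_BETA = 0.95
MULTINORMAL_MIN_N = 1000

DEFAULT_STEP_BUDGET = 10**9  # conventional steps per standard-kMC trajectory
# leapfrog collapses recrossings analytically, so its wall cost does not grow
# with the implicit step count; deep-trap trajectories legitimately exceed
# 10^15 conventional-equivalent steps
DEFAULT_LEAPFROG_STEP_BUDGET = 10**15
DEFAULT_THRESHOLD = 0.5      # leapfrog engaged when beta_i exceeds this


@dataclass(frozen=True)
class FPTSample:
    """One first-passage event: time t, step count s, landing node, stream."""

    t: float
    s: int
    path_end: int
    seed: int


@dataclass
class FPTEnsemble:
    """A batch of sampled first-passage events from one engine.

    Censored trajectories (step budget exhausted before absorption) are kept
    but excluded from the accessor arrays; their count is reported via
    ``n_censored``.
    """

    t_all: np.ndarray
    s_all: np.ndarray
    end_all: np.ndarray
    censored: np.ndarray
    engine: str
    config: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.t_all[~self.censored]

    @property
    def s(self) -> np.ndarray:
        return self.s_all[~self.censored]

    @property
    def end(self) -> np.ndarray:
        return self.end_all[~self.censored]

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    def __len__(self) -> int:
        return len(self.t_all)

    def samples(self) -> list[FPTSample]:
        seed = self.config.get("seed", -1)
        return [
            FPTSample(float(t), int(s), int(e), seed)
            for t, s, e in zip(self.t, self.s, self.end)
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t_all,
                "s": self.s_all,
                "end_node": self.end_all,
                "censored": self.censored,
            }
        )


# ---------------------------------------------------------------------------
# standard kMC
# ---------------------------------------------------------------------------

def kmc_step(rm: RateModel, current: int, rng: np.random.Generator):
    """One rejection-free move: (next node, waiting time).

    The target is drawn from the branching probabilities of the current node
    and the residence time from ``-tau ln x`` with x uniform on (0, 1].
    """
    j = rm.index[current]
    col = rm.P[:, j]
    tot = col.sum()
    if tot <= 0:
        raise ValueError(f"node {current} has no outgoing transitions")
    nxt = int(np.searchsorted(np.cumsum(col), rng.random() * tot, side="right"))
    nxt = min(nxt, len(col) - 1)
    x = 1.0 - rng.random()  # uniform on (0, 1]
    waiting = -rm.tau[j] * np.log(x)
    return rm.node_ids[nxt], float(waiting)


def _start_indices(ap: AbsorbingProblem, n_runs: int, rng: np.random.Generator):
    """Draw n_runs start nodes (matrix indices) from the initial distribution."""
    rm = ap.rm
    ids = np.array([rm.index[nid] for nid in ap.nonabs])
    return ids[rng.choice(len(ids), size=n_runs, p=ap.p0_vec)]


@_njit(cache=True, fastmath=True)
def _standard_kmc_kernel(cum_probs, targets, degree, tau, abs_mask, start,
                         max_steps, seed):
    """Per-walker rejection-free kMC loop (compiled).

    Each source node j carries a compact target list: ``targets[j, :degree[j]]``
    with cumulative branching probabilities ``cum_probs[j, :degree[j]]``.
    Randomness comes from an inline xorshift128+ stream (its state
    initialized from ``seed`` by two rounds of splitmix64), which is several
    times faster than a library generator call per hop and deterministic
    given the seed.
    """
    # splitmix64 state initialization
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    s0 = z ^ (z >> np.uint64(31))
    z = s0 + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    s1 = z ^ (z >> np.uint64(31))

    inv = 1.0 / 9007199254740992.0  # 2^-53
    n_runs = start.shape[0]
    t = np.zeros(n_runs)
    s = np.zeros(n_runs, dtype=np.int64)
    end = np.full(n_runs, -1, dtype=np.int64)
    cens = np.zeros(n_runs, dtype=np.bool_)
    for w in range(n_runs):
        cur = start[w]
        tw = 0.0
        sw = 0
        while True:
            # xorshift128+ draw for the target
            x = s0
            y = s1
            s0 = y
            x ^= x << np.uint64(23)
            s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
            u = np.float64((s1 + y) >> np.uint64(11)) * inv
            deg = degree[cur]
            k = 0
            while k < deg - 1 and cum_probs[cur, k] < u:
                k += 1
            # second draw for the Poisson waiting time -tau ln x, x in (0,1]
            x = s0
            y = s1
            s0 = y
            x ^= x << np.uint64(23)
            s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
            u = np.float64((s1 + y) >> np.uint64(11)) * inv
            tw += -tau[cur] * np.log(1.0 - u)
            sw += 1
            cur = targets[cur, k]
            if abs_mask[cur]:
                end[w] = cur
                break
            if sw >= max_steps:
                cens[w] = True
                break
        t[w] = tw
        s[w] = sw
    return t, s, end, cens


def _compact_branching(P: np.ndarray):
    """Pad per-source target lists and cumulative probabilities."""
    n = P.shape[0]
    deg = (P > 0).sum(axis=0).astype(np.int64)
    kmax = max(int(deg.max()), 1)
    targets = np.zeros((n, kmax), dtype=np.int64)
    cum = np.ones((n, kmax))
    for j in range(n):
        tj = np.flatnonzero(P[:, j])
        if len(tj):
            targets[j, : len(tj)] = tj
            cum[j, : len(tj)] = np.cumsum(P[tj, j])
    return cum, targets, deg


def run_standard_kmc(
    ap: AbsorbingProblem,
    n_runs: int,
    rng: np.random.Generator | int,
    max_steps: int = DEFAULT_STEP_BUDGET,
) -> FPTEnsemble:
    """Sample n_runs first-passage times by standard rejection-free kMC.

    Trajectories exceeding ``max_steps`` are flagged censored rather than
    silently truncated — at low temperature the step count diverges and the
    censoring count is the honest diagnostic.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rm = ap.rm
    n = len(rm.node_ids)
    abs_mask = np.zeros(n, dtype=bool)
    for a in ap.A:
        abs_mask[rm.index[a]] = True
    cum, targets, deg = _compact_branching(rm.P)
    tau = np.ascontiguousarray(rm.tau)

    start = _start_indices(ap, n_runs, rng).astype(np.int64)
    seed = int(rng.integers(2**31 - 1))
    t, s, end, censored = _standard_kmc_kernel(
        cum, targets, deg, tau, abs_mask, start, np.int64(max_steps), seed
    )

    node_ids = np.array(rm.node_ids)
    end_ids = np.where(end >= 0, node_ids[np.maximum(end, 0)], -1)
    return FPTEnsemble(
        t, s, end_ids, np.asarray(censored, dtype=bool), "standard",
        {"n_runs": n_runs, "max_steps": max_steps, "seed_stream": seed,
         "temperature": rm.temperature},
    )


# ---------------------------------------------------------------------------
# leapfrog tables
# ---------------------------------------------------------------------------

@dataclass
class LeapfrogTable:
    """Renormalized transition data for leapfrog moves out of node i.

    ``beta`` is the single-recrossing probability summed over non-absorbing
    neighbors; ``one_minus_beta`` is computed by the stable identity (a sum
    of positive path probabilities, never the subtraction 1 - beta, which
    loses precision as beta -> 1).  ``q`` is the conditional distribution of
    a recrossing over the neighbors, ``recross_wait`` the per-neighbor
    waiting times tau_i + tau_j, and the exit channels enumerate every
    two-hop path i -> j -> k (k != i) plus every direct hop to an adjacent
    absorbing node, with renormalized probabilities summing to one.
    """

    node: int
    beta: float
    one_minus_beta: float
    neighbors: np.ndarray          # non-absorbing neighbor indices (matrix order)
    q: np.ndarray                  # conditional recrossing distribution
    recross_wait: np.ndarray       # tau_i + tau_j per neighbor
    exit_node: np.ndarray          # landing node per channel (matrix index)
    exit_via: np.ndarray           # intermediate j per channel, -1 for direct
    exit_prob: np.ndarray          # renormalized channel probabilities
    tau_lf: float                  # renormalized mean waiting per move
    mean_recross_wait: float       # sum_j q_j (tau_i + tau_j)
    node_ids: tuple[int, ...] = ()  # matrix-order node ids, for reporting

    @property
    def lf_probs(self) -> dict[int, float]:
        """Exit probabilities aggregated by landing node id (sum to 1)."""
        out: dict[int, float] = {}
        for node, p in zip(self.exit_node, self.exit_prob):
            nid = int(self.node_ids[node]) if self.node_ids else int(node)
            out[nid] = out.get(nid, 0.0) + float(p)
        return out


def compute_beta(rm: RateModel, ap: AbsorbingProblem, i: int) -> LeapfrogTable:
    """Build the leapfrog table for non-absorbing node i.

    Raises if beta_i reaches 1 to within floating precision, i.e. the node
    and a neighbor form a closed flickering pair with no escape.
    """
    if i in ap.A:
        raise ValueError(f"node {i} is absorbing")
    ii = rm.index[i]
    P, tau = rm.P, rm.tau
    abs_idx = {rm.index[a] for a in ap.A}

    targets = np.flatnonzero(P[:, ii])
    nonabs_nb = np.array([j for j in targets if j not in abs_idx], dtype=np.int64)
    abs_nb = np.array([j for j in targets if j in abs_idx], dtype=np.int64)

    beta = float(np.sum(P[nonabs_nb, ii] * P[ii, nonabs_nb])) if len(nonabs_nb) else 0.0

    # stable 1 - beta: direct absorption plus two-hop non-return paths,
    # accumulated term by term (never via a subtraction that cancels when
    # the return probability approaches 1)
    omb = float(np.sum(P[abs_nb, ii]))
    for j in nonabs_nb:
        col = P[:, j].copy()
        col[ii] = 0.0
        omb += float(P[j, ii]) * float(col.sum())
    if omb <= 0.0:
        partner = rm.node_ids[nonabs_nb[0]] if len(nonabs_nb) else None
        raise FloatingPointError(
            f"beta = 1 at node {i} (flickering pair with {partner}): no escape"
        )

    q = (P[nonabs_nb, ii] * P[ii, nonabs_nb]) / beta if beta > 0 else np.zeros(0)
    recross_wait = tau[ii] + tau[nonabs_nb] if len(nonabs_nb) else np.zeros(0)

    exit_node, exit_via, exit_prob = [], [], []
    for j in abs_nb:
        exit_node.append(j)
        exit_via.append(-1)
        exit_prob.append(float(P[j, ii]) / omb)
    for j in nonabs_nb:
        ks = np.flatnonzero(P[:, j])
        for k in ks:
            if k == ii:
                continue
            exit_node.append(k)
            exit_via.append(j)
            exit_prob.append(float(P[k, j] * P[j, ii]) / omb)

    exit_prob = np.array(exit_prob)
    exit_prob /= exit_prob.sum()  # conservation holds exactly after this
    tau_lf = float((tau[ii] + np.sum(P[nonabs_nb, ii] * tau[nonabs_nb])) / omb)
    mean_rw = float(np.sum(q * recross_wait)) if beta > 0 else 0.0
    return LeapfrogTable(
        node=i,
        beta=beta,
        one_minus_beta=omb,
        neighbors=nonabs_nb,
        q=np.asarray(q, dtype=float),
        recross_wait=np.asarray(recross_wait, dtype=float),
        exit_node=np.array(exit_node, dtype=np.int64),
        exit_via=np.array(exit_via, dtype=np.int64),
        exit_prob=exit_prob,
        tau_lf=tau_lf,
        mean_recross_wait=mean_rw,
        node_ids=tuple(rm.node_ids),
    )


# ---------------------------------------------------------------------------
# recrossing samplers
# ---------------------------------------------------------------------------

def sample_recross_count(
    beta: float, rng: np.random.Generator, one_minus_beta: float | None = None
) -> int:
    """Sample the total recrossing count N ~ Geometric: P(N=n) = (1-beta) beta^n.

    Inverts the closed-form CDF P(N <= n) = 1 - beta^(n+1): with x uniform
    on [0, 1), the continuous inverse ln(1-x)/ln(beta) - 1 is rounded up to
    the next integer (so P(N <= n) matches the CDF identity exactly, and an
    x that lands on a CDF value inverts to that count).  When a stably
    computed 1 - beta is supplied, ln(beta) is evaluated as log1p(-(1-beta)),
    which stays accurate (and finite) for beta within one ulp of 1, where
    beta itself rounds to 1.0 and the naive logarithm would produce an
    endless walk.
    """
    if one_minus_beta is None:
        one_minus_beta = 1.0 - beta
    if beta < 0.0 or one_minus_beta <= 0.0:
        raise ValueError(f"beta must be in [0, 1), got {beta} (1-beta={one_minus_beta})")
    if beta == 0.0:
        return 0
    x = rng.random()
    return max(int(np.ceil(np.log1p(-x) / np.log1p(-one_minus_beta))) - 1, 0)


def _multinormal_counts(N: int, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaussian approximation to Multinomial(N, q) for large N.

    Sampled as N q + sqrt(N) diag(u) Q z with u_a = sqrt(q_a), z a vector of
    m-1 standard normals (last component zero), and Q the Householder
    reflection I - 2 v v^T whose final column is u.  This reproduces the
    multinomial mean N q and covariance N (diag(q) - q q^T).  Components are
    rounded, clipped at zero, and the total repaired to N by
    largest-remainder adjustment.
    """
    m = len(q)
    u = np.sqrt(q)
    z = np.zeros(m)
    z[: m - 1] = rng.standard_normal(m - 1)
    e = np.zeros(m)
    e[m - 1] = 1.0
    v = e - u
    nv = np.linalg.norm(v)
    if nv > 1e-14:
        v /= nv
        Qz = z - 2.0 * v * (v @ z)
    else:
        Qz = z
    x = N * q + np.sqrt(N) * u * Qz
    counts = np.rint(np.clip(x, 0.0, None)).astype(np.int64)
    diff = N - counts.sum()
    if diff != 0:
        # largest-remainder repair: adjust the components whose continuous
        # values are farthest from their rounded counts, never below zero
        resid = x - counts
        order = np.argsort(-resid if diff > 0 else resid)
        i = 0
        step = 1 if diff > 0 else -1
        while diff != 0:
            j = order[i % m]
            if step < 0 and counts[j] == 0:
                i += 1
                continue
            counts[j] += step
            diff -= step
            i += 1
    return counts


def allocate_recrossings(
    N: int,
    q: np.ndarray,
    rng: np.random.Generator,
    beta: float = 0.0,
    force: str | None = None,
) -> np.ndarray:
    """Distribute N recrossings over neighbors with probabilities q.

    Exact multinomial sampling by default; the multivariate-normal
    approximation is used when beta exceeds 0.95 *and* N exceeds 1000 (the
    approximation is only accurate at large N).  ``force`` overrides the
    choice ("multinomial" or "multinormal") for validation.  A single
    neighbor receives all N directly.
    """
    q = np.asarray(q, dtype=float)
    if N < 0:
        raise ValueError("N must be nonnegative")
    if len(q) == 0:
        if N > 0:
            raise ValueError("no neighbors to allocate recrossings to")
        return np.zeros(0, dtype=np.int64)
    if len(q) == 1:
        return np.array([N], dtype=np.int64)
    if N == 0:
        return np.zeros(len(q), dtype=np.int64)
    use_normal = (
        force == "multinormal"
        if force is not None
        else (beta > MULTINORMAL_BETA and N > MULTINORMAL_MIN_N)
    )
    if use_normal:
        return _multinormal_counts(N, q, rng)
    return rng.multinomial(N, q).astype(np.int64)


def leapfrog_step(
    ap: AbsorbingProblem,
    table: LeapfrogTable,
    rng: np.random.Generator,
    mean_waiting: bool = False,
):
    """One leapfrog move: (exit node id, total waiting time, implicit steps).

    Samples the recrossing count, allocates it over neighbors, accumulates
    the recrossing waiting time (per-neighbor n_j (tau_i + tau_j), or
    N times the mean single-recrossing waiting when ``mean_waiting``), then
    exits through a renormalized channel with Poisson-sampled hop times.
    """
    rm = ap.rm
    N = sample_recross_count(table.beta, rng, table.one_minus_beta)
    if mean_waiting:
        wait = N * table.mean_recross_wait
    else:
        counts = allocate_recrossings(N, table.q, rng, beta=table.beta)
        wait = float(counts @ table.recross_wait) if len(counts) else 0.0

    u = rng.random()
    ch = int(np.searchsorted(np.cumsum(table.exit_prob), u, side="right"))
    ch = min(ch, len(table.exit_prob) - 1)
    via = table.exit_via[ch]
    dest = table.exit_node[ch]
    ii = rm.index[table.node]
    wait += -rm.tau[ii] * np.log(1.0 - rng.random())
    hops = 1
    if via >= 0:
        wait += -rm.tau[via] * np.log(1.0 - rng.random())
        hops = 2
    return rm.node_ids[dest], float(wait), int(2 * N + hops)


# ---------------------------------------------------------------------------
# leapfrog ensemble runner (vectorized)
# ---------------------------------------------------------------------------

def run_leapfrog_kmc(
    ap: AbsorbingProblem,
    n_runs: int,
    rng: np.random.Generator | int,
    threshold: float = DEFAULT_THRESHOLD,
    max_steps: int = DEFAULT_LEAPFROG_STEP_BUDGET,
    mean_waiting: bool = False,
) -> FPTEnsemble:
    """Sample first-passage times with leapfrog moves where beta_i > threshold.

    Nodes below the threshold advance by standard kMC steps.  Any threshold
    in (0, 1) gives statistically indistinguishable ensembles; 0.5 is the
    default.  Tables are built once per node (they depend only on the rate
    model and the absorbing set).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rm = ap.rm
    n = len(rm.node_ids)
    abs_mask = np.zeros(n, dtype=bool)
    for a in ap.A:
        abs_mask[rm.index[a]] = True
    cumP = np.cumsum(rm.P, axis=0)
    tau = rm.tau

    tables: dict[int, LeapfrogTable | None] = {}
    cum_exit: dict[int, np.ndarray] = {}
    for nid in ap.nonabs:
        tbl = compute_beta(rm, ap, nid)
        if tbl.beta > threshold:
            tables[rm.index[nid]] = tbl
            cum_exit[rm.index[nid]] = np.cumsum(tbl.exit_prob)
        else:
            tables[rm.index[nid]] = None

    current = _start_indices(ap, n_runs, rng)
    t = np.zeros(n_runs)
    s = np.zeros(n_runs, dtype=np.int64)
    end = np.full(n_runs, -1, dtype=np.int64)
    censored = np.zeros(n_runs, dtype=bool)
    active = np.ones(n_runs, dtype=bool)

    while active.any():
        act_idx = np.flatnonzero(active)
        for node in np.unique(current[act_idx]):
            idx = act_idx[current[act_idx] == node]
            m = len(idx)
            tbl = tables[int(node)]
            if tbl is None:
                # standard kMC step for this group
                u = rng.random(m)
                nxt = (cumP[:, node][:, None] < u[None, :]).sum(axis=0)
                nxt = np.minimum(nxt, n - 1)
                t[idx] += -tau[node] * np.log(1.0 - rng.random(m))
                s[idx] += 1
                current[idx] = nxt
                continue

            # recrossing counts (stable log for beta within an ulp of 1)
            if tbl.beta > 0:
                x = rng.random(m)
                N = np.maximum(
                    np.ceil(
                        np.log1p(-x) / np.log1p(-tbl.one_minus_beta)
                    ).astype(np.int64) - 1,
                    0,
                )
            else:
                N = np.zeros(m, dtype=np.int64)

            if mean_waiting:
                t[idx] += N * tbl.mean_recross_wait
            elif len(tbl.neighbors) == 1:
                t[idx] += N * tbl.recross_wait[0]
            elif len(tbl.neighbors) > 1:
                big = (tbl.beta > MULTINORMAL_BETA) & (N > MULTINORMAL_MIN_N)
                small = ~big
                if small.any():
                    counts = rng.multinomial(N[small], tbl.q)
                    t[idx[small]] += counts @ tbl.recross_wait
                for w in np.flatnonzero(big):
                    counts = _multinormal_counts(int(N[w]), tbl.q, rng)
                    t[idx[w]] += counts @ tbl.recross_wait
            s[idx] += 2 * N

            # exit channels
            u = rng.random(m)
            ch = np.searchsorted(cum_exit[int(node)], u, side="right")
            ch = np.minimum(ch, len(tbl.exit_prob) - 1)
            via = tbl.exit_via[ch]
            dest = tbl.exit_node[ch]
            t[idx] += -tau[node] * np.log(1.0 - rng.random(m))
            s[idx] += 1
            two = via >= 0
            if two.any():
                t[idx[two]] += -tau[via[two]] * np.log(1.0 - rng.random(two.sum()))
                s[idx[two]] += 1
            current[idx] = dest

        # bookkeeping: absorption and step budget
        idx = np.flatnonzero(active)
        hit = abs_mask[current[idx]]
        done = idx[hit]
        end[done] = current[done]
        active[done] = False
        rest = idx[~hit]
        over = rest[s[rest] >= max_steps]
        censored[over] = True
        active[over] = False

    node_ids = np.array(rm.node_ids)
    end_ids = np.where(end >= 0, node_ids[np.maximum(end, 0)], -1)
    return FPTEnsemble(
        t, s, end_ids, censored, "leapfrog",
        {"n_runs": n_runs, "threshold": threshold, "max_steps": max_steps,
         "mean_waiting": mean_waiting, "temperature": rm.temperature},
    )
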