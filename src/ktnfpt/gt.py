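"""Graph transformation: deterministic mean first passage times.

Intervening nodes are eliminated one at a time; each removal renormalizes the
branching probabilities and waiting times of the survivors so that the mean
first passage time to the absorbing set is preserved exactly:

    P'[b, a] = P[b, a] + P[b, x] P[x, a] / (1 - P[x, x])
    tau'[a]  = tau[a] + P[x, a] tau[x] / (1 - P[x, x])

(matrix entries are target-from-source, so P[x, a] is the probability of
hopping from a to x).  Because only sums, products and one well-conditioned
division appear, the procedure stays accurate at temperatures where the
eigendecomposition loses precision — it is the stable reference for every
other MFPT estimate in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import AbsorbingProblem

__all__ = ["GTNetwork", "gt_remove_node", "gt_mfpt"]


@dataclass
class GTNetwork:
    """Working state of a graph transformation.

    ``P`` is column-stochastic over all nodes (absorbing targets included);
    self-loop entries P[x, x] start at zero and grow as neighbors of x are
    eliminated.  ``alive`` marks nodes not yet removed; absorbing nodes are
    retained as targets but never removed.
    """

    node_ids: list[int]
    P: np.ndarray
    tau: np.ndarray
    absorbing: frozenset[int]
    alive: np.ndarray  # bool mask over node order
    index: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {nid: i for i, nid in enumerate(self.node_ids)}

    @classmethod
    def from_problem(cls, ap: AbsorbingProblem) -> "GTNetwork":
        rm = ap.rm
        n = len(rm.node_ids)
        P = rm.P.copy()
        tau = rm.tau.copy()
        # absorbing nodes emit nothing and wait forever; keep them as sinks
        for a in ap.A:
            i = rm.index[a]
            P[:, i] = 0.0
            tau[i] = 0.0
        return cls(
            node_ids=list(rm.node_ids),
            P=P,
            tau=tau,
            absorbing=frozenset(ap.A),
            alive=np.ones(n, dtype=bool),
        )

    def copy(self) -> "GTNetwork":
        return GTNetwork(
            self.node_ids, self.P.copy(), self.tau.copy(),
            self.absorbing, self.alive.copy(), dict(self.index),
        )


def gt_remove_node(net: GTNetwork, x: int) -> GTNetwork:
    """Eliminate non-absorbing node x in place, renormalizing survivors.

    Raises if x is absorbing, already removed, or an effective trap
    (1 - P[x, x] underflows, meaning escape from x is numerically impossible).
    """
    ix = net.index[x]
    if x in net.absorbing:
        raise ValueError(f"cannot remove absorbing node {x}")
    if not net.alive[ix]:
        raise ValueError(f"node {x} already removed")
    # 1 - P_xx via the column-stochastic invariant (sum over all other
    # targets): direct subtraction cancels catastrophically once x has
    # absorbed its flickering neighbors and P_xx -> 1
    col = net.P[:, ix].copy()
    col[ix] = 0.0
    denom = float(col.sum())
    if denom <= 0.0 or not np.isfinite(denom):
        raise FloatingPointError(
            f"node {x}: 1 - P_xx underflowed ({denom!r}); node is an "
            "absorbing trap artifact"
        )
    live = net.alive.copy()
    live[ix] = False
    src = np.where(live & ~np.isin(np.arange(len(net.node_ids)),
                                   [net.index[a] for a in net.absorbing]))[0]
    # survivors a that fed x inherit x's outgoing flow and waiting time
    px_from = net.P[ix, src] / denom          # P[x, a]/(1-Pxx) per source a
    net.tau[src] += px_from * net.tau[ix]
    net.P[:, src] += np.outer(net.P[:, ix], px_from)
    net.P[ix, :] = 0.0
    net.P[:, ix] = 0.0
    net.alive[ix] = False
    return net


def _absorb_node(net: GTNetwork, b: int) -> float:
    """MFPT from b once b is the only live non-absorbing node."""
    ib = net.index[b]
    col = net.P[:, ib].copy()
    col[ib] = 0.0
    denom = float(col.sum())  # stable 1 - P_bb: flow to the absorbing set
    if denom <= 0.0:
        raise FloatingPointError(f"source {b} cannot escape (1-P_bb={denom!r})")
    return float(net.tau[ib] / denom)


def gt_mfpt(ap: AbsorbingProblem) -> tuple[float, dict[int, float]]:
    """Exact MFPT to A from every source in the initial distribution.

    All intervening nodes are eliminated (greedy minimum-degree order to
    limit fill-in); then, for each source node b carrying initial
    probability, the remaining non-absorbing nodes other than b are
    eliminated in a per-source copy and T_b is read off as
    tau'_b / (1 - P'_bb).  Returns ``(sum_b P0_b T_b, {b: T_b})``.
    """
    base = GTNetwork.from_problem(ap)
    abs_idx = {base.index[a] for a in ap.A}
    sources = [nid for nid, p in zip(ap.nonabs, ap.p0_vec) if p > 0]
    keep = {base.index[s] for s in sources}

    # shared phase: remove all nodes that are neither absorbing nor sources
    def degree(g: GTNetwork, i: int) -> int:
        adj = (g.P[i, :] > 0) | (g.P[:, i] > 0)
        adj[i] = False
        return int(np.count_nonzero(adj & g.alive))

    net = base
    while True:
        cands = [
            i for i in range(len(net.node_ids))
            if net.alive[i] and i not in abs_idx and i not in keep
        ]
        if not cands:
            break
        x = min(cands, key=lambda i: degree(net, i))
        gt_remove_node(net, net.node_ids[x])

    waits: dict[int, float] = {}
    for b in sources:
        sub = net.copy()
        others = [
            sub.node_ids[i] for i in range(len(sub.node_ids))
            if sub.alive[i] and i not in abs_idx and sub.node_ids[i] != b
        ]
        for nid in others:
            gt_remove_node(sub, nid)
        waits[b] = _absorb_node(sub, b)

    p0 = {nid: p for nid, p in zip(ap.nonabs, ap.p0_vec)}
    mfpt = float(sum(p0[b] * waits[b] for b in sources))
    return mfpt, waits
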