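"""Kinetic transition networks and their Markov-chain rate models.

A kinetic transition network (KTN) is a weighted multigraph whose nodes are
local minima of an energy landscape and whose edges are the transition states
connecting them.  Given a temperature, the network is converted into a
continuous-time Markov chain: directed rate constants ``k[i, j]`` (probability
flow *to* i *from* j), mean waiting times ``tau[j] = 1 / sum_i k[i, j]``,
branching probabilities ``P[i, j] = k[i, j] * tau[j]`` and equilibrium
occupation probabilities ``pi[j]``.

Units: the Boltzmann constant is 1, so temperature is measured in the same
units as energy; time is measured in inverse units of the (unit) rate
prefactor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Minimum",
    "TransitionState",
    "KTN",
    "RateModel",
    "validate_ktn",
    "build_rate_model",
    "branching_and_waiting",
]


# ---------------------------------------------------------------------------
# network data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Minimum:
    """A local minimum (network node).

    Parameters
    ----------
    id
        Integer node id, unique within a network.
    energy
        Potential (or free) energy of the minimum, in model energy units.
    log_freq_product
        Log product of normal-mode frequencies, used in the harmonic rate
        expression.  Zero by default (unit prefactor convention).
    pg_order
        Point-group order; enters the equilibrium weight as ``1 / pg_order``.
    """

    id: int
    energy: float
    log_freq_product: float = 0.0
    pg_order: int = 1


@dataclass(frozen=True)
class TransitionState:
    """A transition state (network edge) connecting two minima."""

    id: int
    energy: float
    min1: int
    min2: int
    log_freq_product: float = 0.0


class KTN:
    """A kinetic transition network: minima plus transition states.

    Parallel edges (several transition states between the same pair of
    minima) are allowed; self-loops are rejected.  By default a transition
    state lying below either of its endpoints is an error; pass
    ``permissive=True`` to clamp such barriers to the higher endpoint
    (with a warning), which real databases occasionally require.
    """

    def __init__(
        self,
        minima: Iterable[Minimum],
        transition_states: Iterable[TransitionState],
        permissive: bool = False,
    ):
        self.minima: dict[int, Minimum] = {}
        for m in minima:
            if m.id in self.minima:
                raise ValueError(f"duplicate minimum id {m.id}")
            if m.pg_order < 1:
                raise ValueError(f"minimum {m.id}: pg_order must be >= 1")
            self.minima[m.id] = m
        self.transition_states: list[TransitionState] = []
        self.permissive = permissive
        for ts in transition_states:
            self.add_transition_state(ts)

    def add_transition_state(self, ts: TransitionState) -> None:
        if ts.min1 == ts.min2:
            raise ValueError(f"transition state {ts.id}: self-loop on minimum {ts.min1}")
        for end in (ts.min1, ts.min2):
            if end not in self.minima:
                raise ValueError(
                    f"transition state {ts.id} references missing minimum {end}"
                )
        floor = max(self.minima[ts.min1].energy, self.minima[ts.min2].energy)
        if ts.energy < floor:
            if self.permissive:
                warnings.warn(
                    f"transition state {ts.id} at E={ts.energy} below endpoint "
                    f"maximum {floor}; clamping to {floor}",
                    stacklevel=2,
                )
                ts = TransitionState(ts.id, floor, ts.min1, ts.min2, ts.log_freq_product)
            else:
                raise ValueError(
                    f"transition state {ts.id}: barrier {ts.energy} below "
                    f"endpoint maximum {floor} (use permissive=True to clamp)"
                )
        self.transition_states.append(ts)

    @property
    def node_ids(self) -> list[int]:
        return list(self.minima)

    def __len__(self) -> int:
        return len(self.minima)

    def neighbors(self, node: int) -> set[int]:
        out = set()
        for ts in self.transition_states:
            if ts.min1 == node:
                out.add(ts.min2)
            elif ts.min2 == node:
                out.add(ts.min1)
        return out

    def degree(self, node: int) -> int:
        return sum(1 for ts in self.transition_states if node in (ts.min1, ts.min2))


def validate_ktn(ktn: KTN) -> list[str]:
    """Check network invariants, returning a list of human-readable violations.

    An empty list means the network is well formed.  Violations are reported
    rather than raised so that a whole database can be audited in one pass.
    """
    violations: list[str] = []
    seen_ids: set[int] = set()
    for m in ktn.minima.values():
        if m.id in seen_ids:
            violations.append(f"minimum {m.id}: duplicate id")
        seen_ids.add(m.id)
        if m.pg_order < 1:
            violations.append(f"minimum {m.id}: pg_order {m.pg_order} < 1")
    for ts in ktn.transition_states:
        if ts.min1 == ts.min2:
            violations.append(f"transition state {ts.id}: self-loop on {ts.min1}")
            continue
        missing = [e for e in (ts.min1, ts.min2) if e not in ktn.minima]
        for e in missing:
            violations.append(f"transition state {ts.id}: missing minimum {e}")
        if missing:
            continue
        floor = max(ktn.minima[ts.min1].energy, ktn.minima[ts.min2].energy)
        if ts.energy < floor and not ktn.permissive:
            violations.append(
                f"transition state {ts.id}: barrier below endpoints "
                f"({ts.energy} < {floor})"
            )
    return violations


# ---------------------------------------------------------------------------
# rate model
# ---------------------------------------------------------------------------

@dataclass
class RateModel:
    """Temperature-resolved Markov chain derived from a KTN.

    Attributes
    ----------
    temperature
        Temperature T in energy units (k_B = 1).
    node_ids
        Node ids in matrix order.
    K
        Dense rate matrix, ``K[i, j]`` = rate j -> i, zero diagonal.
    tau
        Waiting times ``tau[j] = 1 / sum_i K[i, j]`` (inf for isolated nodes).
    P
        Branching probabilities ``P[i, j] = K[i, j] * tau[j]``; each column
        with at least one edge sums to 1.
    pi
        Normalized equilibrium occupation probabilities.
    """

    temperature: float
    node_ids: list[int]
    K: np.ndarray
    tau: np.ndarray
    P: np.ndarray
    pi: np.ndarray
    index: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {nid: i for i, nid in enumerate(self.node_ids)}

    def rate(self, to_id: int, from_id: int) -> float:
        return float(self.K[self.index[to_id], self.index[from_id]])

    def waiting_time(self, node_id: int) -> float:
        return float(self.tau[self.index[node_id]])

    def branching(self, to_id: int, from_id: int) -> float:
        return float(self.P[self.index[to_id], self.index[from_id]])

    def equilibrium(self, node_id: int) -> float:
        return float(self.pi[self.index[node_id]])


def build_rate_model(ktn: KTN, temperature: float) -> RateModel:
    """Convert a network into directed rates, waiting times and branching
    probabilities at a given temperature.

    The rate for leaving minimum j over transition state ts towards minimum i
    follows the harmonic form with unit prefactor,

        k(i <- j) = pg_order_j * exp(-(E_ts - E_j)/T - (lfp_ts - lfp_j)),

    where lfp is the log frequency product.  The point-group factor makes the
    rates consistent with the equilibrium weights

        pi_j  propto  exp(-E_j/T - lfp_j) / pg_order_j,

    so detailed balance k(i<-j) pi_j = k(j<-i) pi_i holds exactly by
    construction.  Parallel transition states contribute additively.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    node_ids = ktn.node_ids
    idx = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)
    K = np.zeros((n, n))
    T = float(temperature)
    for ts in ktn.transition_states:
        for src, dst in ((ts.min1, ts.min2), (ts.min2, ts.min1)):
            mj = ktn.minima[src]
            k = mj.pg_order * np.exp(
                -(ts.energy - mj.energy) / T
                - (ts.log_freq_product - mj.log_freq_product)
            )
            K[idx[dst], idx[src]] += k

    out_rate = K.sum(axis=0)
    with np.errstate(divide="ignore"):
        tau = np.where(out_rate > 0, 1.0 / out_rate, np.inf)
    P = np.where(out_rate > 0, K / np.where(out_rate > 0, out_rate, 1.0), 0.0)

    energies = np.array([ktn.minima[nid].energy for nid in node_ids])
    lfp = np.array([ktn.minima[nid].log_freq_product for nid in node_ids])
    order = np.array([ktn.minima[nid].pg_order for nid in node_ids], dtype=float)
    # subtract the minimum energy before exponentiating to avoid overflow
    logw = -(energies - energies.min()) / T - lfp - np.log(order)
    w = np.exp(logw - logw.max())
    pi = w / w.sum()

    return RateModel(T, node_ids, K, tau, P, pi, idx)


def branching_and_waiting(
    rm: RateModel, exclude: Sequence[int] | set[int] = ()
) -> tuple[np.ndarray, np.ndarray]:
    """Return (P, tau) views with rows of excluded target nodes masked.

    The exclusion is bookkeeping only: probabilities are *not* renormalized,
    so each source column still sums to 1 over all targets including the
    excluded ones (the masked entries are returned as a separate matrix of
    zeros in their place).  Un-masking recovers the original arrays exactly.
    """
    excl = {rm.index[e] for e in exclude}
    P = rm.P.copy()
    for i in excl:
        P[:, i] = 0.0  # outgoing entries of excluded sources are masked
    return P, rm.tau.copy()
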