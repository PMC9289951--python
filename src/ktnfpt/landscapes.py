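"""Synthetic multifunnel landscapes, PATHSAMPLE I/O, disconnectivity trees.

The model landscape emulates a multifunnel system: a short downhill main
path from reactant to product with side branches hanging off its interior
nodes.  Each branch descends a ladder of minima into a kinetic trap whose
low internal barriers make kMC trajectories flicker, and whose escape
barrier is the trap depth plus the branch entry barrier.  Increasing trap
depths produce well-separated slow relaxation time scales, one peak per
trap in the log-time first-passage distribution.

The disconnectivity tree groups minima into superbasins at descending energy
thresholds: two minima share a superbasin at threshold E iff they are
connected by a path whose highest transition state lies at or below E.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np

from .ktn import KTN, Minimum, TransitionState

__all__ = [
    "ModelLandscapeSpec",
    "DEFAULT_LANDSCAPE",
    "generate_multifunnel",
    "read_pathsample",
    "write_pathsample",
    "read_native",
    "write_native",
    "DisconnectivityTree",
    "TreeNode",
    "build_disconnectivity_tree",
]


# ---------------------------------------------------------------------------
# model landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelLandscapeSpec:
    """Parameters of the synthetic multifunnel landscape.

    All energies are in model units; the reactant end of the main path sits
    at zero and descends by ``main_path_slope`` per step toward the product.
    Trap depths must increase along the branch list; the internal barrier
    must be lower than the branch entry barrier so the traps flicker rather
    than drain.
    """

    n_branches: int = 4
    trap_depths: tuple[float, ...] = (0.5, 7.0, 13.5, 20.0)
    branch_entry_barrier: float = 3.0
    internal_barrier: float = 2.9
    minima_per_trap: int = 3
    main_path_length: int = 6
    main_path_barrier: float | None = None  # defaults to branch_entry_barrier
    main_path_slope: float = 1.0        # energy drop per main-path step (downhill to product)
    entry_bottleneck: float = 2.0       # entropic prefactor dividing branch-entry rates
    trap_ladder: float = 2.0            # energy drop per minimum descending into each trap
    reactant_tag: str = "start"   # main-path end opposite the product
    product_tag: str = "end"
    seed: int = 0

    def __post_init__(self):
        if len(self.trap_depths) != self.n_branches:
            raise ValueError(
                f"need {self.n_branches} trap depths, got {len(self.trap_depths)}"
            )
        if any(d <= 0 for d in self.trap_depths):
            raise ValueError("trap depths must be positive")
        if list(self.trap_depths) != sorted(self.trap_depths):
            raise ValueError("trap depths must be increasing")
        if self.internal_barrier >= self.branch_entry_barrier:
            raise ValueError("internal barrier must be below the entry barrier")
        if self.minima_per_trap < 2 and self.n_branches > 0:
            raise ValueError("traps need at least 2 minima (flicker pairs)")
        if self.main_path_length < 2:
            raise ValueError("main path needs at least 2 minima")
        if self.n_branches > max(self.main_path_length - 2, 0):
            raise ValueError("not enough interior main-path nodes for branches")
        if self.main_path_slope < 0:
            raise ValueError("main path slope must be nonnegative (downhill)")
        if self.entry_bottleneck < 1:
            raise ValueError("entry bottleneck must be >= 1 (it divides the rate)")
        if self.trap_ladder < 0:
            raise ValueError("trap ladder must be nonnegative")

    @property
    def reactant(self) -> int:
        return 1 if self.product_tag == "end" else self.main_path_length

    @property
    def product(self) -> int:
        return self.main_path_length if self.product_tag == "end" else 1


DEFAULT_LANDSCAPE = ModelLandscapeSpec()


def generate_multifunnel(spec: ModelLandscapeSpec = DEFAULT_LANDSCAPE) -> KTN:
    """Build the multifunnel test landscape described by ``spec``.

    Main-path minima get ids 1..main_path_length, descending toward the
    product by ``main_path_slope`` per step and connected by transition
    states ``main_path_barrier`` above the higher endpoint.  Branch j hangs
    off interior node j+2: an entry transition state at the entry-barrier
    height (carrying a log-frequency-product of ln(entry_bottleneck), an
    entropic bottleneck that divides the entry rate at every temperature)
    drops into a ladder of ``minima_per_trap`` minima descending by
    ``trap_ladder`` per step to the trap bottom at ``trap_depths[j]`` below
    the attachment node, linked by transition states ``internal_barrier``
    above the higher member of each pair (low enough to make trajectories
    flicker).  Escape from trap j therefore requires climbing
    ``trap_depths[j] + branch_entry_barrier``, strictly increasing with j.
    Construction is deterministic; the seed is carried in the spec for
    provenance only.
    """
    L = spec.main_path_length
    main_barrier = (
        spec.main_path_barrier
        if spec.main_path_barrier is not None
        else spec.branch_entry_barrier
    )
    sign = 1 if spec.product_tag == "end" else -1
    main_e = {
        i: -spec.main_path_slope * (i - 1 if sign > 0 else L - i)
        for i in range(1, L + 1)
    }
    entry_lfp = float(np.log(spec.entry_bottleneck))
    minima = [Minimum(i, main_e[i]) for i in range(1, L + 1)]
    tss = []
    ts_id = 1
    for i in range(1, L):
        tss.append(
            TransitionState(
                ts_id, max(main_e[i], main_e[i + 1]) + main_barrier, i, i + 1
            )
        )
        ts_id += 1
    next_min = L + 1
    for j in range(spec.n_branches):
        attach = 2 + j
        depth = spec.trap_depths[j]
        bottom = main_e[attach] - depth
        first = next_min
        # the branch descends from the attachment node down a ladder of
        # minima to the trap bottom; with trap_ladder = 0 all trap minima
        # sit on a common floor, and the ladder never rises above the
        # attachment level (shallow traps flatten out)
        levels = [
            bottom + min(spec.trap_ladder * (spec.minima_per_trap - 1 - m), depth)
            for m in range(spec.minima_per_trap)
        ]
        for e in levels:
            minima.append(Minimum(next_min, e))
            next_min += 1
        tss.append(
            TransitionState(
                ts_id, main_e[attach] + spec.branch_entry_barrier, attach, first,
                log_freq_product=entry_lfp,
            )
        )
        ts_id += 1
        for i, m in enumerate(range(first, next_min - 1)):
            upper = max(levels[i], levels[i + 1])
            tss.append(
                TransitionState(ts_id, upper + spec.internal_barrier, m, m + 1)
            )
            ts_id += 1
    return KTN(minima, tss)


# ---------------------------------------------------------------------------
# PATHSAMPLE-style I/O
# ---------------------------------------------------------------------------

def _parse_rows(path, n_fields_min: int, label: str):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < n_fields_min:
                raise ValueError(
                    f"{label} line {lineno}: expected at least "
                    f"{n_fields_min} fields, got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{label} line {lineno}: non-numeric field") from exc
            rows.append((lineno, vals))
    return rows


def read_pathsample(min_path, ts_path, permissive: bool = False) -> KTN:
    """Read a network from PATHSAMPLE-style min.data / ts.data text files.

    min.data rows: energy, log frequency product, point-group order,
    and three moments of inertia (ignored).  ts.data rows: energy, log
    frequency product, point-group order (ignored for edges), minimum 1,
    minimum 2, three inertia components (ignored).  Minima indices are
    1-based row numbers.  Malformed rows are reported with their line number.
    """
    minima = []
    for i, (lineno, vals) in enumerate(_parse_rows(min_path, 3, "min.data"), start=1):
        minima.append(Minimum(i, vals[0], vals[1], max(int(round(vals[2])), 1)))
    n_min = len(minima)

    tss = []
    for i, (lineno, vals) in enumerate(_parse_rows(ts_path, 5, "ts.data"), start=1):
        m1, m2 = int(round(vals[3])), int(round(vals[4]))
        for m in (m1, m2):
            if not 1 <= m <= n_min:
                raise ValueError(
                    f"ts.data line {lineno}: minimum index {m} out of range "
                    f"(1..{n_min})"
                )
        tss.append(TransitionState(i, vals[0], m1, m2, vals[1]))
    return KTN(minima, tss, permissive=permissive)


def write_pathsample(ktn: KTN, min_path, ts_path) -> None:
    """Write a network as min.data / ts.data (zero inertia fields).

    Minima are emitted in ascending id order; ids are mapped to 1-based row
    numbers, which is the index convention read_pathsample expects.
    """
    order = sorted(ktn.minima)
    row_of = {nid: i for i, nid in enumerate(order, start=1)}
    with open(min_path, "w") as fh:
        for nid in order:
            m = ktn.minima[nid]
            fh.write(
                f"{m.energy:.10f} {m.log_freq_product:.10f} {m.pg_order} 0.0 0.0 0.0\n"
            )
    with open(ts_path, "w") as fh:
        for ts in ktn.transition_states:
            fh.write(
                f"{ts.energy:.10f} {ts.log_freq_product:.10f} 1 "
                f"{row_of[ts.min1]} {row_of[ts.min2]} 0.0 0.0 0.0\n"
            )


def write_native(ktn: KTN, prefix, comment: str = "") -> None:
    """Write the native dialect: <prefix>.minima.tsv, <prefix>.ts.tsv,
    <prefix>.meta.json (tab-delimited tables with headers, 1-based ids)."""
    prefix = Path(prefix)
    with open(f"{prefix}.minima.tsv", "w") as fh:
        fh.write("id\tenergy\tlog_freq_product\tpg_order\n")
        for nid in sorted(ktn.minima):
            m = ktn.minima[nid]
            fh.write(f"{m.id}\t{m.energy:.10f}\t{m.log_freq_product:.10f}\t{m.pg_order}\n")
    with open(f"{prefix}.ts.tsv", "w") as fh:
        fh.write("id\tenergy\tmin1\tmin2\tlog_freq_product\n")
        for ts in ktn.transition_states:
            fh.write(
                f"{ts.id}\t{ts.energy:.10f}\t{ts.min1}\t{ts.min2}\t"
                f"{ts.log_freq_product:.10f}\n"
            )
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump({"units": "model energy units, k_B = 1", "comment": comment}, fh)


def read_native(prefix, permissive: bool = False) -> KTN:
    """Read the native dialect written by :func:`write_native`."""
    import pandas as pd

    prefix = Path(prefix)
    mins = pd.read_csv(f"{prefix}.minima.tsv", sep="\t")
    tss = pd.read_csv(f"{prefix}.ts.tsv", sep="\t")
    minima = [
        Minimum(int(r.id), float(r.energy), float(r.log_freq_product), int(r.pg_order))
        for r in mins.itertuples()
    ]
    states = [
        TransitionState(
            int(r.id), float(r.energy), int(r.min1), int(r.min2),
            float(r.log_freq_product),
        )
        for r in tss.itertuples()
    ]
    return KTN(minima, states, permissive=permissive)


# ---------------------------------------------------------------------------
# disconnectivity tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A superbasin: all minima mutually reachable below ``threshold``."""

    threshold: float
    members: frozenset[int]
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class DisconnectivityTree:
    """Merge tree of superbasins over a descending grid of energy thresholds."""

    roots: list[TreeNode]
    leaves: dict[int, TreeNode]
    levels: list[float]
    min_energies: dict[int, float]

    def node_at(self, minimum: int, threshold: float) -> TreeNode:
        """The superbasin containing ``minimum`` at the given threshold."""
        node = self.leaves[minimum]
        while node.parent is not None and node.parent.threshold <= threshold:
            node = node.parent
        return node

    def leaf_order(self) -> list[int]:
        """Depth-first leaf ordering (children sorted by lowest member energy),
        a simple heuristic that keeps each funnel's branches contiguous and so
        avoids crossings for tree-structured landscapes."""
        order: list[int] = []

        def visit(node: TreeNode) -> None:
            if node.is_leaf:
                order.extend(sorted(node.members))
                return
            for child in sorted(
                node.children,
                key=lambda c: min(self.min_energies[m] for m in c.members),
            ):
                visit(child)

        for root in sorted(
            self.roots, key=lambda r: min(self.min_energies[m] for m in r.members)
        ):
            visit(root)
        return order

    def to_dict(self) -> dict:
        def conv(node: TreeNode) -> dict:
            return {
                "threshold": node.threshold,
                "members": sorted(node.members),
                "children": [conv(c) for c in node.children],
            }

        return {"levels": self.levels, "roots": [conv(r) for r in self.roots]}

    def to_dot(self) -> str:
        lines = ["digraph disconnectivity {", "  rankdir=BT;"]
        counter = [0]

        def visit(node: TreeNode) -> str:
            name = f"n{counter[0]}"
            counter[0] += 1
            if node.is_leaf:
                label = ",".join(str(m) for m in sorted(node.members))
            else:
                label = f"E<={node.threshold:g}"
            lines.append(f'  {name} [label="{label}"];')
            for child in node.children:
                cname = visit(child)
                lines.append(f"  {cname} -> {name};")
            return name

        for root in self.roots:
            visit(root)
        lines.append("}")
        return "\n".join(lines)


class _DSU:
    """Minimal union-find over node ids."""

    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def build_disconnectivity_tree(
    ktn: KTN, delta_e: float, e_max: float
) -> DisconnectivityTree:
    """Group minima into superbasins at thresholds e_max, e_max - delta_e, ...

    At each threshold minima belong to the same superbasin iff they are
    connected through transition states lying at or below the threshold
    (branches of the tree merge when the energy exceeds the highest
    transition state on the lowest-energy path between them).  The grid
    descends until it passes below the lowest transition state, at which
    point every minimum is its own leaf.
    """
    if delta_e <= 0:
        raise ValueError("delta_e must be positive")
    min_e = {nid: m.energy for nid, m in ktn.minima.items()}
    ts_floor = min((ts.energy for ts in ktn.transition_states), default=e_max)
    levels = []
    e = e_max
    while e >= ts_floor:
        levels.append(e)
        e -= delta_e
    levels.append(e)  # one level below every transition state
    ascending = levels[::-1]

    leaves = {nid: TreeNode(min_e[nid], frozenset([nid])) for nid in ktn.minima}
    current: dict[int, TreeNode] = dict(leaves)  # representative -> node

    for level in ascending:
        dsu = _DSU(ktn.minima)
        for ts in ktn.transition_states:
            if ts.energy <= level:
                dsu.union(ts.min1, ts.min2)
        groups: dict[int, set[int]] = {}
        for nid in ktn.minima:
            groups.setdefault(dsu.find(nid), set()).add(nid)
        new_current: dict[int, TreeNode] = {}
        for rep, members in groups.items():
            parts: dict[int, TreeNode] = {}
            for m in members:
                node = current[m]
                parts[id(node)] = node
            uniq = list(parts.values())
            if len(uniq) == 1:
                new_current[rep] = uniq[0]
            else:
                node = TreeNode(level, frozenset(members), children=uniq)
                for child in uniq:
                    child.parent = node
                new_current[rep] = node
        current = {m: new_current[dsu.find(m)] for m in ktn.minima}

    roots = []
    seen = set()
    for node in current.values():
        if id(node) not in seen:
            seen.add(id(node))
            roots.append(node)
    return DisconnectivityTree(roots, leaves, levels, min_e)
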