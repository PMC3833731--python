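"""Distance matrices over banding-sequence pools; minimal-step networks, trees.

Networks are built per arm: the integer inversion-step distances between all
mapped sequences of one arm (species pools plus registry entries), a minimum
spanning tree over them (the star-like relation diagrams with basic sequences
as hubs), and a neighbor-joining tree for distance-based phylogeny export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np

from .band_model import ArmSequence, BasicRegistry, Karyotype
from .errors import IncomparableArmsError, ValidationError
from .reversal import arm_distance


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, nonnegative integers

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        problems = []
        if v.shape != (len(self.labels), len(self.labels)):
            problems.append(f"matrix shape {v.shape} does not match {len(self.labels)} labels")
        elif not np.array_equal(v, v.T):
            problems.append("matrix is not symmetric")
        elif np.any(np.diag(v) != 0):
            problems.append("matrix diagonal is not zero")
        elif np.any(v < 0):
            problems.append("matrix has negative entries")
        if len(set(self.labels)) != len(self.labels):
            problems.append("duplicate labels")
        if problems:
            raise ValidationError(problems)
        self.values = v
        n = len(self.labels)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if v[i, j] > v[i, k] + v[k, j]:
                        warnings.warn(
                            f"triangle inequality violated for "
                            f"({self.labels[i]}, {self.labels[j]}, {self.labels[k]})",
                            stacklevel=2,
                        )
                        return

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> int:
        return int(self.values[self.labels.index(a), self.labels.index(b)])


def distance_matrix(seqs: list[ArmSequence]) -> DistanceMatrix:
    """Pairwise inversion-step distances between sequences of one arm."""
    if not seqs:
        raise ValidationError(["distance_matrix requires at least one sequence"])
    arms = {s.arm for s in seqs}
    if len(arms) > 1:
        raise IncomparableArmsError(f"sequences from different arms: {sorted(arms)}")
    labels = tuple(s.code for s in seqs)
    if len(set(labels)) != len(labels):
        raise ValidationError(["duplicate sequence codes in matrix input"])
    n = len(seqs)
    values = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = arm_distance(seqs[i], seqs[j]).distance
            except IncomparableArmsError as e:
                raise IncomparableArmsError(
                    f"cannot compare {labels[i]} and {labels[j]}: {e}"
                ) from e
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def mst_network(m: DistanceMatrix) -> list[tuple[str, str, int]]:
    """Minimum spanning tree edges, deterministic (lexicographic tie-break)."""
    if m.n < 2:
        raise ValidationError(["mst_network requires at least 2 labels"])
    g = nx.Graph()
    pairs = sorted(
        (tuple(sorted((m.labels[i], m.labels[j]))), int(m.values[i, j]))
        for i in range(m.n)
        for j in range(i + 1, m.n)
    )
    for (a, b), w in pairs:
        g.add_edge(a, b, weight=w)
    edges = nx.minimum_spanning_edges(g, algorithm="kruskal", data=True)
    out = sorted((min(a, b), max(a, b), d["weight"]) for a, b, d in edges)
    return out


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(m: DistanceMatrix) -> tuple[dendropy.Tree, str]:
    """Standard neighbor joining; recovers additive matrices exactly.

    Ties in the Q criterion are broken by smallest index pair, so output is
    deterministic.  Returns the unrooted tree and its Newick string.
    """
    if m.n < 3:
        raise ValidationError(["nj_tree requires at least 3 labels"])
    d = m.values.astype(float).copy()
    nodes = [f"{lab}" for lab in m.labels]  # current Newick fragment per row
    active = list(range(m.n))
    next_internal = 0
    while len(active) > 2:
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (len(active) - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = d[i, j] - li
        new_frag = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # reuse slot i for the new internal node
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[i, k] = d[k, i] = dk
        nodes[i] = new_frag
        active.remove(j)
        next_internal += 1
    i, j = active
    newick = f"({nodes[i]},{nodes[j]}:{d[i, j]:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree, newick


# ---------------------------------------------------------------------------
# writers


def write_phylip(m: DistanceMatrix) -> str:
    """Square PHYLIP distance matrix."""
    lines = [f"{m.n}"]
    for i, lab in enumerate(m.labels):
        vals = " ".join(f"{int(v)}" for v in m.values[i])
        lines.append(f"{lab:<10} {vals}")
    return "\n".join(lines) + "\n"


def write_dot(edges: list[tuple[str, str, int]], name: str = "mst") -> str:
    """DOT export of an MST network."""
    lines = [f"graph {name} {{"]
    for a, b, w in edges:
        lines.append(f'  "{a}" -- "{b}" [label="{w}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def arm_pool(
    records: list[Karyotype], arm: str, registry: BasicRegistry | None = None
) -> list[ArmSequence]:
    """All mapped sequences of one arm across a study, plus registry entries.

    Registry stubs without formulas are excluded (names without usable
    sequences cannot enter the computation).
    """
    seqs = [s for k in records for s in k.pool.get(arm, []) if s.is_mapped]
    if registry is not None:
        for entry in registry.for_arm(arm):
            seqs.append(entry.sequence)
    return seqs
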