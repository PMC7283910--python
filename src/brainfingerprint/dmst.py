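"""Directed minimum spanning trees (minimum arborescences) of STE digraphs.

The STE matrix is an asymmetric weighted digraph, so the brain network is
built as a minimum spanning arborescence: a spanning tree rooted at a chosen
node in which every other node has exactly one entering edge and the summed
edge weight is minimal.  The solver is the Chu-Liu/Edmonds algorithm —
greedy choice of the cheapest entering edge per node, contraction of any
cycle with the weight update ``w − in[u]``, recursion, and expansion of the
contracted cycles by dropping each cycle's superseded entering edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import ChannelMap
from .ste import STEMatrix


@dataclass(frozen=True)
class _Edge:
    u: int
    v: int
    w: float
    orig: tuple[int, int]  # endpoints in the original graph


@dataclass
class WeightedDigraph:
    """Dense weighted digraph on nodes ``0..n−1``; NaN entries mark absent edges."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if np.any(np.isinf(self.weights)):
            raise ValueError("edge weights must be finite (use NaN for absent edges)")
        diag = np.diag(self.weights)
        if np.any(~np.isnan(diag)):
            raise ValueError("self-loops are not allowed (diagonal must be NaN)")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        us, vs = np.nonzero(~np.isnan(self.weights))
        return [(int(u), int(v), float(self.weights[u, v])) for u, v in zip(us, vs)]


def from_ste(matrix: STEMatrix, mode: str = "literal") -> WeightedDigraph:
    """Turn an STE matrix into a complete weighted digraph.

    ``literal`` uses the TE values themselves as distances, so the minimum
    arborescence minimizes summed TE; ``negate`` uses −TE so it maximizes
    total information flow.  Both are kept one flag apart because the right
    orientation is a modelling choice, not a mathematical one.
    """
    if mode not in ("literal", "negate"):
        raise ValueError(f"mode must be 'literal' or 'negate', got {mode!r}")
    w = matrix.values.copy() if mode == "literal" else -matrix.values
    np.fill_diagonal(w, np.nan)
    return WeightedDigraph(w)


@dataclass
class Arborescence:
    """Rooted spanning tree of a digraph: ``parent[v]`` for every non-root v."""

    root: int
    parent: dict[int, int]
    weights: dict[int, float]  # weight of the edge parent[v] -> v
    mode: str = "literal"

    def __post_init__(self) -> None:
        n = len(self.parent) + 1
        nodes = set(self.parent) | {self.root}
        if len(nodes) != n:
            raise ValueError("parent map must cover every non-root node exactly once")
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        # reachability from root == acyclicity for a functional parent map
        for v in self.parent:
            seen = set()
            node = v
            while node != self.root:
                if node in seen:
                    raise ValueError(f"parent map contains a cycle through node {node}")
                seen.add(node)
                node = self.parent[node]

    @property
    def n(self) -> int:
        return len(self.parent) + 1

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    def edges(self) -> list[tuple[int, int, float]]:
        """Edges as (source, target, weight), sorted by target."""
        return [(self.parent[v], v, self.weights[v]) for v in sorted(self.parent)]

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for v, u in self.parent.items():
            deg[u] += 1
        return deg

    def to_edge_tsv(self, path) -> None:
        pd.DataFrame(self.edges(), columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    def to_dot(self, labels: Sequence[str] | None = None) -> str:
        def name(i: int) -> str:
            return f'"{labels[i]}"' if labels is not None else str(i)

        lines = ["digraph arborescence {"]
        for u, v, w in self.edges():
            lines.append(f"  {name(u)} -> {name(v)} [label=\"{w:.4g}\"];")
        lines.append("}")
        return "\n".join(lines)


def _best_entering(edges: list[_Edge], nodes: set[int], root: int) -> dict[int, _Edge]:
    best: dict[int, _Edge] = {}
    for e in edges:
        if e.v == root or e.u == e.v:
            continue
        b = best.get(e.v)
        # deterministic tie-break: lowest source index
        if b is None or (e.w, e.u) < (b.w, b.u):
            best[e.v] = e
    missing = nodes - {root} - set(best)
    if missing:
        raise ValueError(f"nodes unreachable from root {root}: {sorted(missing)}")
    return best


def _find_cycle(best: Mapping[int, _Edge]) -> list[int] | None:
    visited: dict[int, int] = {}
    for start in best:
        if start in visited:
            continue
        path: list[int] = []
        node = start
        while node in best and node not in visited:
            visited[node] = start
            path.append(node)
            node = best[node].u
        if node in best and visited.get(node) == start:
            return path[path.index(node):]
    return None


def _solve(nodes: set[int], edges: list[_Edge], root: int) -> dict[tuple[int, int], float]:
    best = _best_entering(edges, nodes, root)
    cycle = _find_cycle(best)
    if cycle is None:
        return {e.orig: e.w for e in best.values()}

    cyc = set(cycle)
    super_node = max(nodes) + 1
    new_edges: list[_Edge] = []
    entering: dict[int, tuple[_Edge, int]] = {}  # source -> (reduced edge, cycle target)
    for e in edges:
        if e.u in cyc and e.v in cyc:
            continue
        if e.v in cyc:
            # entering the contracted ring: reduced cost w − in[v]
            cand = _Edge(e.u, super_node, e.w - best[e.v].w, e.orig)
            prev = entering.get(e.u)
            if prev is None or (cand.w, cand.orig) < (prev[0].w, prev[0].orig):
                entering[e.u] = (cand, e.v)
        elif e.u in cyc:
            new_edges.append(_Edge(super_node, e.v, e.w, e.orig))
        else:
            new_edges.append(e)
    new_edges.extend(cand for cand, _ in entering.values())
    sub = _solve((nodes - cyc) | {super_node}, new_edges, root)

    # expansion ("breaking the loop"): keep all cycle edges except the one
    # superseded by the chosen edge entering the contracted node
    chosen: dict[tuple[int, int], float] = dict(sub)
    entry_target = None
    for cand, v_level in entering.values():
        if cand.orig in sub:
            entry_target = v_level
            break
    if entry_target is None:  # pragma: no cover - contraction guarantees an entry
        raise RuntimeError("contracted cycle has no entering edge in the solution")
    for v in cyc:
        if v != entry_target:
            e = best[v]
            chosen[e.orig] = e.w
    return chosen


def minimum_arborescence(
    graph: WeightedDigraph, root: int, mode: str = "literal"
) -> Arborescence:
    """Minimum-total-weight spanning arborescence rooted at ``root``.

    Raises a labelled error if some node cannot be reached from the root.
    Ties between equally cheap entering edges are broken toward the lowest
    source index, making the result deterministic for a given root.
    """
    n = graph.n
    if not 0 <= root < n:
        raise ValueError(f"root {root} outside 0..{n - 1}")
    edges = [
        _Edge(u, v, w, (u, v)) for u, v, w in graph.edges() if u != v
    ]
    solution = _solve(set(range(n)), edges, root)
    parent = {v: u for (u, v) in solution}
    weights = {v: float(graph.weights[u, v]) for (u, v) in solution}
    arb = Arborescence(root=root, parent=parent, weights=weights, mode=mode)
    if arb.n != n:
        raise RuntimeError("solver returned a non-spanning arborescence")
    return arb


def select_root(
    matrix: STEMatrix,
    policy: str | int = "random",
    seed: int | None = None,
    channels: ChannelMap | None = None,
) -> int:
    """Pick the arborescence root.

    ``"random"`` draws uniformly (seeded), an integer or electrode label
    selects that node, and ``"max-out-strength"`` picks the channel with the
    largest summed outgoing TE.
    """
    if isinstance(policy, int):
        return policy
    if policy == "random":
        rng = np.random.default_rng(seed)
        return int(rng.integers(matrix.n))
    if policy == "max-out-strength":
        return int(np.argmax(matrix.values.sum(axis=1)))
    cmap = channels or ChannelMap(matrix.channels)
    return cmap.index(policy) - 1


def out_degree_profile(
    tree: Arborescence, channels: ChannelMap | None = None
) -> tuple[pd.DataFrame, set[str]]:
    """Per-node out-degrees with electrode labels and the key node(s).

    Returns the labelled degree table and the set of labels attaining the
    maximum out-degree (a singleton unless tied).
    """
    deg = tree.out_degrees()
    if channels is not None:
        labels = [channels.label(i + 1) for i in range(tree.n)]
    else:
        labels = [str(i) for i in range(tree.n)]
    table = pd.DataFrame({"node": range(tree.n), "label": labels, "out_degree": deg})
    key = {labels[i] for i in np.flatnonzero(deg == deg.max())}
    return table, key
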