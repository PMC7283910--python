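"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from brainfingerprint.io import EventRecord, EventTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def reference_event_table() -> EventTable:
    """The printed 15-row event table of a reference task run:
    rest events of 672 samples alternating with 656-sample task events,
    each separated by a 641-sample gap."""
    codes = (1, 3, 1, 2, 1, 2, 1, 3, 1, 3, 1, 2, 1, 3, 1)
    latencies = (1, 1313, 2609, 3921, 5217, 6529, 7825, 9297,
                 10593, 11905, 13201, 14513, 15809, 17281, 18577)
    durations = tuple(672 if c == 1 else 656 for c in codes)
    return EventTable(
        EventRecord(code=c, latency=l, duration=d)
        for c, l, d in zip(codes, latencies, durations)
    )


def brute_force_min_arborescence(weights: np.ndarray, root: int) -> float | None:
    """Exhaustive minimum over all spanning arborescences rooted at ``root``.

    ``weights[u, v]`` is the u→v edge weight, NaN marking absent edges.
    Enumerates every parent assignment of the non-root nodes and keeps the
    cheapest acyclic one; returns None if no spanning arborescence exists.
    Only feasible for small n — this is the enumeration oracle.
    """
    n = weights.shape[0]
    nodes = [v for v in range(n) if v != root]
    best: float | None = None
    for parents in product(range(n), repeat=len(nodes)):
        assign = dict(zip(nodes, parents))
        if any(u == v for v, u in assign.items()):
            continue
        if any(np.isnan(weights[u, v]) for v, u in assign.items()):
            continue
        ok = True
        for v in nodes:
            seen, node = set(), v
            while node != root:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = assign[node]
            if not ok:
                break
        if not ok:
            continue
        total = float(sum(weights[u, v] for v, u in assign.items()))
        if best is None or total < best:
            best = total
    return best


def brute_force_transfer_entropy(source, target) -> float:
    """Direct summation of the k = l = 1 transfer-entropy formula from an
    explicitly built joint frequency table (independent counting oracle)."""
    import math
    from collections import Counter

    src = list(source)
    tgt = list(target)
    n = len(tgt) - 1
    triple = Counter(zip(tgt[1:], tgt[:-1], src[:-1]))
    pair_xx = Counter(zip(tgt[1:], tgt[:-1]))
    pair_xy = Counter(zip(tgt[:-1], src[:-1]))
    single = Counter(tgt[:-1])
    te = 0.0
    for (x1, x0, y0), c in triple.items():
        te += (c / n) * math.log2(
            (c * single[x0]) / (pair_xx[(x1, x0)] * pair_xy[(x0, y0)])
        )
    return te
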