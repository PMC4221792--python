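"""Per-ordering simulator of the adaptive compressed census.

Simulates the pooled search on one concrete ordering of the cells: pools
are contiguous slices of the ordering, each sensed round senses every
active pool, leaves (single-cell pools) with reliable coverage are deeply
sequenced and their genomes added to the captured set, and the next
round's pools are chosen by either a depth-first rule (keep the pool with
the largest assembly, stack the rest, pop stacked pools unless their
assembly is subsumed by the captured set) or a breadth-first rule (keep a
minimum assembly-set cover of the round).  Pools judged unreliable
(coverage at or below ``M_l``) are re-explored with doubled budgets.

The simulator is the object of the structural guarantees — the DFS rule
needs at most two pools (barcodes) per round, the BFS rule finishes in
``ceil(log2 n)`` splitting rounds — while the ensemble module analyses
the cost of the depth-first recursion exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .community import CommunityProfile, Parameters
from .ensemble import CaptureDistribution, simulate_ordering
from .oracle import (
    AssemblyProfile,
    allocate_sequence_assemble,
    subsumed,
)

__all__ = [
    "NodeSet",
    "CapturedSet",
    "SearchResult",
    "MonteCarloResult",
    "run_compressed_search",
    "select_next_level_sets",
    "min_assembly_set_cover",
    "ensemble_monte_carlo",
]

#: exact set-cover enumeration is used up to this many pools per round
_EXACT_COVER_LIMIT = 12


@dataclass(frozen=True)
class NodeSet:
    """One pool: a contiguous slice of the cell ordering.

    ``members`` are original cell indices, ``labels`` the matching genome
    labels.  ``boost`` counts budget doublings granted after low-quality
    rounds; ``order`` is a tie-break rank (creation order).
    """

    members: tuple[int, ...]
    labels: tuple[int, ...]
    a_parent: float
    boost: int = 0
    order: int = 0
    assembly: AssemblyProfile | None = None
    sampled: float = 0.0

    def profile_counts(self, s: int) -> tuple[int, ...]:
        p = [0] * s
        for lab in self.labels:
            p[lab - 1] += 1
        return tuple(p)


@dataclass
class CapturedSet:
    """Deeply sequenced genomes and their (complete) assemblies."""

    g: tuple[float, ...]
    identified: set[int] = field(default_factory=set)
    representatives: dict[int, int] = field(default_factory=dict)

    @property
    def assembly(self) -> AssemblyProfile:
        a = tuple(
            self.g[j] if (j + 1) in self.identified else 0.0
            for j in range(len(self.g))
        )
        return AssemblyProfile(a, 0.0)

    def add(self, genome: int, cell_index: int) -> None:
        if genome not in self.identified:
            self.identified.add(genome)
            self.representatives[genome] = cell_index


@dataclass(frozen=True)
class SearchResult:
    """Ledger of one simulated adaptive search run."""

    strategy: str
    n: int
    total_sequenced: float
    rounds: int
    max_pools_per_round: int
    identified: frozenset[int]
    representatives: dict[int, int]
    missed: frozenset[int]


def _sense(node: NodeSet, g: tuple[float, ...], params: Parameters) -> NodeSet:
    """Sense one pool, honouring any low-quality budget doubling."""
    p = node.profile_counts(len(g))
    alloc = allocate_sequence_assemble(
        p, g, node.a_parent * (2 ** node.boost), params
    )
    return replace(node, assembly=alloc.assembly, sampled=alloc.t)


def _deep_sequence(
    node: NodeSet, g: tuple[float, ...], params: Parameters
) -> float:
    """Extra nucleotides to push a leaf's coverage up to ``M_u``."""
    assert node.assembly is not None
    extra = 0.0
    c = node.assembly.c
    a_total = node.assembly.total
    p = node.profile_counts(len(g))
    while c < params.m_upper:
        alloc = allocate_sequence_assemble(p, g, a_total, params)
        extra += alloc.t
        c = alloc.assembly.c
        a_total = alloc.assembly.total
    return extra


def _union_assembly(assemblies: Iterable[AssemblyProfile], s: int) -> tuple[float, ...]:
    u = [0.0] * s
    for a in assemblies:
        for j, aj in enumerate(a.a_bar):
            u[j] = max(u[j], aj)
    return tuple(u)


def min_assembly_set_cover(
    nodes: Sequence[NodeSet],
    captured: AssemblyProfile,
    params: Parameters,
) -> list[NodeSet]:
    """Smallest sub-collection of pools whose union assembly covers the round.

    Feasibility follows the containment form of the subsumption test: the
    union of all pool assemblies (plus the captured assembly) must exceed
    the union over the chosen pools (plus captured) by at most a
    ``tau``-fraction.  Minimises total cell count, tie-broken by fewer
    pools; exact subset enumeration up to 12 pools, greedy by assembly
    size beyond.
    """
    if not nodes:
        return []
    s = len(captured.a_bar)
    full = _union_assembly(
        [n.assembly for n in nodes if n.assembly is not None] + [captured], s
    )
    full_total = math.fsum(full)
    if full_total <= 0:
        return []

    def feasible(subset: Sequence[NodeSet]) -> bool:
        u = _union_assembly(
            [n.assembly for n in subset if n.assembly is not None] + [captured], s
        )
        d = params.tau - (full_total - math.fsum(u)) / full_total
        return d >= -1e-12

    if len(nodes) <= _EXACT_COVER_LIMIT:
        best: list[NodeSet] | None = None
        best_key = (math.inf, math.inf)
        for k in range(0, len(nodes) + 1):
            for subset in combinations(nodes, k):
                key = (sum(len(n.members) for n in subset), k)
                if key < best_key and feasible(subset):
                    best, best_key = list(subset), key
        assert best is not None  # the full collection is always feasible
        return best
    # greedy fallback: add pools by decreasing assembly size until feasible
    ranked = sorted(
        nodes, key=lambda n: (-(n.assembly.total if n.assembly else 0.0), n.order)
    )
    chosen: list[NodeSet] = []
    for node in ranked:
        if feasible(chosen):
            break
        chosen.append(node)
    return chosen


def select_next_level_sets(
    active: Sequence[NodeSet],
    waiting: list[NodeSet],
    captured: CapturedSet,
    params: Parameters,
    strategy: str,
    order_start: int = 0,
) -> tuple[list[NodeSet], list[NodeSet], float]:
    """One round transition: route sensed pools to the next round.

    ``active`` must already be sensed.  Reliable leaves are deeply
    sequenced into ``captured`` (their extra nucleotides are returned as
    the third element); low-quality pools are re-explored with doubled
    budgets; surviving pools are chosen per strategy and halved.
    Returns ``(next_active, next_waiting, extra_sequenced_bp)``.
    """
    g = captured.g
    s = len(g)
    extra = 0.0
    low: list[NodeSet] = []
    remaining: list[NodeSet] = []
    for node in active:
        assert node.assembly is not None, "pools must be sensed before selection"
        if node.assembly.c <= params.m_lower:
            low.append(node)
        elif len(node.members) == 1:
            extra += _deep_sequence(node, g, params)
            captured.add(node.labels[0], node.members[0])
        else:
            remaining.append(node)

    next_waiting = list(waiting)
    survivors: list[NodeSet]
    if strategy == "bfs":
        survivors = min_assembly_set_cover(remaining, captured.assembly, params)
        survivors = survivors + low
    elif strategy == "dfs":
        # keep the pool with the largest assembly; stack the rest
        keep: NodeSet | None = None
        if remaining:
            keep = max(
                remaining, key=lambda nd: (nd.assembly.total, -nd.order)
            )
            for node in remaining:
                if node is not keep:
                    next_waiting.append(node)
        for node in low:
            next_waiting.append(replace(node, boost=node.boost + 1))
        survivors = [keep] if keep is not None else []
        while not survivors and next_waiting:
            node = next_waiting.pop()
            if not subsumed(
                node.assembly, captured.assembly, node.assembly.c, params
            ):
                survivors = [node]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    next_active: list[NodeSet] = []
    order = order_start
    for node in survivors:
        child_boost = node.boost + 1 if node.assembly.c <= params.m_lower else 0
        a_next = node.assembly.total if node.assembly.total > 0 else node.a_parent
        if len(node.members) == 1:
            # unreliable single cell: re-sense it with a doubled budget
            next_active.append(
                replace(node, boost=child_boost, a_parent=a_next,
                        assembly=None, sampled=0.0, order=order)
            )
            order += 1
            continue
        half = (len(node.members) + 1) // 2
        for sl in (slice(None, half), slice(half, None)):
            next_active.append(
                NodeSet(
                    members=node.members[sl],
                    labels=node.labels[sl],
                    a_parent=a_next,
                    boost=child_boost,
                    order=order,
                )
            )
            order += 1
    return next_active, next_waiting, extra


def run_compressed_search(
    cells: Sequence[int],
    g: Sequence[float],
    params: Parameters | None = None,
    strategy: str = "dfs",
    max_rounds: int | None = None,
) -> SearchResult:
    """Run the full adaptive census on one ordering of genome labels.

    ``cells`` is the ordered list of genome labels (``1..s``); pools are
    index slices of it.  Returns the run ledger: total nucleotides, round
    count, the widest round (pools = barcodes), and which genomes were
    identified versus missed.
    """
    if params is None:
        params = Parameters()
    g = tuple(float(x) for x in g)
    labels = tuple(int(x) for x in cells)
    n = len(labels)
    if n < 1:
        raise ValueError("community must contain at least one cell")
    if any(not 1 <= lab <= len(g) for lab in labels):
        raise ValueError("cell labels must be in 1..s")
    if strategy not in ("dfs", "bfs"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if max_rounds is None:
        max_rounds = 50 * n + 200

    a_root = (
        max(g) if params.root_assembly == "max"
        else float(sum(g)) if params.root_assembly == "sum"
        else float(params.root_assembly)
    )
    indices = tuple(range(n))
    if n == 1:
        active = [NodeSet(indices, labels, a_root, order=0)]
    else:
        half = (n + 1) // 2
        active = [
            NodeSet(indices[:half], labels[:half], a_root, order=0),
            NodeSet(indices[half:], labels[half:], a_root, order=1),
        ]
    waiting: list[NodeSet] = []
    captured = CapturedSet(g=g)
    total = 0.0
    rounds = 0
    max_pools = 0
    order = 2
    while active or waiting:
        if rounds >= max_rounds:
            raise RuntimeError(f"search did not terminate within {max_rounds} rounds")
        if active:
            rounds += 1
            max_pools = max(max_pools, len(active))
            active = [_sense(node, g, params) for node in active]
            total += sum(node.sampled for node in active)
        active, waiting, extra = select_next_level_sets(
            active, waiting, captured, params, strategy, order_start=order
        )
        order += len(active)
        total += extra

    represented = frozenset(labels)
    identified = frozenset(captured.identified)
    return SearchResult(
        strategy=strategy,
        n=n,
        total_sequenced=total,
        rounds=rounds,
        max_pools_per_round=max_pools,
        identified=identified,
        representatives=dict(captured.representatives),
        missed=represented - identified,
    )


@dataclass(frozen=True)
class MonteCarloResult:
    """Empirical ensemble estimate over random cell orderings."""

    strategy: str
    reps: int
    mean_total: float
    se_total: float
    capture: CaptureDistribution
    capture_se: tuple[float, ...]


def ensemble_monte_carlo(
    profile: CommunityProfile,
    params: Parameters | None = None,
    strategy: str = "dfs",
    reps: int = 1000,
    seed: int = 0,
) -> MonteCarloResult:
    """Monte-Carlo estimate of the ensemble cost and capture distribution.

    Draws ``reps`` independent uniform orderings of the community's cells.
    For the depth-first strategy each ordering is run through the exact
    per-ordering recursion the ensemble analysis averages (so the sample
    mean is an unbiased estimate of the dynamic program's ``E[t]``); for
    the breadth-first strategy — which has no tractable exact analysis —
    the full search simulator is used.
    """
    if params is None:
        params = Parameters()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    base_labels = []
    for j, pj in enumerate(profile.p, start=1):
        base_labels.extend([j] * pj)
    base_labels = np.asarray(base_labels)
    a_root = profile.root_assembly_size(params)
    totals = np.empty(reps)
    mask_counts: dict[int, int] = {}
    for r in range(reps):
        perm = rng.permutation(base_labels)
        if strategy == "dfs":
            t, mask = simulate_ordering(
                perm.tolist(), profile.g, params, 0, a_root
            )
        else:
            res = run_compressed_search(perm.tolist(), profile.g, params, strategy)
            t = res.total_sequenced
            mask = sum(1 << (j - 1) for j in res.identified)
        totals[r] = t
        mask_counts[mask] = mask_counts.get(mask, 0) + 1
    freqs = {m: k / reps for m, k in mask_counts.items()}
    capture = CaptureDistribution.from_sparse(freqs, profile.s)
    se = tuple(
        math.sqrt(q * (1 - q) / reps) for q in capture.P
    )
    mean_total = float(np.mean(totals))
    se_total = float(np.std(totals, ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0
    return MonteCarloResult(
        strategy=strategy,
        reps=reps,
        mean_total=mean_total,
        se_total=se_total,
        capture=capture,
        capture_se=se,
    )
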