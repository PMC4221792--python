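"""Exact ensemble analysis of the depth-first adaptive census.

The depth-first search explores pools of cells recursively: sense the
pool, prune it if its assembly is subsumed by what has already been
captured, deeply sequence it if it is a single cell, and otherwise halve
it and explore the two halves in order.  Over a uniformly random ordering
of the ``n`` cells, the composition of the first half of a pool is
multivariate-hypergeometric in the pool's population profile — which
makes the expectation of the total sequenced nucleotides ``E[t]`` and the
joint distribution of the final capture state computable exactly by
dynamic programming over (profile, capture state, parent assembly size)
without enumerating the ``n!`` orderings.

Also provided: a factorial-time brute-force validator that enumerates the
orderings outright (tiny ``n`` only), a per-permutation recursion shared
with the Monte-Carlo estimator, and a driver for expected-cost trend
curves over community size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityProfile, Parameters, state_to_bitstring
from .oracle import allocate_sequence_assemble, subsumed_ensemble

__all__ = [
    "Division",
    "CaptureDistribution",
    "EnsembleResult",
    "enumerate_divisions",
    "cost",
    "ensemble_analysis",
    "brute_force_ensemble",
    "simulate_ordering",
    "expected_cost_curve",
]

_BRUTE_FORCE_GUARD = 8


@dataclass(frozen=True)
class Division:
    """One split of a pool profile ``p`` into halves ``v + w = p``.

    ``pi`` is the multivariate-hypergeometric probability that a uniformly
    random ordering of the pool puts exactly ``v`` in the first half.
    """

    v: tuple[int, ...]
    w: tuple[int, ...]
    pi: float


@dataclass(frozen=True)
class CaptureDistribution:
    """Probability vector over the ``2**s`` capture states.

    ``P[j-1]`` is the probability of the state with 1-based index ``j``
    (the state's reversed-binary value plus one).
    """

    P: tuple[float, ...]

    def __init__(self, P: Sequence[float]) -> None:
        P = tuple(float(x) for x in P)
        k = len(P)
        if k == 0 or k & (k - 1):
            raise ValueError(f"length must be a power of two, got {k}")
        if any(x < -1e-15 for x in P):
            raise ValueError("negative probability")
        object.__setattr__(self, "P", P)

    @property
    def s(self) -> int:
        return (len(self.P)).bit_length() - 1

    @classmethod
    def from_sparse(cls, masses: dict[int, float], s: int) -> "CaptureDistribution":
        P = [0.0] * (1 << s)
        for mask, q in masses.items():
            P[mask] += q
        return cls(P)

    def prob(self, bits: str) -> float:
        """Probability of the state written as ``I_1 I_2 ... I_s``."""
        mask = sum(int(b) << j for j, b in enumerate(bits))
        return self.P[mask]

    def labels(self) -> list[str]:
        return [state_to_bitstring(m, self.s) for m in range(len(self.P))]

    def per_genome_capture(self) -> tuple[float, ...]:
        """Marginal probability that each genome is captured."""
        s = self.s
        return tuple(
            math.fsum(q for m, q in enumerate(self.P) if (m >> j) & 1)
            for j in range(s)
        )

    def total(self) -> float:
        return math.fsum(self.P)


@dataclass(frozen=True)
class EnsembleResult:
    """Output of the ensemble analysis for one community profile."""

    profile: CommunityProfile
    params: Parameters
    expected_total: float  # E[t] in bp
    capture: CaptureDistribution
    node_evaluations: int

    @property
    def expected_total_gbp(self) -> float:
        return self.expected_total / 1e9

    @property
    def per_genome_capture(self) -> tuple[float, ...]:
        return self.capture.per_genome_capture()


@lru_cache(maxsize=None)
def _divisions_cached(p: tuple[int, ...]) -> tuple[Division, ...]:
    n = sum(p)
    half = (n + 1) // 2  # first half takes the extra cell
    denom = math.comb(n, half)
    out: list[Division] = []

    def rec(j: int, remaining: int, v: list[int], weight: int) -> None:
        if j == len(p):
            if remaining == 0:
                w = tuple(pj - vj for pj, vj in zip(p, v))
                out.append(Division(tuple(v), w, weight / denom))
            return
        lo = max(0, remaining - sum(p[j + 1:]))
        hi = min(p[j], remaining)
        for vj in range(lo, hi + 1):
            v.append(vj)
            rec(j + 1, remaining - vj, v, weight * math.comb(p[j], vj))
            v.pop()

    rec(0, half, [], 1)
    return tuple(out)


def enumerate_divisions(p: Sequence[int]) -> list[Division]:
    """All halvings ``v + w = p`` with ``||v|| = ceil(||p||/2)``.

    Each division carries its multivariate-hypergeometric weight
    ``prod_j C(p_j, v_j) / C(||p||, ||v||)``; the weights sum to one.
    """
    p = tuple(int(x) for x in p)
    if sum(p) < 2:
        raise ValueError("a pool of fewer than two cells cannot be divided")
    return list(_divisions_cached(p))


class _Analyzer:
    """Memoised recursion computing (E[t], capture distribution) per node."""

    def __init__(self, g: tuple[float, ...], params: Parameters, memoize: bool = True):
        self.g = g
        self.params = params
        self.memoize = memoize
        self._memo: dict[tuple, tuple[float, dict[int, float]]] = {}
        self.node_evaluations = 0

    def cost(
        self, p: tuple[int, ...], mask: int, a_parent: float
    ) -> tuple[float, dict[int, float]]:
        key = (p, mask, round(a_parent))
        if self.memoize and key in self._memo:
            return self._memo[key]
        result = self._evaluate(p, mask, a_parent)
        if self.memoize:
            self._memo[key] = result
        return result

    def _evaluate(
        self, p: tuple[int, ...], mask: int, a_parent: float
    ) -> tuple[float, dict[int, float]]:
        params = self.params
        self.node_evaluations += 1
        alloc = allocate_sequence_assemble(p, self.g, a_parent, params)
        abar = alloc.assembly
        e_t = alloc.t

        if subsumed_ensemble(abar, abar.c, mask, params):
            # nothing new in this pool: capture state unchanged
            return e_t, {mask: 1.0}

        if sum(p) == 1:
            # leaf: deep-sequence the single cell to completion
            c = abar.c
            while c < 2 * params.m_upper:
                alloc = allocate_sequence_assemble(
                    p, self.g, alloc.assembly.total, params
                )
                e_t += alloc.t
                c = alloc.assembly.c
            k = max(range(len(p)), key=lambda j: p[j])
            return e_t, {mask | (1 << k): 1.0}

        # recursion: average over all halvings of the pool
        a_total = abar.total
        e_terms: list[float] = []
        P: dict[int, float] = {}
        for div in _divisions_cached(p):
            t_div = 0.0
            dist = {mask: 1.0}
            for u in (div.v, div.w):
                nxt: dict[int, float] = {}
                for b, qb in dist.items():
                    t_u, P_u = self.cost(u, b, a_total)
                    t_div += qb * t_u
                    for m2, q2 in P_u.items():
                        nxt[m2] = nxt.get(m2, 0.0) + qb * q2
                dist = nxt
            e_terms.append(div.pi * t_div)
            for m2, q2 in dist.items():
                P[m2] = P.get(m2, 0.0) + div.pi * q2
        return e_t + math.fsum(e_terms), P


def cost(
    p: Sequence[int],
    captured_mask: int,
    a_parent: float,
    g: Sequence[float],
    params: Parameters,
    memoize: bool = True,
) -> tuple[float, CaptureDistribution]:
    """Expected cost and capture distribution of exploring one pool.

    Runs the ensemble recursion from a pool with population profile ``p``,
    prior capture state ``captured_mask`` (bit ``j-1`` = genome ``j``
    captured) and parent assembly size ``a_parent`` (bp).  Returns
    ``E[t]`` in bp and the distribution over final capture states.
    """
    p = tuple(int(x) for x in p)
    if sum(p) < 1:
        raise ValueError("pool must contain at least one cell")
    analyzer = _Analyzer(tuple(float(x) for x in g), params, memoize=memoize)
    e_t, P = analyzer.cost(p, captured_mask, float(a_parent))
    return e_t, CaptureDistribution.from_sparse(P, len(p))


def ensemble_analysis(
    profile: CommunityProfile,
    params: Parameters | None = None,
    captured_mask: int = 0,
) -> EnsembleResult:
    """Full ensemble analysis of a community from an empty capture state.

    The root pool holds all ``n`` cells; its (nonexistent) parent assembly
    is initialised per ``params.root_assembly``.  The adaptive search
    divides the community before any pooled sequencing, so the root call
    only seeds the first-round allocations and its own notional sensing is
    excluded from the reported ``E[t]`` (for ``n >= 2``).
    """
    if params is None:
        params = Parameters()
    a_root = profile.root_assembly_size(params)
    analyzer = _Analyzer(profile.g, params)
    e_t, P = analyzer.cost(profile.p, captured_mask, a_root)
    if profile.n >= 2:
        e_t -= params.safety_factor * params.m_upper * a_root
    capture = CaptureDistribution.from_sparse(P, profile.s)
    return EnsembleResult(
        profile=profile,
        params=params,
        expected_total=e_t,
        capture=capture,
        node_evaluations=analyzer.node_evaluations,
    )


# ---------------------------------------------------------------------------
# Per-ordering recursion, brute force and trends


def simulate_ordering(
    labels: Sequence[int],
    g: Sequence[float],
    params: Parameters,
    captured_mask: int = 0,
    a_parent: float | None = None,
    charge_root: bool = False,
) -> tuple[float, int]:
    """Deterministic census of one concrete cell ordering.

    Runs the same recursion the ensemble analysis averages: sense the
    pool, prune its subtree if the assembly is subsumed, deep-sequence
    leaves, otherwise recurse on the first ``ceil(m/2)`` cells then the
    rest.  ``labels`` are genome labels in ``1..s``.  As in
    :func:`ensemble_analysis`, the root pool's own sensing is excluded
    from the total unless ``charge_root`` is set (single-cell inputs are
    always charged).  Returns (total sequenced bp, final capture mask).
    """
    g = tuple(float(x) for x in g)
    s = len(g)
    if a_parent is None:
        a_parent = _root_assembly(g, params)

    def walk(cells: tuple[int, ...], mask: int, a_par: float) -> tuple[float, int]:
        p = [0] * s
        for lab in cells:
            p[lab - 1] += 1
        alloc = allocate_sequence_assemble(p, g, a_par, params)
        total = alloc.t
        abar = alloc.assembly
        if subsumed_ensemble(abar, abar.c, mask, params):
            return total, mask
        if len(cells) == 1:
            c = abar.c
            while c < 2 * params.m_upper:
                alloc = allocate_sequence_assemble(
                    p, g, alloc.assembly.total, params
                )
                total += alloc.t
                c = alloc.assembly.c
            return total, mask | (1 << (cells[0] - 1))
        half = (len(cells) + 1) // 2
        a_total = abar.total
        t_v, mask = walk(cells[:half], mask, a_total)
        t_w, mask = walk(cells[half:], mask, a_total)
        return total + t_v + t_w, mask

    labels = tuple(int(x) for x in labels)
    total, mask = walk(labels, captured_mask, float(a_parent))
    if not charge_root and len(labels) >= 2:
        total -= params.safety_factor * params.m_upper * float(a_parent)
    return total, mask


def _root_assembly(g: tuple[float, ...], params: Parameters) -> float:
    if params.root_assembly == "max":
        return max(g)
    if params.root_assembly == "sum":
        return float(sum(g))
    return float(params.root_assembly)


def brute_force_ensemble(
    profile: CommunityProfile,
    params: Parameters | None = None,
    captured_mask: int = 0,
) -> tuple[float, CaptureDistribution]:
    """Ensemble expectation by explicit enumeration of cell orderings.

    Averages :func:`simulate_ordering` over all distinct orderings of the
    community's label multiset with their multinomial weights.  Factorial
    time; guarded to ``n <= 8``.  Serves as an independent check of the
    dynamic program on tiny communities.
    """
    if params is None:
        params = Parameters()
    n = profile.n
    if n > _BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute force enumeration limited to n <= {_BRUTE_FORCE_GUARD}, got {n}"
        )
    labels = []
    for j, pj in enumerate(profile.p, start=1):
        labels.extend([j] * pj)
    a_root = profile.root_assembly_size(params)
    seen: dict[tuple[int, ...], tuple[float, int]] = {}
    counts: dict[tuple[int, ...], int] = {}
    for perm in permutations(labels):
        if perm not in seen:
            seen[perm] = simulate_ordering(
                perm, profile.g, params, captured_mask, a_root
            )
        counts[perm] = counts.get(perm, 0) + 1
    total_orderings = math.factorial(n)
    e_t = math.fsum(seen[o][0] * k for o, k in counts.items()) / total_orderings
    masses: dict[int, float] = {}
    for o, k in counts.items():
        m = seen[o][1]
        masses[m] = masses.get(m, 0.0) + k / total_orderings
    return e_t, CaptureDistribution.from_sparse(masses, profile.s)


def expected_cost_curve(
    base_profile: Sequence[int],
    g: Sequence[float],
    n_values: Sequence[int],
    params: Parameters | None = None,
) -> pd.DataFrame:
    """Expected-cost trend over community size at a fixed profile shape.

    For each ``n`` the base profile is scaled to ``n`` cells (the scale
    ``n / sum(base_profile)`` must be a positive integer) and analysed.
    The returned frame carries ``E[t]``, the naive comparator, per-genome
    capture probabilities, and residual sums of squares of least-squares
    fits ``E[t] ~ a + b*log(n)`` and ``E[t] ~ a + b*n`` (as frame
    attributes ``rss_log`` / ``rss_linear``) for trend checks.
    """
    if params is None:
        params = Parameters()
    base = tuple(int(x) for x in base_profile)
    base_n = sum(base)
    rows = []
    for n in n_values:
        scale, rem = divmod(int(n), base_n)
        if rem or scale < 1:
            raise ValueError(
                f"n={n} is not a positive integer multiple of sum(base)={base_n}"
            )
        profile = CommunityProfile([scale * x for x in base], g)
        res = ensemble_analysis(profile, params)
        row = {
            "n": int(n),
            "expected_total_bp": res.expected_total,
            "naive_bp": params.m_upper * max(profile.g) * profile.n,
        }
        for j, q in enumerate(res.per_genome_capture, start=1):
            row[f"capture_genome_{j}"] = q
        rows.append(row)
    frame = pd.DataFrame(rows)
    x_log = np.column_stack([np.ones(len(frame)), np.log(frame["n"])])
    x_lin = np.column_stack([np.ones(len(frame)), frame["n"]])
    y = frame["expected_total_bp"].to_numpy()
    for name, x in (("rss_log", x_log), ("rss_linear", x_lin)):
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        frame.attrs[name] = float(np.sum((y - x @ coef) ** 2))
    return frame
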