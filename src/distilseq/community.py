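"""Core domain types for the distilled-sensing genome census.

A microbial community is abstracted as a *population profile*: ``s``
distinct genomes, genome ``j`` present in ``p[j]`` cells and of length
``g[j]`` base pairs.  Genomes are sizes only — the sequencing/assembly
oracle is a black box and no sequence content is ever represented.

Capture states (which distinct genomes have been deeply sequenced and
completely assembled) are binary vectors ``I`` of length ``s``.  They are
stored internally as bit masks where bit ``j-1`` holds ``I_j``, so the
1-based vector index into a capture distribution is ``mask + 1`` — the
decimal value of ``I`` read in reverse order, plus one.  For ``s = 3`` the
state ``I = (0, 1, 1)`` ("q011") therefore has index 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Parameters",
    "CommunityProfile",
    "CaptureState",
    "state_to_index",
    "index_to_state",
    "state_to_bitstring",
    "bitstring_to_state",
    "naive_cost",
    "make_profile",
    "cells_from_profile",
]

#: recognised pool-coverage summary policies (see sensing oracle)
COVERAGE_SUMMARIES = ("min", "mean_weighted")

#: recognised root-assembly initialisation policies
ROOT_ASSEMBLY_POLICIES = ("max", "sum")


@dataclass(frozen=True)
class Parameters:
    """Tunable parameters of the error-free sensing model.

    Attributes
    ----------
    m_upper
        Coverage multiple ``M_u`` above which the assembly of a genome is
        complete (no gaps).  Dimensionless (×).
    m_lower
        Coverage multiple ``M_l`` at or below which an assembly is
        considered unreliable ("low quality") and its pool is explored
        further instead of being compared.
    tau
        Dissimilarity tolerance in ``[0, 1)``: the largest fraction of
        novel content an assembly may carry and still be declared subsumed
        by a reference.
    safety_factor
        Dimensionless multiplier on the error-free allocation lower bound
        ``M_u * a_parent``; 2 by default (sample twice the bound as a safe
        margin).
    root_assembly
        Initialisation of ``a_parent`` for the root sensing round, for
        which no parent exists: ``"max"`` (largest genome size, consistent
        with the naive comparator), ``"sum"`` (sum of distinct genome
        sizes), or an explicit size in bp.
    coverage_summary
        How the scalar pool coverage ``c`` used by the reliability test is
        summarised from per-genome coverages: ``"min"`` over represented
        genomes (conservative default) or ``"mean_weighted"`` (pool-average
        coverage: total nucleotides over total assembled length).
    """

    m_upper: float = 5.0
    m_lower: float = 0.3
    tau: float = 0.2
    safety_factor: float = 2.0
    root_assembly: str | float = "max"
    coverage_summary: str = "min"

    def __post_init__(self) -> None:
        if not self.m_upper > 0:
            raise ValueError(f"m_upper must be > 0, got {self.m_upper}")
        if not 0 <= self.m_lower < self.m_upper:
            raise ValueError(
                f"m_lower must satisfy 0 <= m_lower < m_upper, got {self.m_lower}"
            )
        if not 0 <= self.tau < 1:
            raise ValueError(f"tau must be in [0, 1), got {self.tau}")
        if not self.safety_factor >= 1:
            raise ValueError(f"safety_factor must be >= 1, got {self.safety_factor}")
        if isinstance(self.root_assembly, str):
            if self.root_assembly not in ROOT_ASSEMBLY_POLICIES:
                raise ValueError(
                    f"root_assembly must be one of {ROOT_ASSEMBLY_POLICIES} "
                    f"or a size in bp, got {self.root_assembly!r}"
                )
        elif not self.root_assembly > 0:
            raise ValueError("explicit root_assembly must be > 0 bp")
        if self.coverage_summary not in COVERAGE_SUMMARIES:
            raise ValueError(
                f"coverage_summary must be one of {COVERAGE_SUMMARIES}, "
                f"got {self.coverage_summary!r}"
            )


@dataclass(frozen=True)
class CommunityProfile:
    """Population profile: cells per distinct genome plus genome sizes.

    ``p[j]`` is the number of cells carrying distinct genome ``j`` and
    ``g[j]`` its size in base pairs.  ``n = sum(p)`` is the community size.
    """

    p: tuple[int, ...]
    g: tuple[float, ...]

    def __init__(self, p: Sequence[int], g: Sequence[float]) -> None:
        p = tuple(int(x) for x in p)
        g = tuple(float(x) for x in g)
        if len(p) == 0:
            raise ValueError("empty profile")
        if len(p) != len(g):
            raise ValueError(f"len(p)={len(p)} != len(g)={len(g)}")
        if any(x < 0 for x in p):
            raise ValueError(f"cell counts must be nonnegative, got {p}")
        if any(x <= 0 for x in g):
            raise ValueError(f"genome sizes must be positive, got {g}")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "g", g)

    @property
    def s(self) -> int:
        """Number of distinct genomes (length of the profile)."""
        return len(self.p)

    @property
    def n(self) -> int:
        """Total number of cells."""
        return sum(self.p)

    def root_assembly_size(self, params: Parameters) -> float:
        """Resolve the root ``a_parent`` (bp) under ``params.root_assembly``."""
        if params.root_assembly == "max":
            return float(max(self.g))
        if params.root_assembly == "sum":
            return float(sum(self.g))
        return float(params.root_assembly)


# ---------------------------------------------------------------------------
# Capture-state indexing


def state_to_index(state: Sequence[int] | int, s: int | None = None) -> int:
    """1-based capture-distribution index of a binary capture state.

    ``index = <I, (2^0, 2^1, ..., 2^{s-1})> + 1`` — the state read as a
    reversed binary number, plus one.
    """
    if isinstance(state, int):
        return state + 1
    return sum(int(b) << j for j, b in enumerate(state)) + 1


def index_to_state(index: int, s: int) -> tuple[int, ...]:
    """Inverse of :func:`state_to_index` for ``index`` in ``[1, 2**s]``."""
    if not 1 <= index <= 2**s:
        raise ValueError(f"index {index} out of range for s={s}")
    mask = index - 1
    return tuple((mask >> j) & 1 for j in range(s))


def state_to_bitstring(state: Sequence[int] | int, s: int | None = None) -> str:
    """Human-readable label ``I_1 I_2 ... I_s``, e.g. ``"011"``."""
    if isinstance(state, int):
        if s is None:
            raise ValueError("s required when state is a mask")
        state = index_to_state(state + 1, s)
    return "".join(str(int(b)) for b in state)


def bitstring_to_state(bits: str) -> tuple[int, ...]:
    if not bits or any(ch not in "01" for ch in bits):
        raise ValueError(f"not a capture bitstring: {bits!r}")
    return tuple(int(ch) for ch in bits)


@dataclass(frozen=True)
class CaptureState:
    """Binary vector marking which distinct genomes are fully assembled."""

    I: tuple[int, ...]

    def __init__(self, I: Sequence[int]) -> None:
        I = tuple(int(b) for b in I)
        if any(b not in (0, 1) for b in I):
            raise ValueError(f"capture state entries must be 0/1, got {I}")
        object.__setattr__(self, "I", I)

    @property
    def s(self) -> int:
        return len(self.I)

    @property
    def index(self) -> int:
        return state_to_index(self.I)

    @property
    def mask(self) -> int:
        return self.index - 1

    @property
    def bitstring(self) -> str:
        return state_to_bitstring(self.I)

    @classmethod
    def from_index(cls, index: int, s: int) -> "CaptureState":
        return cls(index_to_state(index, s))

    @classmethod
    def from_mask(cls, mask: int, s: int) -> "CaptureState":
        return cls(index_to_state(mask + 1, s))


# ---------------------------------------------------------------------------
# Costs and fixtures


def naive_cost(profile: CommunityProfile, params: Parameters) -> float:
    """Total nucleotides (bp) of the naive cell-by-cell census.

    Every one of the ``n`` cells is sequenced to coverage ``M_u`` of the
    largest genome that could be present: ``M_u * max_j g_j * n``.
    """
    return params.m_upper * max(profile.g) * profile.n


def make_profile(
    s: int,
    n: int,
    size_range: tuple[float, float] = (1e6, 12e6),
    skew: str = "uniform",
    seed: int = 0,
) -> CommunityProfile:
    """Deterministic community fixture with ``s`` genomes and ``n`` cells.

    ``skew="uniform"`` spreads cells as evenly as possible (``~n/s`` each);
    ``skew="worst"`` puts ``n - s + 1`` cells on genome 1 and one cell on
    each other genome.  Genome sizes are drawn uniformly from
    ``size_range`` (bp) under ``seed``.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if s > n:
        raise ValueError(f"cannot spread {s} distinct genomes over {n} cells")
    lo, hi = size_range
    if not 0 < lo <= hi:
        raise ValueError(f"invalid size_range {size_range}")
    if skew == "uniform":
        base, extra = divmod(n, s)
        p = tuple(base + (1 if j < extra else 0) for j in range(s))
    elif skew == "worst":
        p = (n - s + 1,) + (1,) * (s - 1)
    else:
        raise ValueError(f"unknown skew {skew!r} (expected 'uniform' or 'worst')")
    rng = np.random.default_rng(seed)
    g = tuple(float(x) for x in rng.uniform(lo, hi, size=s))
    return CommunityProfile(p, g)


def cells_from_profile(profile: CommunityProfile, seed: int = 0) -> tuple[int, ...]:
    """One uniformly random ordering of the community's cells.

    Returns a length-``n`` tuple of genome labels in ``1..s`` whose
    multiset equals the profile ``p``.  Deterministic under ``seed``.
    """
    labels = np.repeat(np.arange(1, profile.s + 1), profile.p)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return tuple(int(x) for x in labels)
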