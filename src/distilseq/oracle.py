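"""Error-free sequencing-and-assembly black box.

The wet-lab side of the census — pooling, partial sequencing, co-assembly
— is modelled by an oracle that maps nucleotides sampled from a pool to a
per-genome assembly profile.  Coverage is uniform and error-free: a genome
covered at ``c`` assembles to ``g * c / M_u`` bases until it saturates at
its full length ``g`` when ``c >= M_u``.  Under this model the adaptive
resource-allocation rule reduces to ``t = safety_factor * M_u * a_parent``
nucleotides per pool.

Assemblies of the same genome are nested (a deterministic prefix of the
genome), so set differences between assembly profiles reduce to per-genome
length differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .community import Parameters

__all__ = [
    "AssemblyProfile",
    "AllocationResult",
    "RoundContext",
    "assembly_size",
    "sense_genome",
    "resource_allocate",
    "allocate_sequence_assemble",
    "d_tau",
    "exclusive_size",
    "subsumed",
    "subsumed_ensemble",
]

#: relative tolerance for the subsumption boundary D = 0
_BOUNDARY_RTOL = 1e-12


@dataclass(frozen=True)
class AssemblyProfile:
    """Per-genome assembled lengths (bp) plus a scalar coverage summary."""

    a_bar: tuple[float, ...]
    c: float

    def __init__(self, a_bar: Sequence[float], c: float) -> None:
        a_bar = tuple(float(x) for x in a_bar)
        if any(x < 0 for x in a_bar):
            raise ValueError("assembled lengths must be nonnegative")
        if c < 0:
            raise ValueError("coverage must be nonnegative")
        object.__setattr__(self, "a_bar", a_bar)
        object.__setattr__(self, "c", float(c))

    @property
    def total(self) -> float:
        """Total assembly size ``||a_bar||_1`` in bp."""
        return math.fsum(self.a_bar)

    @classmethod
    def empty(cls, s: int) -> "AssemblyProfile":
        return cls((0.0,) * s, 0.0)


@dataclass(frozen=True)
class AllocationResult:
    """Outcome of sensing one pool: budget split and resulting assembly."""

    t: float  # total nucleotides sampled for the pool (bp)
    t_pc: float  # nucleotides per cell (bp)
    t_pdg: tuple[float, ...]  # nucleotides per distinct genome (bp)
    coverages: tuple[float, ...]  # per-genome coverage (×)
    assembly: AssemblyProfile


@dataclass(frozen=True)
class RoundContext:
    """Sensing statistics of a parent pool feeding the allocation rule."""

    t_parent: float
    a_parent: float
    c_parent: float


def assembly_size(c: float, g: float, params: Parameters) -> float:
    """Assembled length (bp) of a genome of size ``g`` at coverage ``c``.

    Linear ramp ``g * c / M_u`` below the completion coverage ``M_u``,
    saturating at ``g``; continuous at ``c = M_u``.
    """
    if c < 0:
        raise ValueError(f"coverage must be nonnegative, got {c}")
    if g <= 0:
        raise ValueError(f"genome size must be positive, got {g}")
    if c >= params.m_upper:
        return g
    return g * c / params.m_upper


def sense_genome(t: float, g: float, params: Parameters) -> tuple[float, float]:
    """Assembly and coverage of one genome given ``t`` sampled nucleotides.

    Coverage is uniform over the whole genome, ``c = t / g``; the
    assembled length follows the ramp :func:`assembly_size`, i.e.
    ``a = t / M_u`` until the assembly saturates at the complete genome
    for ``c >= M_u``.  Returns ``(a, c)``.
    """
    if t < 0:
        raise ValueError(f"sampled nucleotides must be nonnegative, got {t}")
    if g <= 0:
        raise ValueError(f"genome size must be positive, got {g}")
    c = t / g
    return assembly_size(c, g, params), c


def resource_allocate(
    ctx: RoundContext,
    a_prime: float,
    c_prime: float | None = None,
    params: Parameters | None = None,
) -> float:
    """General adaptive allocation: target sampling size of a child pool.

    ``t = t_parent * c' * a' / (c_parent * a_parent)`` where ``a'`` is the
    child's anticipated assembly size and ``c'`` the intended coverage
    (defaulting to ``M_u`` so the child assembles completely on average).
    """
    if params is None:
        params = Parameters()
    if c_prime is None:
        c_prime = params.m_upper
    if ctx.c_parent <= 0 or ctx.a_parent <= 0:
        raise ValueError(
            "allocation undefined for zero parent coverage/assembly "
            f"(c_parent={ctx.c_parent}, a_parent={ctx.a_parent})"
        )
    if ctx.t_parent <= 0:
        raise ValueError(f"t_parent must be positive, got {ctx.t_parent}")
    return ctx.t_parent * c_prime * a_prime / (ctx.c_parent * ctx.a_parent)


def _pool_coverage(
    coverages: Sequence[float],
    p: Sequence[int],
    total_assembly: float,
    t: float,
    params: Parameters,
) -> float:
    """Scalar coverage summary of a pool under the configured policy."""
    represented = [cov for cov, pj in zip(coverages, p) if pj > 0]
    if not represented:
        return 0.0
    if params.coverage_summary == "min":
        return min(represented)
    # mean_weighted: average coverage of the assembled content, t / ||a||
    return t / total_assembly if total_assembly > 0 else 0.0


def allocate_sequence_assemble(
    p: Sequence[int],
    g: Sequence[float],
    a_parent: float,
    params: Parameters,
) -> AllocationResult:
    """Sense one pool under the error-free model.

    Allocates ``t = safety_factor * M_u * a_parent`` nucleotides to the
    pool, splits them evenly over its cells, and asks the oracle for the
    per-genome assembly: genome ``j`` receives ``t_pc * p_j`` nucleotides,
    hence coverage ``c_j = t_pc * p_j / g_j`` and assembled length
    ``assembly_size(c_j, g_j)``.  Genomes absent from the pool contribute
    nothing.
    """
    n_cells = sum(p)
    if n_cells < 1:
        raise ValueError("pool must contain at least one cell")
    if a_parent <= 0:
        raise ValueError(f"a_parent must be positive, got {a_parent}")
    t = params.safety_factor * params.m_upper * a_parent
    t_pc = t / n_cells
    t_pdg = tuple(t_pc * pj for pj in p)
    a_bar = []
    coverages = []
    for t_j, pj, gj in zip(t_pdg, p, g):
        if pj > 0:
            aj, cj = sense_genome(t_j, gj, params)
        else:
            aj, cj = 0.0, 0.0
        a_bar.append(aj)
        coverages.append(cj)
    total = math.fsum(a_bar)
    c = _pool_coverage(coverages, p, total, t, params)
    return AllocationResult(
        t=t, t_pc=t_pc, t_pdg=t_pdg, coverages=tuple(coverages),
        assembly=AssemblyProfile(a_bar, c),
    )


# ---------------------------------------------------------------------------
# Subsumption


def d_tau(a1_exclusive: float, a1_total: float, params: Parameters) -> float:
    """Thresholded dissimilarity ``tau - ||A1 \\ A2|| / ||A1||``.

    Nonnegative iff assembly 1 is subsumed by the reference: its exclusive
    content is at most a ``tau``-fraction of its size.
    """
    if a1_total <= 0:
        raise ValueError("dissimilarity undefined for an empty assembly")
    if not 0 <= a1_exclusive <= a1_total:
        raise ValueError(
            f"exclusive size {a1_exclusive} outside [0, {a1_total}]"
        )
    return params.tau - a1_exclusive / a1_total


def exclusive_size(a_new: AssemblyProfile, a_ref: AssemblyProfile) -> float:
    """``||A_new \\ A_ref||`` under the nested-assembly model (bp)."""
    return math.fsum(
        max(0.0, an - ar) for an, ar in zip(a_new.a_bar, a_ref.a_bar)
    )


def subsumed(
    a_new: AssemblyProfile,
    a_reference: AssemblyProfile,
    c: float,
    params: Parameters,
) -> bool:
    """Is a pool's assembly subsumed by the reference (captured) assembly?

    A low-quality pool (``c <= M_l``) is never subsumed — it must be
    explored further.  Otherwise subsumption holds iff the pool's
    exclusive content is at most a ``tau``-fraction of its assembly, with
    the boundary ``D = 0`` counting as subsumed.
    """
    if c <= params.m_lower:
        return False
    total = a_new.total
    excl = exclusive_size(a_new, a_reference)
    return d_tau(excl, total, params) >= -_BOUNDARY_RTOL


def subsumed_ensemble(
    a_bar: AssemblyProfile,
    c: float,
    captured_mask: int,
    params: Parameters,
) -> bool:
    """Ensemble-analysis subsumption of a pool against a capture state.

    The exclusive part is the assembled length of genomes not yet captured
    (``I_j = 0``); the pool is subsumed iff that is at most a
    ``tau``-fraction of its total assembly.  ``captured_mask`` holds
    ``I_j`` in bit ``j-1``.
    """
    if c <= params.m_lower:
        return False
    total = a_bar.total
    if total <= 0:
        raise ValueError("subsumption undefined for an empty assembly")
    x = math.fsum(
        aj for j, aj in enumerate(a_bar.a_bar) if not (captured_mask >> j) & 1
    )
    return params.tau - x / total >= -_BOUNDARY_RTOL
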