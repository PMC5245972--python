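"""Place-field maps under a same-interneuron exclusion constraint, and their combinatorics.

Pyramidal cells that couple to the same interneuron disrupt sequence
compression when their place fields overlap, so admissible spatial maps keep
same-interneuron field centers at least a distance ``D`` apart (the exclusion
zone).  On a circular track of length ``L`` discretized into bins of size
``x_res`` this module provides:

* map generators (uniform-random and optimal equally-spaced layouts) and a
  constraint checker;
* the density bound ``F_max = (NI/Np) * (L/D)`` on the fraction of cells that
  can express fields;
* sequential-choice counts of distinct maps (exact product form and its
  Stirling approximation), of cell assemblies, and of phase sequences, all in
  log space via log-gamma with an exact big-integer mode for small instances;
* a brute-force enumeration oracle for tiny instances.

The sequential map-counting argument treats each already-placed field as
removing exactly ``Nd = D/x_res`` bins for the cells of its interneuron
class; it is exact when the removed blocks cannot overlap (e.g. ``Nd == 1``),
and an upper bound otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "TrackDiscretization",
    "ExclusionConstraint",
    "CapacityParams",
    "PlaceFieldMap",
    "ConstraintSaturatedError",
    "random_map",
    "optimal_map",
    "optimal_centers",
    "verify_map",
    "density_bound",
    "exact_map_count",
    "log_map_count",
    "log_map_count_stirling",
    "log_assembly_count",
    "log_assembly_count_stirling",
    "log_sequence_count",
    "log_sequence_count_stirling",
    "brute_force_map_count",
    "ln_to_log10",
]

LN10 = math.log(10.0)


def ln_to_log10(x: float) -> float:
    """Convert a natural logarithm to a base-10 logarithm."""
    return x / LN10


class ConstraintSaturatedError(ValueError):
    """The requested number of fields exceeds what the exclusion constraint admits."""


def _integral_ratio(num: float, den: float, what: str) -> int:
    ratio = num / den
    n = round(ratio)
    if n < 1 or abs(ratio - n) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(f"{what} must be a positive integer, got {ratio}")
    return n


@dataclass(frozen=True)
class TrackDiscretization:
    """Circular track of length ``length`` (m) divided into bins of ``resolution`` (m)."""

    length: float
    resolution: float
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0 or self.resolution <= 0:
            raise ValueError("length and resolution must be > 0")
        _integral_ratio(self.length, self.resolution, "length / resolution")

    @property
    def n_bins(self) -> int:
        return _integral_ratio(self.length, self.resolution, "length / resolution")

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.resolution

    def circular_bin_distance(self, a, b) -> np.ndarray:
        d = np.abs(np.asarray(a) - np.asarray(b))
        if self.circular:
            d = np.minimum(d, self.n_bins - d)
        return d


@dataclass(frozen=True)
class ExclusionConstraint:
    """Minimum same-interneuron separation ``zone_size`` (m) between field centers."""

    zone_size: float

    def __post_init__(self) -> None:
        if self.zone_size <= 0:
            raise ValueError("zone size must be > 0")

    def zone_bins(self, track: TrackDiscretization) -> int:
        return _integral_ratio(self.zone_size, track.resolution, "zone_size / resolution")


@dataclass(frozen=True)
class CapacityParams:
    """Population sizes and counting inputs for the capacity formulas."""

    n_pyramidal: int
    n_interneuron: int
    fields_per_cell: float = 1.0
    assembly_size: int | None = None
    sequence_length: int | None = None

    def __post_init__(self) -> None:
        if self.n_pyramidal < 1 or self.n_interneuron < 1:
            raise ValueError("population sizes must be >= 1")
        if self.fields_per_cell <= 0:
            raise ValueError("fields_per_cell must be > 0")

    @property
    def n_fields(self) -> int:
        """Total number of fields ``F * Np``, rounded to the nearest integer."""
        n = round(self.fields_per_cell * self.n_pyramidal)
        if n < 1:
            raise ValueError("F * Np rounds to zero fields")
        return n


@dataclass(frozen=True)
class PlaceFieldMap:
    """Assignment of active cells to track bins and interneuron classes."""

    bins: np.ndarray  # 0-based bin index per active cell
    interneurons: np.ndarray  # interneuron index per active cell
    track: TrackDiscretization
    constraint: ExclusionConstraint | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.bins)
        g = np.asarray(self.interneurons)
        if b.shape != g.shape or b.ndim != 1:
            raise ValueError("bins and interneurons must be 1-d arrays of equal length")
        if b.size and (b.min() < 0 or b.max() >= self.track.n_bins):
            raise ValueError("bin index out of range")

    @property
    def n_active(self) -> int:
        return int(np.asarray(self.bins).size)

    def positions(self) -> np.ndarray:
        """Field-center positions (m) at the center of each assigned bin."""
        return (np.asarray(self.bins) + 0.5) * self.track.resolution


def _block_assignment(n_cells: int, n_interneuron: int) -> np.ndarray:
    if n_cells % n_interneuron:
        raise ValueError("number of interneurons must divide the number of active cells")
    return np.repeat(np.arange(n_interneuron), n_cells // n_interneuron)


def random_map(
    n_active: int,
    n_interneuron: int,
    track: TrackDiscretization,
    seed: int | np.random.Generator = 0,
) -> PlaceFieldMap:
    """Uniform-random map: each active cell's field bin drawn independently.

    No exclusion constraint is enforced; random maps may violate it, which is
    exactly what degrades sequence compression at high field density.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = rng.integers(0, track.n_bins, size=n_active)
    return PlaceFieldMap(
        bins=bins,
        interneurons=_block_assignment(n_active, n_interneuron),
        track=track,
    )


def optimal_centers(n_active: int, n_interneuron: int, length: float) -> np.ndarray:
    """Continuous optimal field centers (m): same-interneuron fields equally
    spaced, the whole population uniformly tiling the track."""
    if n_active % n_interneuron:
        raise ValueError("number of interneurons must divide the number of active cells")
    per = n_active // n_interneuron
    centers = np.empty(n_active)
    for j in range(n_interneuron):
        within = np.arange(per)
        centers[j * per : (j + 1) * per] = (within * n_interneuron + j) * (length / n_active)
    return centers


def optimal_map(
    n_active: int, n_interneuron: int, track: TrackDiscretization
) -> PlaceFieldMap:
    """Deterministic optimal map on the discretized track (see :func:`optimal_centers`)."""
    pos = optimal_centers(n_active, n_interneuron, track.length)
    bins = np.floor(pos / track.resolution).astype(int) % track.n_bins
    return PlaceFieldMap(
        bins=bins,
        interneurons=_block_assignment(n_active, n_interneuron),
        track=track,
    )


def verify_map(
    pf_map: PlaceFieldMap, constraint: ExclusionConstraint | None = None
) -> list[tuple[int, int]]:
    """List same-interneuron cell pairs whose circular bin distance is below the zone."""
    cons = constraint or pf_map.constraint
    if cons is None:
        raise ValueError("no exclusion constraint supplied")
    nd = cons.zone_bins(pf_map.track)
    bins = np.asarray(pf_map.bins)
    groups = np.asarray(pf_map.interneurons)
    bad: list[tuple[int, int]] = []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        for i, j in combinations(idx.tolist(), 2):
            if pf_map.track.circular_bin_distance(bins[i], bins[j]) < nd:
                bad.append((i, j))
    return bad


def density_bound(n_interneuron: int, n_pyramidal: int, length: float, zone: float) -> float:
    """Maximum fraction of cells that can express fields: ``(NI/Np) * (L/D)``."""
    return (n_interneuron / n_pyramidal) * (length / zone)


def _sequential_factors(
    params: CapacityParams, track: TrackDiscretization, constraint: ExclusionConstraint
) -> list[int]:
    """Integer factors ``Np*Nbins - (i-1)*(Np/NI)*Nd`` of the ordered-choice product."""
    n_fields = params.n_fields
    nbins = track.n_bins
    nd = constraint.zone_bins(track)
    per_class = _integral_ratio(params.n_pyramidal, params.n_interneuron, "Np / NI")
    factors = []
    for i in range(1, n_fields + 1):
        f = params.n_pyramidal * nbins - (i - 1) * per_class * nd
        if f <= 0:
            raise ConstraintSaturatedError(
                f"choice {i} has no admissible cell-bin pairs left "
                f"(field density exceeds the bound {density_bound(params.n_interneuron, params.n_pyramidal, track.length, constraint.zone_size):.4g})"
            )
        factors.append(f)
    return factors


def exact_map_count(
    params: CapacityParams, track: TrackDiscretization, constraint: ExclusionConstraint
) -> Fraction:
    """Sequential-choice count of distinct maps, ``prod_i f_i / (F Np)!``, exactly.

    Returned as a :class:`fractions.Fraction` because the order-correction by
    ``(F Np)!`` need not divide the product evenly outside the regime where
    the sequential argument is exact.
    """
    factors = _sequential_factors(params, track, constraint)
    num = 1
    for f in factors:
        num *= f
    return Fraction(num, math.factorial(params.n_fields))


def log_map_count(
    params: CapacityParams, track: TrackDiscretization, constraint: ExclusionConstraint
) -> float:
    """Natural log of the sequential-choice map count (log-gamma arithmetic)."""
    factors = _sequential_factors(params, track, constraint)
    return float(np.sum(np.log(np.asarray(factors, dtype=float))) - gammaln(params.n_fields + 1))


def log_map_count_stirling(
    params: CapacityParams, track: TrackDiscretization, constraint: ExclusionConstraint
) -> float:
    """Stirling approximation to the log map count.

    ``F Np (1 + ln L - ln x_res - ln F) + sum_{i=1}^{F Np} ln(1 - (i-1) D / (L NI))``
    """
    n_fields = params.n_fields
    f = params.fields_per_cell
    ratio = constraint.zone_size / (track.length * params.n_interneuron)
    i = np.arange(n_fields)
    args = 1.0 - i * ratio
    if np.any(args <= 0):
        raise ConstraintSaturatedError("Stirling sum has a non-positive log argument")
    lead = n_fields * (1.0 + math.log(track.length) - math.log(track.resolution) - math.log(f))
    return float(lead + np.sum(np.log(args)))


def _log_binomial(n: float, k: float) -> float:
    if k < 0 or k > n:
        raise ValueError(f"binomial coefficient C({n}, {k}) undefined")
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def log_assembly_count(params: CapacityParams) -> float:
    """Natural log of the number of cell assemblies, ``C(NI, n) * (Np/NI)^n``.

    An assembly of ``n`` coactive cells satisfying the constraint uses ``n``
    distinct interneurons, one cell each.  Evaluated via log-gamma (not the
    printed Stirling expansion, available separately).
    """
    n = params.assembly_size
    if n is None:
        raise ValueError("assembly_size not set")
    if n > params.n_interneuron:
        raise ValueError("assembly size exceeds the number of interneurons")
    return _log_binomial(params.n_interneuron, n) + n * math.log(
        params.n_pyramidal / params.n_interneuron
    )


def log_assembly_count_stirling(params: CapacityParams) -> float:
    """Stirling form: ``NI ln NI - (NI-n) ln(NI-n) + n (ln Np - ln NI - ln n)``."""
    ni, n = params.n_interneuron, params.assembly_size
    if n is None:
        raise ValueError("assembly_size not set")
    if not 0 < n < ni:
        raise ValueError("Stirling form requires 0 < n < NI")
    return (
        ni * math.log(ni)
        - (ni - n) * math.log(ni - n)
        + n * (math.log(params.n_pyramidal) - math.log(ni) - math.log(n))
    )


def log_sequence_count(params: CapacityParams) -> float:
    """Natural log of the number of phase sequences of ``m`` disjoint assemblies.

    ``sum_{i=1}^{m} ln C(NI - (i-1) n, n) + m n ln(Np / NI)`` -- the
    interneuron pool depletes by ``n`` with each successive assembly.
    """
    n, m = params.assembly_size, params.sequence_length
    if n is None or m is None:
        raise ValueError("assembly_size and sequence_length must be set")
    if m * n > params.n_interneuron:
        raise ValueError("interneuron pool exhausted: m * n > NI")
    total = 0.0
    for i in range(m):
        total += _log_binomial(params.n_interneuron - i * n, n)
    return total + m * n * math.log(params.n_pyramidal / params.n_interneuron)


def log_sequence_count_stirling(params: CapacityParams) -> float:
    """Stirling form of the phase-sequence count."""
    ni, n, m = params.n_interneuron, params.assembly_size, params.sequence_length
    if n is None or m is None:
        raise ValueError("assembly_size and sequence_length must be set")
    if m * n >= ni + 1:
        raise ValueError("interneuron pool exhausted")
    total = 0.0
    for i in range(1, m + 1):
        hi = ni - (i - 1) * n
        lo = ni - i * n
        total += hi * math.log(hi) - (lo * math.log(lo) if lo > 0 else 0.0)
        total += n * (math.log(params.n_pyramidal) - math.log(ni) - math.log(n))
    return total


def brute_force_map_count(
    params: CapacityParams,
    track: TrackDiscretization,
    constraint: ExclusionConstraint,
    max_work: int = 10_000_000,
) -> int:
    """Exhaustively count distinct constraint-satisfying maps on a tiny instance.

    A map is an unordered set of ``F Np`` distinct (cell, bin) fields in which
    every same-interneuron pair (including two fields of one cell) sits at
    circular bin distance ``>= Nd``.  This is the symmetric-minimum-distance
    reading of the constraint, matching :func:`verify_map`; for ``Nd == 1`` it
    coincides exactly with the sequential product divided by ``(F Np)!``.
    """
    n_fields = params.n_fields
    nbins = track.n_bins
    npyr = params.n_pyramidal
    per_class = _integral_ratio(npyr, params.n_interneuron, "Np / NI")
    nd = constraint.zone_bins(track)
    universe = npyr * nbins
    est = math.comb(universe, n_fields)
    if est > max_work:
        raise ValueError(f"instance too large: C({universe}, {n_fields}) = {est} > {max_work}")

    def cell_of(pair: int) -> int:
        return pair // nbins

    def bin_of(pair: int) -> int:
        return pair % nbins

    def cls_of(pair: int) -> int:
        return cell_of(pair) // per_class

    def conflict(a: int, b: int) -> bool:
        if cls_of(a) != cls_of(b):
            return False
        d = abs(bin_of(a) - bin_of(b))
        if track.circular:
            d = min(d, nbins - d)
        return d < nd

    count = 0
    chosen: list[int] = []

    def extend(start: int) -> None:
        nonlocal count
        if len(chosen) == n_fields:
            count += 1
            return
        for pair in range(start, universe):
            if any(conflict(pair, c) for c in chosen):
                continue
            chosen.append(pair)
            extend(pair + 1)
            chosen.pop()

    extend(0)
    return count
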