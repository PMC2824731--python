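"""Monte-Carlo simulation of hydrodynamic shearing of DNA molecules.

Hydrodynamic shearing fragments DNA by forcing a solution through a narrow
constriction: drag stretches each strand until it snaps, preferentially near
its midpoint.  The model implemented here is iterative near-midpoint
breakage: every fragment whose length is at least a *critical length* breaks
at a position drawn from ``Normal(L/2, sd_frac * L)``; fragments below the
critical length experience too little drag and are final.  The critical
length is the single knob that maps onto the shear speed setting of a
laboratory instrument, and :func:`calibrate_critical_length` finds the value
that yields a requested mean final fragment size.

Two topologies are supported.  A linear molecule has fixed termini at 0 and
``length_bp`` and its shear-resistant terminal zones are the object of study.
A circular molecule has no midpoint, so its first break is drawn uniformly;
the molecule is then re-coordinatized to start at that break and sheared as a
linear molecule.  By rotational symmetry, pooled circular breaks are uniform
on the original frame.

Coordinates are integers, 0-based and half-open throughout, so that fragment
tiling of the parent is exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .errors import CalibrationError

Topology = Literal["linear", "circular"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class MoleculeSpec:
    """A parent DNA molecule: length, topology and optional sequence."""

    name: str
    length_bp: int
    topology: Topology = "linear"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"length_bp must be >= 1, got {self.length_bp}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValueError(
                f"sequence length {len(self.sequence)} != length_bp {self.length_bp}"
            )


@dataclass(frozen=True)
class ShearParams:
    """Parameters of the iterative midpoint-breakage model.

    ``sd_frac`` is the standard deviation of the break position as a fraction
    of fragment length (0.125 is the measured value for hydrodynamic
    shearing; 0 gives deterministic midpoint splitting).  Fragments shorter
    than ``critical_length_bp`` never break — the hard-threshold stand-in for
    drag forces becoming too small.
    """

    sd_frac: float = 0.125
    critical_length_bp: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.sd_frac < 0.5):
            raise ValueError(f"sd_frac must be in [0, 0.5), got {self.sd_frac}")
        if self.critical_length_bp < 2:
            raise ValueError(
                f"critical_length_bp must be >= 2, got {self.critical_length_bp}"
            )


@dataclass
class BreakSet:
    """Ordered break coordinates on a parent molecule.

    Simulated linear breaks are strictly increasing and interior to
    ``(0, length_bp)``.  Circular breaks live on ``[0, length_bp)`` in the
    original (unrotated) frame.  Break sets recovered from read mapping may
    contain duplicates and boundary coordinates, because break *density* is
    the analyte.
    """

    molecule: MoleculeSpec | None
    coordinates: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.int64)
        if self.coordinates.ndim != 1:
            raise ValueError("coordinates must be one-dimensional")
        if np.any(np.diff(self.coordinates) < 0):
            raise ValueError("coordinates must be sorted nondecreasing")

    def __len__(self) -> int:
        return int(self.coordinates.size)


@dataclass(frozen=True)
class Fragment:
    """A sheared piece on the parent frame, 0-based half-open."""

    parent: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid fragment [{self.start}, {self.end})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def random_sequence(length_bp: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string, used to give simulated molecules a sequence."""
    idx = rng.integers(0, 4, size=length_bp)
    return _BASES[idx].tobytes().decode("ascii")


def random_molecule(
    name: str,
    length_bp: int,
    topology: Topology,
    rng: np.random.Generator,
) -> MoleculeSpec:
    """A molecule with a uniform random sequence attached."""
    return MoleculeSpec(name, length_bp, topology, random_sequence(length_bp, rng))


def draw_break_position(
    length_bp: int, params: ShearParams, rng: np.random.Generator
) -> int:
    """Draw one break position on a fragment of the given length.

    The position is ``Normal(length_bp / 2, sd_frac * length_bp)`` rounded to
    the nearest integer.  Draws outside the interior ``[1, length_bp - 1]``
    are redrawn rather than clamped, so no artificial pile-up occurs at the
    fragment boundaries.
    """
    if length_bp < 2:
        raise ValueError(f"cannot break a fragment of length {length_bp} (< 2)")
    mid = length_bp / 2.0
    sd = params.sd_frac * length_bp
    if sd == 0:
        return min(max(round(mid), 1), length_bp - 1)
    while True:
        pos = round(rng.normal(mid, sd))
        if 1 <= pos <= length_bp - 1:
            return int(pos)


def _shear_interval(
    length_bp: int, params: ShearParams, rng: np.random.Generator
) -> tuple[list[int], list[tuple[int, int]]]:
    """Core recursion on [0, length_bp): returns (interior breaks, fragments)."""
    breaks: list[int] = []
    final: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = [(0, length_bp)]
    while stack:
        s, e = stack.pop()
        if e - s < params.critical_length_bp:
            final.append((s, e))
            continue
        cut = s + draw_break_position(e - s, params, rng)
        breaks.append(cut)
        # push right first so the left child is processed next (left-to-right order)
        stack.append((cut, e))
        stack.append((s, cut))
    final.sort()
    breaks.sort()
    return breaks, final


def shear_linear(
    molecule: MoleculeSpec, params: ShearParams, rng: np.random.Generator
) -> tuple[BreakSet, list[Fragment]]:
    """Shear a linear molecule by iterative near-midpoint breakage.

    Fragments at or above the critical length keep breaking; the returned
    fragments tile ``[0, length_bp)`` exactly and the break coordinates are
    reported on the parent frame.
    """
    if molecule.topology != "linear":
        raise ValueError(f"shear_linear requires a linear molecule, got {molecule.topology}")
    breaks, intervals = _shear_interval(molecule.length_bp, params, rng)
    frags = [Fragment(molecule.name, s, e) for s, e in intervals]
    return BreakSet(molecule, np.array(breaks, dtype=np.int64)), frags


def shear_circular_with_offset(
    molecule: MoleculeSpec, params: ShearParams, rng: np.random.Generator
) -> tuple[BreakSet, list[Fragment], int]:
    """Shear a circular molecule, also returning the rotation offset.

    A circle has no midpoint, so the first break is uniform on
    ``[0, length_bp)``.  The molecule is re-coordinatized to start at that
    break (the returned *offset*): fragments are emitted on the rotated frame
    (position 0 of the rotated frame is original position ``offset``), while
    break coordinates are mapped back to the original frame so pooled breaks
    can be profiled against the original reference.
    """
    if molecule.topology != "circular":
        raise ValueError(f"requires a circular molecule, got {molecule.topology}")
    L = molecule.length_bp
    if L < params.critical_length_bp:
        frag = Fragment(molecule.name, 0, L)
        return BreakSet(molecule), [frag], 0
    offset = int(rng.integers(0, L))
    rot_breaks, intervals = _shear_interval(L, params, rng)
    coords = sorted(((b + offset) % L for b in rot_breaks), key=int)
    coords = np.sort(np.array(list(coords) + [offset], dtype=np.int64))
    frags = [Fragment(molecule.name, s, e) for s, e in intervals]
    return BreakSet(molecule, coords), frags, offset


def shear_circular(
    molecule: MoleculeSpec, params: ShearParams, rng: np.random.Generator
) -> tuple[BreakSet, list[Fragment]]:
    """Shear a circular molecule (see :func:`shear_circular_with_offset`)."""
    breakset, frags, _ = shear_circular_with_offset(molecule, params, rng)
    return breakset, frags


def shear(
    molecule: MoleculeSpec, params: ShearParams, rng: np.random.Generator
) -> tuple[BreakSet, list[Fragment]]:
    """Topology-dispatching shear."""
    if molecule.topology == "linear":
        return shear_linear(molecule, params, rng)
    return shear_circular(molecule, params, rng)


def replicate_rng(base_seed: int, *indices: int) -> np.random.Generator:
    """Seeded generator for one replicate / stage.

    Replicates derive their streams from the base seed plus an index tuple
    via :class:`numpy.random.SeedSequence`, which is collision-free and
    reproducible across runs.
    """
    return np.random.default_rng((base_seed, *indices))


def iter_replicates(
    molecule: MoleculeSpec,
    params: ShearParams,
    replicates: int,
    base_seed: int,
) -> Iterator[tuple[BreakSet, list[Fragment]]]:
    """Independent seeded shear replicates of one molecule."""
    for i in range(replicates):
        yield shear(molecule, params, replicate_rng(base_seed, i))


def pooled_breaks(
    molecule: MoleculeSpec,
    params: ShearParams,
    replicates: int,
    base_seed: int,
) -> np.ndarray:
    """Break coordinates pooled over seeded replicates (sorted)."""
    chunks = [bs.coordinates for bs, _ in iter_replicates(molecule, params, replicates, base_seed)]
    if not chunks:
        return np.array([], dtype=np.int64)
    return np.sort(np.concatenate(chunks))


def _mean_final_length(
    molecule_length_bp: int,
    params: ShearParams,
    critical_length_bp: int,
    replicates: int,
    rng: np.random.Generator,
) -> float:
    p = dataclasses.replace(params, critical_length_bp=critical_length_bp)
    total_frags = 0
    for _ in range(replicates):
        breaks, _ = _shear_interval(molecule_length_bp, p, rng)
        total_frags += len(breaks) + 1
    return molecule_length_bp * replicates / total_frags


def calibrate_critical_length(
    target_mean_bp: int,
    molecule_length_bp: int,
    params: ShearParams,
    rng: np.random.Generator,
    *,
    replicates: int = 128,
    tol: float = 0.02,
) -> int:
    """Find the critical length whose Monte-Carlo mean fragment size hits a target.

    Mean final fragment length is nondecreasing in the critical length
    (larger threshold -> fragments stop breaking sooner -> larger pieces), so
    an integer bisection converges.  The returned value reproduces
    ``target_mean_bp`` within ``tol`` (relative), verified by a fresh
    re-simulation; otherwise :class:`CalibrationError` is raised.
    """
    if not 2 <= target_mean_bp < molecule_length_bp:
        raise CalibrationError(
            f"target mean {target_mean_bp} must lie in [2, molecule length {molecule_length_bp})"
        )

    def mean_for(crit: int, reps: int = replicates) -> float:
        return _mean_final_length(molecule_length_bp, params, crit, reps, rng)

    lo = max(2, target_mean_bp // 2)
    while lo > 2 and mean_for(lo) > target_mean_bp:
        lo = max(2, lo // 2)
    hi = min(molecule_length_bp + 1, max(lo + 1, 4 * target_mean_bp))
    while mean_for(hi) < target_mean_bp and hi < molecule_length_bp + 1:
        hi = min(molecule_length_bp + 1, hi * 2)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mean_for(mid) < target_mean_bp:
            lo = mid
        else:
            hi = mid
    # pick the closer of the two bracketing integers with a larger check run
    candidates = sorted({lo, hi})
    best, best_err = None, None
    for crit in candidates:
        err = abs(mean_for(crit, 2 * replicates) - target_mean_bp)
        if best_err is None or err < best_err:
            best, best_err = crit, err
    assert best is not None and best_err is not None
    if best_err > tol * target_mean_bp:
        raise CalibrationError(
            f"no critical length reproduces mean {target_mean_bp} bp within "
            f"{tol:.0%} (best error {best_err:.0f} bp at critical length {best})"
        )
    return best


def fragment_boundaries(fragments: Sequence[Fragment]) -> np.ndarray:
    """All fragment boundary coordinates (start and end of each), sorted."""
    out = np.empty(2 * len(fragments), dtype=np.int64)
    for i, f in enumerate(fragments):
        out[2 * i] = f.start
        out[2 * i + 1] = f.end
    return np.sort(out)
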