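"""Locate shearing breakpoints and insert sizes from clone end reads.

The start of every insert read marks a shearing breakpoint: the read begins
with the vector polylinker, and the first ``anchor_k`` bases of the insert
uniquely place it on the reference.  Mapping is exact-match on both strands
(simulated reads are error-free), mate pairs are validated for opposite
orientation and plausible insert size, and the validated insert boundaries
become the break coordinates whose density is profiled downstream.

Coordinate convention: a break boundary is always reported in the forward
0-based half-open frame.  A forward-strand hit reports the k-mer's left end;
a reverse-strand hit reports the k-mer's right end (the insert's outermost
base), so the left and right mates of one clone reproduce the fragment's
``(start, end)`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .errors import ConfigurationError, InsufficientDataError
from .library_prep import DEFAULT_POLYLINKER, ReadRecord
from .shearing import BreakSet, MoleculeSpec


@dataclass(frozen=True)
class MapperParams:
    """Anchor length, expected polylinker and chimera-filter settings.

    ``anchor_k`` bases immediately after the polylinker are used as the
    placement anchor.  ``chimera_size_factor`` times the mean insert size is
    the oversize threshold; mates mapping on the same strand are orientation
    chimeras when ``require_opposite_orientation`` is set.
    """

    anchor_k: int = 24
    polylinker: str = DEFAULT_POLYLINKER
    chimera_size_factor: float = 2.0
    require_opposite_orientation: bool = True

    def __post_init__(self) -> None:
        if self.anchor_k < 8:
            raise ValueError(f"anchor_k must be >= 8, got {self.anchor_k}")
        if self.chimera_size_factor <= 1:
            raise ValueError(
                f"chimera_size_factor must be > 1, got {self.chimera_size_factor}"
            )


@dataclass(frozen=True)
class MappedRead:
    """A read placed (or not) on the reference.

    ``insert_start`` is present iff ``status == 'mapped'`` and is the break
    boundary implied by the read start, in forward half-open frame.
    """

    read_id: str
    clone_id: str
    mate: str
    insert_start: int | None
    strand: str | None
    status: str  # mapped | ambiguous | unmapped | no_polylinker


@dataclass(frozen=True)
class CloneInsert:
    """A validated (or rejected) insert interval implied by a mate pair."""

    clone_id: str
    start: int | None
    end: int | None
    status: str  # valid | chimera_orientation | chimera_size | incomplete

    @property
    def size_bp(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return self.end - self.start


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_insert_start(
    read: ReadRecord, reference: MoleculeSpec, params: MapperParams
) -> MappedRead:
    """Strip the polylinker, anchor the next k bases, exact-search both strands.

    Exactly one hit across both strands maps the read; multiple hits make it
    ambiguous (excluded from break calling as the conservative treatment of
    repeats); zero hits leave it unmapped.  Circular references are searched
    across the origin.
    """
    if reference.sequence is None:
        raise ConfigurationError("reference molecule carries no sequence")
    seq = read.sequence
    pl = params.polylinker
    k = params.anchor_k
    if seq is None or not seq.startswith(pl):
        return MappedRead(read.read_id, read.clone_id, read.mate, None, None, "no_polylinker")
    anchor = seq[len(pl) : len(pl) + k]
    if len(anchor) < k:
        return MappedRead(read.read_id, read.clone_id, read.mate, None, None, "unmapped")
    ref = reference.sequence
    L = reference.length_bp
    circular = reference.topology == "circular"
    space = ref + ref[: k - 1] if circular else ref
    hits: list[tuple[int, str]] = [(p, "+") for p in _find_all(space, anchor)]
    for p in _find_all(space, reverse_complement(anchor)):
        boundary = (p + k) % L if circular else p + k
        hits.append((boundary, "-"))
    if len(hits) == 1:
        pos, strand = hits[0]
        return MappedRead(read.read_id, read.clone_id, read.mate, int(pos), strand, "mapped")
    status = "ambiguous" if hits else "unmapped"
    return MappedRead(read.read_id, read.clone_id, read.mate, None, None, status)


def validate_clone_pair(
    left: MappedRead,
    right: MappedRead,
    mean_insert_bp: float,
    params: MapperParams,
) -> CloneInsert:
    """Classify a mate pair as a valid insert or a chimera.

    Both mates mapped, opposite strands, inward-facing geometry and implied
    size at most ``chimera_size_factor x mean_insert_bp`` -> valid.  Same
    strand (or outward-facing mates, whose implied size is negative) ->
    orientation chimera; oversized -> size chimera; an unplaced mate ->
    incomplete.
    """
    cid = left.clone_id
    if left.status != "mapped" or right.status != "mapped":
        return CloneInsert(cid, None, None, "incomplete")
    if params.require_opposite_orientation and left.strand == right.strand:
        return CloneInsert(cid, None, None, "chimera_orientation")
    plus, minus = (left, right) if left.strand == "+" else (right, left)
    start, end = plus.insert_start, minus.insert_start
    assert start is not None and end is not None
    if end <= start:
        return CloneInsert(cid, None, None, "chimera_orientation")
    if end - start > params.chimera_size_factor * mean_insert_bp:
        return CloneInsert(cid, None, None, "chimera_size")
    return CloneInsert(cid, start, end, "valid")


def pair_reads(
    mapped: Iterable[MappedRead],
) -> dict[str, dict[str, MappedRead]]:
    """Group mapped reads by clone, keyed by mate side."""
    pairs: dict[str, dict[str, MappedRead]] = {}
    for m in mapped:
        pairs.setdefault(m.clone_id, {})[m.mate] = m
    return pairs


def estimate_mean_insert(mapped: Iterable[MappedRead]) -> float:
    """Provisional mean insert size from opposite-strand, inward-facing pairs.

    This is the first pass of the two-pass chimera-size filter: the mean is
    estimated from all provisionally valid pairs, then pairs are re-checked
    against ``chimera_size_factor`` times that mean.  On clean data the
    procedure is a fixed point.
    """
    sizes = []
    for mates in pair_reads(mapped).values():
        left, right = mates.get("left"), mates.get("right")
        if left is None or right is None:
            continue
        if left.status != "mapped" or right.status != "mapped":
            continue
        if left.strand == right.strand:
            continue
        plus, minus = (left, right) if left.strand == "+" else (right, left)
        if minus.insert_start > plus.insert_start:
            sizes.append(minus.insert_start - plus.insert_start)
    if not sizes:
        raise InsufficientDataError("no provisionally valid pairs to estimate mean insert")
    return float(np.mean(sizes))


def validate_clones(
    mapped: Iterable[MappedRead],
    params: MapperParams,
    mean_insert_bp: float | None = None,
) -> list[CloneInsert]:
    """Two-pass validation of all clones: estimate mean insert, then filter."""
    mapped = list(mapped)
    if mean_insert_bp is None:
        try:
            mean_insert_bp = estimate_mean_insert(mapped)
        except InsufficientDataError:
            mean_insert_bp = math.inf  # nothing to size-filter against
    inserts = []
    for cid, mates in pair_reads(mapped).items():
        left, right = mates.get("left"), mates.get("right")
        if left is None or right is None:
            inserts.append(CloneInsert(cid, None, None, "incomplete"))
            continue
        inserts.append(validate_clone_pair(left, right, mean_insert_bp, params))
    return inserts


def breaks_from_inserts(
    inserts: Sequence[CloneInsert], molecule: MoleculeSpec | None = None
) -> BreakSet:
    """Break boundaries from valid inserts: each start and end, duplicates kept.

    Every shear breakpoint is a boundary between two fragments, so both ends
    of every validated insert are emitted; duplicates are retained because
    break *density* is the analyte.
    """
    coords: list[int] = []
    for ins in inserts:
        if ins.status == "valid":
            coords.append(ins.start)  # type: ignore[arg-type]
            coords.append(ins.end)  # type: ignore[arg-type]
    return BreakSet(molecule, np.sort(np.array(coords, dtype=np.int64)))


def insert_size_stats(inserts: Sequence[CloneInsert]) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and count of valid insert sizes."""
    sizes = np.array(
        [ins.size_bp for ins in inserts if ins.status == "valid"], dtype=float
    )
    if sizes.size < 2:
        raise InsufficientDataError(
            f"need >= 2 valid inserts for size statistics, got {sizes.size}"
        )
    return float(sizes.mean()), float(sizes.std(ddof=1)), int(sizes.size)


def dedupe_inserts(inserts: Sequence[CloneInsert]) -> list[CloneInsert]:
    """Drop duplicate valid (start, end) intervals, keeping first occurrence.

    Off by default in the pipeline (density is read-derived); exposed for
    callers who want unique clones.
    """
    seen: set[tuple[int, int]] = set()
    out = []
    for ins in inserts:
        if ins.status == "valid":
            key = (ins.start, ins.end)
            if key in seen:
                continue
            seen.add(key)
        out.append(ins)
    return out
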