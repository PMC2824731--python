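"""Post-shear library construction: size selection, end reads, chimeras.

Models the steps between shearing and sequencing in a shotgun project: a
hard gel size-selection window, cloning into a vector whose polylinker
appears as a fixed prefix on every read, paired end-read generation from the
two ends of each insert, and optional injection of chimeric clones (the
artefacts the downstream mate-pair filters are designed to catch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .shearing import Fragment, MoleculeSpec

logger = logging.getLogger(__name__)

#: Fixed 10 bp cloning-site remnant prepended to every read, standing in for
#: the vector polylinker sequence visible at the start of insert reads.
DEFAULT_POLYLINKER = "TCGAGGTCGA"

#: Reads shorter than this are not informative and such fragments are skipped.
MIN_READ_BP = 50


@dataclass(frozen=True)
class LibraryParams:
    """Size-selection window, read-length model, polylinker and chimera rate.

    Defaults model a typical ~4 kb shotgun library: gel window 3.8-4.2 kb,
    read lengths Normal(400, 30) bp truncated to [50, fragment length].
    """

    select_min_bp: int = 3800
    select_max_bp: int = 4200
    read_len_mean_bp: int = 400
    read_len_sd_bp: int = 30
    polylinker: str = DEFAULT_POLYLINKER
    chimera_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.select_min_bp <= self.select_max_bp:
            raise ValueError(
                f"invalid selection window [{self.select_min_bp}, {self.select_max_bp}]"
            )
        if self.read_len_mean_bp < 1:
            raise ValueError("read_len_mean_bp must be >= 1")
        if self.read_len_sd_bp < 0:
            raise ValueError("read_len_sd_bp must be >= 0")
        if not 0 <= self.chimera_rate <= 1:
            raise ValueError(f"chimera_rate must be in [0, 1], got {self.chimera_rate}")


@dataclass
class ReadRecord:
    """One simulated end read with its ground truth on the parent frame.

    ``sequence`` is polylinker + insert prefix (``None`` in sequence-free
    mode).  ``truth_start``/``truth_end`` give the covered parent interval and
    ``truth_strand`` the strand read; ``truth_chimera`` records whether the
    clone was rewritten as an orientation or size chimera.
    """

    clone_id: str
    mate: str  # "left" | "right"
    sequence: str | None
    truth_start: int | None = None
    truth_end: int | None = None
    truth_strand: str | None = None
    truth_chimera: str | None = None

    @property
    def read_id(self) -> str:
        return f"{self.clone_id}/{1 if self.mate == 'left' else 2}"


def size_select(
    fragments: Sequence[Fragment], params: LibraryParams
) -> list[Fragment]:
    """Hard gel window: keep fragments with length in [select_min, select_max].

    A pure filter — fragments are not modified and order is preserved; an
    empty result is valid.
    """
    return [
        f
        for f in fragments
        if params.select_min_bp <= f.length_bp <= params.select_max_bp
    ]


def _draw_read_length(
    frag_len: int, params: LibraryParams, rng: np.random.Generator
) -> int:
    r = int(round(rng.normal(params.read_len_mean_bp, params.read_len_sd_bp)))
    return int(min(max(r, MIN_READ_BP), frag_len))


def generate_end_reads(
    fragments: Sequence[Fragment],
    parent: MoleculeSpec,
    params: LibraryParams,
    rng: np.random.Generator,
    *,
    id_prefix: str = "clone",
) -> list[ReadRecord]:
    """Two end reads per fragment: left mate forward, right mate reverse.

    The left mate covers ``[start, start + r1)`` on the forward strand; the
    right mate covers ``[end - r2, end)`` and is reverse-complemented, so the
    two mates of a clone derive from opposite ends and opposite strands.
    Emitted sequences are polylinker + insert prefix when the parent carries
    a sequence.  Fragments shorter than ``MIN_READ_BP`` are skipped (count
    logged).
    """
    seq = parent.sequence
    reads: list[ReadRecord] = []
    skipped = 0
    for i, frag in enumerate(fragments):
        if frag.length_bp < MIN_READ_BP:
            skipped += 1
            continue
        clone_id = f"{id_prefix}{i:05d}"
        r1 = _draw_read_length(frag.length_bp, params, rng)
        r2 = _draw_read_length(frag.length_bp, params, rng)
        left_seq = None if seq is None else params.polylinker + seq[frag.start : frag.start + r1]
        right_seq = (
            None
            if seq is None
            else params.polylinker + reverse_complement(seq[frag.end - r2 : frag.end])
        )
        reads.append(
            ReadRecord(clone_id, "left", left_seq, frag.start, frag.start + r1, "+")
        )
        reads.append(
            ReadRecord(clone_id, "right", right_seq, frag.end - r2, frag.end, "-")
        )
    if skipped:
        logger.info("skipped %d fragments shorter than %d bp", skipped, MIN_READ_BP)
    return reads


def inject_chimeras(
    reads: Sequence[ReadRecord],
    rate: float,
    rng: np.random.Generator,
    *,
    polylinker_len: int = len(DEFAULT_POLYLINKER),
) -> list[ReadRecord]:
    """Rewrite a fraction ``rate`` of clones as chimeras, recording truth.

    Two classes, chosen with equal probability per affected clone:

    * *orientation* — the right mate's insert portion is reverse-complemented
      in place, so both mates read the same strand;
    * *size* — the right mate is replaced by a copy of the right mate of a
      distant clone, so the implied insert is far larger (> 3x the mean) than
      a real insert.  If no sufficiently distant donor exists the clone falls
      back to the orientation class.

    Returns a new list; input records are never mutated.
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    by_clone: dict[str, dict[str, ReadRecord]] = {}
    order: list[str] = []
    for r in reads:
        if r.clone_id not in by_clone:
            order.append(r.clone_id)
            by_clone[r.clone_id] = {}
        by_clone[r.clone_id][r.mate] = r

    spans = [
        by_clone[c]["right"].truth_end - by_clone[c]["left"].truth_start
        for c in order
        if "left" in by_clone[c] and "right" in by_clone[c]
    ]
    mean_span = float(np.mean(spans)) if spans else 0.0

    out: dict[str, dict[str, ReadRecord]] = {
        c: {m: replace(r) for m, r in mates.items()} for c, mates in by_clone.items()
    }
    for cid in order:
        if rng.random() >= rate:
            continue
        mates = out[cid]
        if "left" not in mates or "right" not in mates:
            continue
        kind = "orientation" if rng.random() < 0.5 else "size"
        if kind == "size":
            left_start = mates["left"].truth_start
            donors = [
                c
                for c in order
                if c != cid
                and "right" in by_clone[c]
                and by_clone[c]["right"].truth_end - left_start > 3 * mean_span
            ]
            if donors:
                donor = by_clone[donors[int(rng.integers(len(donors)))]]["right"]
                mates["right"] = replace(donor, clone_id=cid, truth_chimera="size")
                mates["left"].truth_chimera = "size"
                continue
            kind = "orientation"  # no distant donor available
        right = mates["right"]
        if right.sequence is not None:
            insert = right.sequence[polylinker_len:]
            right.sequence = right.sequence[:polylinker_len] + reverse_complement(insert)
        right.truth_strand = "+" if right.truth_strand == "-" else "-"
        right.truth_chimera = "orientation"
        mates["left"].truth_chimera = "orientation"
    return [out[c][m] for c in order for m in ("left", "right") if m in out[c]]
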