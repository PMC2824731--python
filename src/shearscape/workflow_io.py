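"""Configuration, file I/O and the end-to-end experiment runner.

File formats are plain text throughout: FASTA for sequences and reads
(80-column wrap, mate naming ``cloneNNNNN/1`` / ``cloneNNNNN/2``), 3-column
BED for break coordinates (0-based half-open, one row per break), TSV for
fragments, mapped reads, inserts and window profiles, JSON for reports, and
YAML for experiment configuration.

:func:`run_experiment` reproduces the three-arm study design in one call:
the same ~36 kb molecule sheared in circular form at a ~3.8 kb mean (the
control, whose breaks are uniform), in linear form at ~3.8 kb, and in linear
form at ~1.9 kb, each followed by size selection, paired end-read
generation, mapping and terminus statistics.  The whole run is deterministic
given the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from . import __version__
from .break_mapping import (
    CloneInsert,
    MappedRead,
    MapperParams,
    breaks_from_inserts,
    insert_size_stats,
    locate_insert_start,
    validate_clones,
)
from .errors import InsufficientDataError
from .library_prep import (
    DEFAULT_POLYLINKER,
    LibraryParams,
    ReadRecord,
    generate_end_reads,
    inject_chimeras,
    size_select,
)
from .shearing import (
    BreakSet,
    Fragment,
    MoleculeSpec,
    ShearParams,
    calibrate_critical_length,
    random_sequence,
    replicate_rng,
    shear_circular_with_offset,
    shear_linear,
)
from .terminus_analysis import (
    TerminusReport,
    WindowProfile,
    WindowSpec,
    density_peak,
    make_terminus_report,
    sliding_window_profile,
)

# ---------------------------------------------------------------------------
# file I/O


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTA wrapped at 80 columns."""
    seqrecords = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(seqrecords)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (name, sequence) pairs; an empty file yields []."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_reads_fasta(reads: Sequence[ReadRecord], path: str | Path) -> None:
    """Reads as FASTA named ``<clone>/1`` (left) and ``<clone>/2`` (right)."""
    records = []
    for r in reads:
        if r.sequence is None:
            raise ValueError(f"read {r.read_id} has no sequence; cannot write FASTA")
        records.append((r.read_id, r.sequence))
    write_fasta(records, path)


def read_reads_fasta(path: str | Path) -> list[ReadRecord]:
    """Reads from FASTA; mate side parsed from the ``/1`` / ``/2`` suffix."""
    reads = []
    for name, seq in read_fasta(path):
        if "/" not in name:
            raise ValueError(f"read name {name!r} lacks a /1 or /2 mate suffix")
        clone_id, mate_no = name.rsplit("/", 1)
        if mate_no not in ("1", "2"):
            raise ValueError(f"read name {name!r} has mate suffix {mate_no!r}")
        reads.append(ReadRecord(clone_id, "left" if mate_no == "1" else "right", seq))
    return reads


def write_truth_tsv(reads: Sequence[ReadRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "clone_id": [r.clone_id for r in reads],
            "mate": [r.mate for r in reads],
            "truth_start": [r.truth_start for r in reads],
            "truth_end": [r.truth_end for r in reads],
            "truth_strand": [r.truth_strand for r in reads],
            "truth_chimera": [r.truth_chimera or "" for r in reads],
        }
    ).to_csv(path, sep="\t", index=False)


def write_breaks_bed(
    breaks: BreakSet | np.ndarray | Sequence[int], chrom: str, path: str | Path
) -> None:
    """Each break as a 1 bp BED interval (chrom, b, b+1)."""
    coords = breaks.coordinates if isinstance(breaks, BreakSet) else np.asarray(breaks)
    with open(path, "w") as fh:
        for b in coords:
            fh.write(f"{chrom}\t{int(b)}\t{int(b) + 1}\n")


def read_breaks_bed(path: str | Path) -> tuple[str | None, np.ndarray]:
    """Break coordinates (BED start column) and the chrom name."""
    chrom = None
    coords = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end != start + 1:
                raise ValueError(f"{path}: line {lineno}: break intervals must be 1 bp")
            chrom = chrom or fields[0]
            coords.append(start)
    return chrom, np.sort(np.array(coords, dtype=np.int64))


def write_fragments_tsv(fragments: Sequence[Fragment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "parent": [f.parent for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "length": [f.length_bp for f in fragments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> list[Fragment]:
    df = pd.read_csv(path, sep="\t")
    return [
        Fragment(str(row.parent), int(row.start), int(row.end))
        for row in df.itertuples()
    ]


def write_mapped_tsv(mapped: Sequence[MappedRead], path: str | Path) -> None:
    pd.DataFrame(
        {
            "read_id": [m.read_id for m in mapped],
            "clone_id": [m.clone_id for m in mapped],
            "mate": [m.mate for m in mapped],
            "insert_start": [m.insert_start if m.insert_start is not None else -1 for m in mapped],
            "strand": [m.strand or "." for m in mapped],
            "status": [m.status for m in mapped],
        }
    ).to_csv(path, sep="\t", index=False)


def write_inserts_tsv(inserts: Sequence[CloneInsert], path: str | Path) -> None:
    pd.DataFrame(
        {
            "clone_id": [i.clone_id for i in inserts],
            "start": [i.start if i.start is not None else -1 for i in inserts],
            "end": [i.end if i.end is not None else -1 for i in inserts],
            "size": [i.size_bp if i.size_bp is not None else -1 for i in inserts],
            "status": [i.status for i in inserts],
        }
    ).to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: WindowProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def write_json(obj: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ArmConfig:
    """One experimental arm: topology, target shear mean and gel window."""

    name: str
    topology: str = "linear"
    target_mean_bp: int = 3800
    select_min_bp: int = 3800
    select_max_bp: int = 4200
    replicates: int = 50


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete, serializable description of a simulation experiment."""

    molecule_name: str = "cosmid"
    molecule_length_bp: int = 36000
    sd_frac: float = 0.125
    read_len_mean_bp: int = 400
    read_len_sd_bp: int = 30
    polylinker: str = DEFAULT_POLYLINKER
    chimera_rate: float = 0.0
    anchor_k: int = 24
    chimera_size_factor: float = 2.0
    window_bp: int = 1000
    step_bp: int = 100
    extent_bp: int = 10000
    seed: int = 0
    arms: tuple[ArmConfig, ...] = (
        ArmConfig("circular_3800", "circular", 3800, 3800, 4200, 50),
        ArmConfig("linear_3800", "linear", 3800, 3800, 4200, 50),
        ArmConfig("linear_1900", "linear", 1900, 1800, 2200, 50),
    )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["arms"] = [dataclasses.asdict(a) for a in self.arms]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        arms = tuple(ArmConfig(**a) for a in d.pop("arms", []))
        if not arms:
            arms = cls.__dataclass_fields__["arms"].default
        return cls(arms=arms, **d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# experiment runner


@dataclass
class ArmResult:
    """Everything measured for one arm, JSON-serializable via ``to_dict``."""

    name: str
    topology: str
    critical_length_bp: int
    n_replicates: int
    n_clones: int
    n_valid_inserts: int
    discard_counts: dict[str, int]
    insert_size_mean_bp: float | None
    insert_size_sd_bp: float | None
    mean_fragment_bp: float
    recovered_breaks: np.ndarray
    profiles: dict[str, WindowProfile]
    terminus_reports: list[TerminusReport]

    def to_dict(self) -> dict[str, Any]:
        def _num(x: float | None) -> float | None:
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return None
            return round(float(x), 6)

        reports = []
        for tr in self.terminus_reports:
            reports.append(
                {
                    "terminus": tr.terminus,
                    "nearest_break_bp": (
                        None if math.isinf(tr.nearest_break_bp) else tr.nearest_break_bp
                    ),
                    "breaks_within_1kb": tr.breaks_within_1kb,
                    "breaks_within_2kb": tr.breaks_within_2kb,
                    "mean_breaks_per_2kb_window_interior": _num(
                        tr.mean_breaks_per_2kb_window_interior
                    ),
                    "observed_terminal_reads": tr.observed_terminal_reads,
                    "expected_terminal_reads": _num(tr.expected_terminal_reads),
                }
            )
        profiles = {
            key: {
                "window_start": prof.window_start.tolist(),
                "edge_distance": prof.edge_distance.tolist(),
                "count": prof.count.tolist(),
            }
            for key, prof in self.profiles.items()
        }
        return {
            "name": self.name,
            "topology": self.topology,
            "critical_length_bp": self.critical_length_bp,
            "n_replicates": self.n_replicates,
            "n_clones": self.n_clones,
            "n_valid_inserts": self.n_valid_inserts,
            "discard_counts": dict(sorted(self.discard_counts.items())),
            "insert_size_mean_bp": _num(self.insert_size_mean_bp),
            "insert_size_sd_bp": _num(self.insert_size_sd_bp),
            "mean_fragment_bp": _num(self.mean_fragment_bp),
            "n_recovered_breaks": int(self.recovered_breaks.size),
            "profiles": profiles,
            "terminus_reports": reports,
        }


@dataclass
class ExperimentReport:
    """Per-arm results plus provenance (config digest, seed, version)."""

    config_digest: str
    seed: int
    version: str
    arms: dict[str, ArmResult]

    def to_dict(self) -> dict[str, Any]:
        return {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "version": self.version,
            "arms": {name: arm.to_dict() for name, arm in self.arms.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _rotate(seq: str, offset: int) -> str:
    return seq[offset:] + seq[:offset]


def run_arm(
    arm: ArmConfig,
    config: ExperimentConfig,
    reference: MoleculeSpec,
    arm_index: int,
) -> ArmResult:
    """Shear -> size-select -> end reads -> map -> validate -> profile, one arm."""
    L = config.molecule_length_bp
    base = ShearParams(sd_frac=config.sd_frac, critical_length_bp=2)
    crit = calibrate_critical_length(
        arm.target_mean_bp, L, base, replicate_rng(config.seed, arm_index, 0)
    )
    shear_params = ShearParams(sd_frac=config.sd_frac, critical_length_bp=crit)
    lib_params = LibraryParams(
        select_min_bp=arm.select_min_bp,
        select_max_bp=arm.select_max_bp,
        read_len_mean_bp=config.read_len_mean_bp,
        read_len_sd_bp=config.read_len_sd_bp,
        polylinker=config.polylinker,
        chimera_rate=config.chimera_rate,
    )
    map_params = MapperParams(
        anchor_k=config.anchor_k,
        polylinker=config.polylinker,
        chimera_size_factor=config.chimera_size_factor,
    )
    molecule = MoleculeSpec(
        config.molecule_name, L, arm.topology, reference.sequence  # type: ignore[arg-type]
    )

    all_mapped: list[MappedRead] = []
    all_inserts: list[CloneInsert] = []
    frag_lengths: list[int] = []
    n_clones = 0
    for rep in range(arm.replicates):
        rng = replicate_rng(config.seed, arm_index, rep + 1)
        if arm.topology == "linear":
            _, frags = shear_linear(molecule, shear_params, rng)
            gen_parent = molecule
        else:
            _, frags, offset = shear_circular_with_offset(molecule, shear_params, rng)
            gen_parent = MoleculeSpec(
                molecule.name, L, "linear", _rotate(molecule.sequence, offset)
            )
        frag_lengths.extend(f.length_bp for f in frags)
        selected = size_select(frags, lib_params)
        reads = generate_end_reads(
            selected, gen_parent, lib_params, rng, id_prefix=f"{arm.name}.r{rep:04d}.c"
        )
        if config.chimera_rate > 0:
            reads = inject_chimeras(
                reads, config.chimera_rate, rng, polylinker_len=len(config.polylinker)
            )
        n_clones += len(reads) // 2
        mapped = [locate_insert_start(r, molecule, map_params) for r in reads]
        all_mapped.extend(mapped)
        all_inserts.extend(validate_clones(mapped, map_params))

    valid = [i for i in all_inserts if i.status == "valid"]
    breakset = breaks_from_inserts(valid, molecule)
    discard = {
        s: sum(1 for m in all_mapped if m.status == s)
        for s in ("no_polylinker", "ambiguous", "unmapped")
    }
    for s in ("chimera_orientation", "chimera_size", "incomplete"):
        discard[s] = sum(1 for i in all_inserts if i.status == s)
    try:
        ins_mean, ins_sd, _ = insert_size_stats(all_inserts)
    except InsufficientDataError:
        ins_mean = ins_sd = None

    spec = WindowSpec(config.window_bp, config.step_bp, "terminal")
    profiles: dict[str, WindowProfile] = {}
    reports: list[TerminusReport] = []
    if arm.topology == "linear":
        profiles["terminus_left"] = sliding_window_profile(
            breakset, 0, spec, config.extent_bp, direction=1
        )
        profiles["terminus_right"] = sliding_window_profile(
            breakset, L, spec, config.extent_bp, direction=-1
        )
        starts = np.array(
            [m.insert_start for m in all_mapped if m.status == "mapped"], dtype=np.int64
        )
        total_mapped = int(starts.size)
        for terminus in (0, L):
            reports.append(
                make_terminus_report(
                    breakset,
                    terminus,
                    L,
                    read_starts=starts,
                    total_reads=total_mapped,
                    terminal_region_bp=arm.target_mean_bp,
                )
            )
    else:
        span = WindowSpec(config.window_bp, config.step_bp, "spanning")
        profiles["full_circle"] = sliding_window_profile(
            breakset, L // 2, span, L // 2
        )
        # a circle has no termini, hence no terminus reports

    return ArmResult(
        name=arm.name,
        topology=arm.topology,
        critical_length_bp=crit,
        n_replicates=arm.replicates,
        n_clones=n_clones,
        n_valid_inserts=len(valid),
        discard_counts=discard,
        insert_size_mean_bp=ins_mean,
        insert_size_sd_bp=ins_sd,
        mean_fragment_bp=float(np.mean(frag_lengths)) if frag_lengths else math.nan,
        recovered_breaks=breakset.coordinates,
        profiles=profiles,
        terminus_reports=reports,
    )


def run_experiment(
    config: ExperimentConfig, output_dir: str | Path | None = None
) -> ExperimentReport:
    """Run every arm of the configured experiment; deterministic given the seed.

    When ``output_dir`` is given, writes the reference FASTA, per-arm break
    BEDs and profile TSVs, and ``report.json``.
    """
    ref_rng = replicate_rng(config.seed, 0)
    sequence = random_sequence(config.molecule_length_bp, ref_rng)
    reference = MoleculeSpec(
        config.molecule_name, config.molecule_length_bp, "linear", sequence
    )
    arms: dict[str, ArmResult] = {}
    for ai, arm in enumerate(config.arms, start=1):
        arms[arm.name] = run_arm(arm, config, reference, ai)
    report = ExperimentReport(
        config_digest=config.digest(),
        seed=config.seed,
        version=__version__,
        arms=arms,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([(config.molecule_name, sequence)], out / "reference.fasta")
        for name, arm_res in arms.items():
            write_breaks_bed(
                arm_res.recovered_breaks, config.molecule_name, out / f"{name}.breaks.bed"
            )
            for key, prof in arm_res.profiles.items():
                write_profile_tsv(prof, out / f"{name}.{key}.profile.tsv")
        with open(out / "report.json", "w") as fh:
            fh.write(report.to_json())
            fh.write("\n")
    return report


def markdown_summary(report: ExperimentReport) -> str:
    """Human-readable per-arm summary of an experiment report."""
    lines = [
        f"# Shearing experiment report (seed {report.seed}, config {report.config_digest})",
        "",
    ]
    for name, arm in report.arms.items():
        lines.append(f"## Arm `{name}` ({arm.topology})")
        lines.append("")
        lines.append(f"- critical length: {arm.critical_length_bp} bp")
        lines.append(f"- mean fragment: {arm.mean_fragment_bp:.0f} bp")
        lines.append(f"- clones: {arm.n_clones}, valid inserts: {arm.n_valid_inserts}")
        if arm.insert_size_mean_bp is not None:
            lines.append(
                f"- insert size: {arm.insert_size_mean_bp:.0f} "
                f"+/- {arm.insert_size_sd_bp:.0f} bp"
            )
        for tr in arm.terminus_reports:
            nearest = (
                "none" if math.isinf(tr.nearest_break_bp) else f"{tr.nearest_break_bp:.0f} bp"
            )
            lines.append(
                f"- terminus {tr.terminus}: nearest break {nearest}, "
                f"{tr.breaks_within_1kb} breaks within 1 kb, "
                f"{tr.breaks_within_2kb} within 2 kb"
            )
        for key, prof in arm.profiles.items():
            peak = density_peak(prof)
            if peak is not None and not math.isnan(peak.plateau_mean):
                lines.append(
                    f"- {key}: peak {peak.peak_count} breaks at edge distance "
                    f"{peak.peak_edge_distance} bp (plateau {peak.plateau_mean:.1f})"
                )
        lines.append("")
    return "\n".join(lines)
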