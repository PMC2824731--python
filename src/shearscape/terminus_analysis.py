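"""Break-density statistics near DNA termini.

Sliding-window break profiles, nearest-break and within-distance terminus
statistics, observed-vs-expected terminal read counts, break-density peak and
oscillation detection, and fragment-size-distribution transforms
(mass-weighted fluorescence intensity vs number-weighted molecule counts).

A *spanning* profile slides a window across a region centred on an anchor
(used for an intact circular control, where breaks should be uniform).  A
*terminal* profile starts with the window's trailing edge at a terminus and
slides inward, which is the natural frame for quantifying the shear-resistant
zone: near-zero counts at the end, a rise to a distinct peak at roughly the
mean fragment size, a Gibbs-like undershoot beyond it, then an interior
plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .break_mapping import MappedRead
from .errors import InsufficientDataError
from .shearing import BreakSet, Fragment


def _coords(breaks: BreakSet | np.ndarray | Sequence[int]) -> np.ndarray:
    if isinstance(breaks, BreakSet):
        return breaks.coordinates
    return np.sort(np.asarray(breaks, dtype=np.int64))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: window width, step and mode."""

    window_bp: int = 1000
    step_bp: int = 100
    mode: str = "spanning"  # spanning | terminal

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window_bp and step_bp must be positive")
        if self.step_bp > self.window_bp:
            raise ValueError(
                f"step_bp ({self.step_bp}) must not exceed window_bp ({self.window_bp})"
            )
        if self.mode not in ("spanning", "terminal"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class WindowProfile:
    """Break counts per window, ordered by window start.

    ``edge_distance`` is the distance from the window edge nearest the anchor
    to the anchor (signed in spanning mode, negative upstream; nonnegative in
    terminal mode).  ``window_mid`` is the midpoint coordinate; both x-axis
    conventions are carried because peaks are naturally described by midpoint
    while terminal tracks are plotted against nearest-edge distance.
    """

    spec: WindowSpec
    window_start: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    window_mid: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    edge_distance: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    count: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __len__(self) -> int:
        return int(self.window_start.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.window_start,
                "window_mid": self.window_mid,
                "edge_distance": self.edge_distance,
                "count": self.count,
            }
        )


@dataclass(frozen=True)
class PeakSummary:
    """Break-density peak and interior plateau of a window profile."""

    peak_start: int
    peak_mid: float
    peak_count: int
    peak_edge_distance: int
    plateau_mean: float


@dataclass(frozen=True)
class OscillationSummary:
    """Gibbs-like overshoot/undershoot relative to the interior plateau."""

    peak: PeakSummary
    undershoot_min: float
    has_overshoot: bool
    has_undershoot: bool


@dataclass(frozen=True)
class Overrepresentation:
    """Observed vs uniform-expected read count in a region."""

    observed: int
    expected: float
    ratio: float | None


@dataclass(frozen=True)
class TerminusReport:
    """Per-terminus break statistics."""

    terminus: int
    nearest_break_bp: float  # inf when no breaks
    breaks_within_1kb: int
    breaks_within_2kb: int
    mean_breaks_per_2kb_window_interior: float
    observed_terminal_reads: int | None = None
    expected_terminal_reads: float | None = None


@dataclass
class SizeDistribution:
    """Fragment-size abundance, mass- or number-weighted.

    ``kind='curve'`` marks a densitometric trace sampled along a length axis
    (integrated by trapezoid); ``kind='discrete'`` marks an exact fragment
    table (summed directly).
    """

    bins: np.ndarray
    values: np.ndarray
    weighting: str = "number"  # mass | number
    kind: str = "discrete"  # discrete | curve

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bins.shape != self.values.shape:
            raise ValueError("bins and values must have the same shape")
        if self.weighting not in ("mass", "number"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.kind not in ("discrete", "curve"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if np.any(self.values < 0):
            raise ValueError("values must be nonnegative")
        if self.values.size and self.values.sum() <= 0:
            raise ValueError("nonempty distribution must have positive total")
        order = np.argsort(self.bins)
        self.bins = self.bins[order]
        self.values = self.values[order]


def sliding_window_profile(
    breaks: BreakSet | np.ndarray | Sequence[int],
    anchor: int,
    spec: WindowSpec,
    extent_bp: int,
    direction: int = 1,
) -> WindowProfile:
    """Count breaks in windows slid across (spanning) or away from (terminal) an anchor.

    Spanning mode covers ``[anchor - extent, anchor + extent]``; terminal mode
    starts with the trailing edge at the anchor (a terminus) and slides in
    ``direction`` (+1 rightward, -1 leftward) until the leading edge reaches
    ``extent_bp`` from the anchor.  Each row counts breaks ``b`` with
    ``window_start <= b < window_start + window_bp``; breaks outside the
    profiled region are simply not counted.
    """
    if extent_bp < spec.window_bp:
        raise ValueError(
            f"extent_bp ({extent_bp}) must be >= window_bp ({spec.window_bp})"
        )
    coords = _coords(breaks)
    w, step = spec.window_bp, spec.step_bp
    n = (extent_bp - w) // step + 1
    offsets = step * np.arange(n, dtype=np.int64)
    if spec.mode == "spanning":
        n_span = (2 * extent_bp - w) // step + 1
        starts = anchor - extent_bp + step * np.arange(n_span, dtype=np.int64)
        left_edge = starts
        right_edge = starts + w
        edge = np.where(
            right_edge <= anchor,
            -(anchor - right_edge),
            np.where(left_edge >= anchor, left_edge - anchor, 0),
        )
    else:
        if direction >= 0:
            starts = anchor + offsets
        else:
            starts = np.sort(anchor - w - offsets)
        edge = np.minimum(np.abs(starts - anchor), np.abs(starts + w - anchor))
    counts = np.searchsorted(coords, starts + w, side="left") - np.searchsorted(
        coords, starts, side="left"
    )
    return WindowProfile(
        spec,
        starts,
        starts + w / 2.0,
        edge.astype(np.int64),
        counts.astype(np.int64),
    )


def nearest_break_distance(
    breaks: BreakSet | np.ndarray | Sequence[int], terminus: int
) -> float:
    """Distance from the terminus to the nearest break; ``inf`` when none."""
    coords = _coords(breaks)
    if coords.size == 0:
        return math.inf
    return float(np.min(np.abs(coords - terminus)))


def breaks_within(
    breaks: BreakSet | np.ndarray | Sequence[int], terminus: int, d_bp: int
) -> int:
    """Number of breaks with ``|b - terminus| <= d_bp``."""
    if d_bp <= 0:
        raise ValueError(f"d_bp must be positive, got {d_bp}")
    coords = _coords(breaks)
    return int(np.count_nonzero(np.abs(coords - terminus) <= d_bp))


def expected_reads_uniform(
    total_reads: float, region_bp: float, reference_bp: float
) -> float:
    """Expected reads in a region under uniform breakage: ``N * region / reference``."""
    if total_reads < 0 or region_bp <= 0 or reference_bp <= 0:
        raise ValueError("total_reads, region_bp and reference_bp must be positive")
    if region_bp > reference_bp:
        raise ValueError(
            f"region ({region_bp} bp) exceeds reference ({reference_bp} bp)"
        )
    return total_reads * region_bp / reference_bp


def overrepresentation_report(
    reads: Sequence[MappedRead] | np.ndarray | Sequence[int],
    region: tuple[int, int],
    total_reads: int,
    reference_bp: int,
) -> Overrepresentation:
    """Observed vs expected reads whose insert start lies in ``[region0, region1)``."""
    lo, hi = region
    if not 0 <= lo < hi <= reference_bp:
        raise ValueError(f"region {region} not within reference of {reference_bp} bp")
    if len(reads) > 0 and isinstance(reads[0], MappedRead):
        starts = np.array(
            [r.insert_start for r in reads if r.status == "mapped"], dtype=np.int64
        )
    else:
        starts = np.asarray(reads, dtype=np.int64)
    observed = int(np.count_nonzero((starts >= lo) & (starts < hi)))
    if total_reads == 0:
        return Overrepresentation(observed, 0.0, None)
    expected = expected_reads_uniform(total_reads, hi - lo, reference_bp)
    ratio = observed / expected if expected > 0 else None
    return Overrepresentation(observed, expected, ratio)


def density_peak(profile: WindowProfile) -> PeakSummary | None:
    """Maximal-count window (ties -> smallest window start) and interior plateau.

    The plateau is the mean count over rows whose nearest edge lies beyond
    twice the peak's edge distance from the anchor (NaN when no such rows).
    Returns ``None`` for an all-zero profile (no peak).
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    counts = profile.count
    if not np.any(counts > 0):
        return None
    idx = int(np.argmax(counts))  # argmax returns the first maximum; rows are start-ordered
    peak_dist = int(abs(profile.edge_distance[idx]))
    beyond = np.abs(profile.edge_distance) > 2 * peak_dist
    plateau = float(np.mean(counts[beyond])) if np.any(beyond) else math.nan
    return PeakSummary(
        peak_start=int(profile.window_start[idx]),
        peak_mid=float(profile.window_mid[idx]),
        peak_count=int(counts[idx]),
        peak_edge_distance=peak_dist,
        plateau_mean=plateau,
    )


def oscillation_summary(profile: WindowProfile) -> OscillationSummary | None:
    """Detect the Gibbs-like overshoot/undershoot pattern of a terminal track.

    The peak must exceed the interior plateau (overshoot) and some window
    whose nearest edge lies between the peak distance and twice the peak
    distance must fall below the plateau (undershoot).
    """
    peak = density_peak(profile)
    if peak is None or math.isnan(peak.plateau_mean):
        return None
    dist = np.abs(profile.edge_distance)
    band = (dist > peak.peak_edge_distance) & (dist <= 2 * peak.peak_edge_distance)
    if not np.any(band):
        return None
    undershoot_min = float(np.min(profile.count[band]))
    return OscillationSummary(
        peak=peak,
        undershoot_min=undershoot_min,
        has_overshoot=peak.peak_count > peak.plateau_mean,
        has_undershoot=undershoot_min < peak.plateau_mean,
    )


def make_terminus_report(
    breaks: BreakSet | np.ndarray | Sequence[int],
    terminus: int,
    molecule_length_bp: int,
    *,
    interior_window_bp: int = 2000,
    exclusion_bp: int = 4000,
    read_starts: Sequence[int] | np.ndarray | None = None,
    total_reads: int | None = None,
    terminal_region_bp: int | None = None,
) -> TerminusReport:
    """Assemble the per-terminus statistics table row.

    The interior mean is computed over non-overlapping ``interior_window_bp``
    windows excluding ``exclusion_bp`` at each molecule end ("interior" is not
    sharply defined in the field, so the exclusion zone is an explicit
    parameter).  When read starts and a terminal region length are supplied,
    observed and uniform-expected terminal read counts are included.
    """
    coords = _coords(breaks)
    nearest = nearest_break_distance(coords, terminus)
    w1 = breaks_within(coords, terminus, 1000)
    w2 = breaks_within(coords, terminus, 2000)
    lo, hi = exclusion_bp, molecule_length_bp - exclusion_bp
    starts = np.arange(lo, hi - interior_window_bp + 1, interior_window_bp)
    if starts.size:
        counts = np.searchsorted(coords, starts + interior_window_bp, side="left") - (
            np.searchsorted(coords, starts, side="left")
        )
        interior_mean = float(np.mean(counts))
    else:
        interior_mean = math.nan
    observed = expected = None
    if read_starts is not None and total_reads is not None and terminal_region_bp:
        if terminus == 0:
            region = (0, terminal_region_bp)
        else:
            region = (terminus - terminal_region_bp, terminus)
        rep = overrepresentation_report(
            np.asarray(read_starts), region, total_reads, molecule_length_bp
        )
        observed, expected = rep.observed, rep.expected
    return TerminusReport(
        terminus=terminus,
        nearest_break_bp=nearest,
        breaks_within_1kb=w1,
        breaks_within_2kb=w2,
        mean_breaks_per_2kb_window_interior=interior_mean,
        observed_terminal_reads=observed,
        expected_terminal_reads=expected,
    )


def fragment_size_distribution(
    fragments: Sequence[Fragment] | Sequence[int] | np.ndarray,
    weighting: str = "number",
) -> SizeDistribution:
    """Discrete size distribution from a fragment table.

    Number weighting counts molecules per unique length; mass weighting
    multiplies each count by the length (fluorescence intensity is
    proportional to mass).
    """
    if len(fragments) and isinstance(fragments[0], Fragment):
        lengths = np.array([f.length_bp for f in fragments], dtype=np.int64)
    else:
        lengths = np.asarray(fragments, dtype=np.int64)
    bins, counts = np.unique(lengths, return_counts=True)
    values = counts.astype(float)
    if weighting == "mass":
        values = values * bins
    return SizeDistribution(bins.astype(float), values, weighting, "discrete")


def number_weighted(dist: SizeDistribution) -> SizeDistribution:
    """Mass -> number weighting: divide each value by its fragment length."""
    if dist.weighting != "mass":
        raise ValueError("number_weighted expects a mass-weighted distribution")
    if np.any(dist.bins <= 0):
        raise ValueError("all bin lengths must be positive")
    return SizeDistribution(dist.bins, dist.values / dist.bins, "number", dist.kind)


def mass_weighted(dist: SizeDistribution) -> SizeDistribution:
    """Number -> mass weighting: multiply each value by its fragment length."""
    if dist.weighting != "number":
        raise ValueError("mass_weighted expects a number-weighted distribution")
    if np.any(dist.bins <= 0):
        raise ValueError("all bin lengths must be positive")
    return SizeDistribution(dist.bins, dist.values * dist.bins, "mass", dist.kind)


def fraction_below(dist: SizeDistribution, cutoff_bp: float) -> float:
    """Fraction of the distribution's total lying below a length cutoff.

    Exact summation for discrete fragment tables; trapezoidal accumulation
    (with linear interpolation at the cutoff) for sampled curves.
    """
    if cutoff_bp <= 0:
        raise ValueError(f"cutoff_bp must be positive, got {cutoff_bp}")
    if dist.values.size == 0:
        raise InsufficientDataError("empty size distribution")
    if dist.kind == "discrete":
        return float(dist.values[dist.bins < cutoff_bp].sum() / dist.values.sum())
    bins, values = dist.bins, dist.values
    if cutoff_bp <= bins[0]:
        return 0.0
    if cutoff_bp >= bins[-1]:
        return 1.0
    total = float(np.trapezoid(values, bins))
    v_cut = float(np.interp(cutoff_bp, bins, values))
    mask = bins < cutoff_bp
    xs = np.append(bins[mask], cutoff_bp)
    ys = np.append(values[mask], v_cut)
    return float(np.trapezoid(ys, xs) / total)


def required_break_distance(read_length_bp: int, min_overlap_bp: int) -> int:
    """Farthest break from a molecule end that still links the terminal read.

    An inward-reading terminal read of ``read_length_bp`` overlaps an
    outward-reading subterminal read by at least ``min_overlap_bp`` only if a
    break falls within ``read_length_bp - min_overlap_bp`` of the end.
    """
    if min_overlap_bp < 0:
        raise ValueError("min_overlap_bp must be nonnegative")
    if min_overlap_bp >= read_length_bp:
        raise ValueError("min_overlap_bp must be smaller than read_length_bp")
    return read_length_bp - min_overlap_bp
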