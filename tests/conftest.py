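"""Shared fixtures: calibrated shear parameters and pooled simulation runs.

Expensive Monte-Carlo pools are session-scoped so the density, resistance
and overrepresentation tests share one simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shearscape as ss

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")

MOLECULE_BP = 36000


@pytest.fixture(scope="session")
def crit_3800() -> int:
    """Critical length calibrated to a ~3.8 kb mean on a 36 kb molecule."""
    params = ss.ShearParams(sd_frac=0.125, critical_length_bp=2)
    rng = np.random.default_rng(2024)
    return ss.calibrate_critical_length(3800, MOLECULE_BP, params, rng)


@pytest.fixture(scope="session")
def crit_1900() -> int:
    """Critical length calibrated to a ~1.9 kb mean on a 36 kb molecule."""
    params = ss.ShearParams(sd_frac=0.125, critical_length_bp=2)
    rng = np.random.default_rng(2025)
    return ss.calibrate_critical_length(1900, MOLECULE_BP, params, rng)


@dataclass
class LinearPool:
    """Pooled linear-shear output at the ~3.8 kb mean."""

    molecule: ss.MoleculeSpec
    params: ss.ShearParams
    breaks: np.ndarray  # pooled over replicates, sorted
    fragment_lengths: np.ndarray
    replicates: int


@pytest.fixture(scope="session")
def linear_pool_3800(crit_3800: int) -> LinearPool:
    """12,000 seeded shears of a 36 kb linear molecule (~1e5 pooled breaks)."""
    molecule = ss.MoleculeSpec("cosmid", MOLECULE_BP, "linear")
    params = ss.ShearParams(sd_frac=0.125, critical_length_bp=crit_3800)
    replicates = 12000
    breaks: list[np.ndarray] = []
    lengths: list[int] = []
    for bs, frags in ss.iter_replicates(molecule, params, replicates, 4242):
        breaks.append(bs.coordinates)
        lengths.extend(f.length_bp for f in frags)
    return LinearPool(
        molecule,
        params,
        np.sort(np.concatenate(breaks)),
        np.array(lengths, dtype=np.int64),
        replicates,
    )


@dataclass
class LibraryRun:
    """A sheared, size-selected, sequenced and mapped clone library."""

    molecule: ss.MoleculeSpec
    shear_params: ss.ShearParams
    lib_params: ss.LibraryParams
    map_params: ss.MapperParams
    selected: list[ss.Fragment]
    reads: list[ss.ReadRecord]
    mapped: list[ss.MappedRead]
    inserts: list[ss.CloneInsert]


@pytest.fixture(scope="session")
def library_run(crit_3800: int) -> LibraryRun:
    """Clean pipeline run (no chimeras) on a unique-sequence 36 kb molecule."""
    rng = np.random.default_rng(77)
    molecule = ss.random_molecule("cosmid", MOLECULE_BP, "linear", rng)
    shear_params = ss.ShearParams(sd_frac=0.125, critical_length_bp=crit_3800)
    lib_params = ss.LibraryParams(select_min_bp=3800, select_max_bp=4200)
    map_params = ss.MapperParams()
    selected: list[ss.Fragment] = []
    reads: list[ss.ReadRecord] = []
    for rep in range(800):
        r = ss.replicate_rng(555, rep)
        _, frags = ss.shear_linear(molecule, shear_params, r)
        sel = ss.size_select(frags, lib_params)
        selected.extend(sel)
        reads.extend(
            ss.generate_end_reads(sel, molecule, lib_params, r, id_prefix=f"r{rep:04d}c")
        )
    mapped = [ss.locate_insert_start(rd, molecule, map_params) for rd in reads]
    inserts = ss.validate_clones(mapped, map_params)
    return LibraryRun(
        molecule, shear_params, lib_params, map_params, selected, reads, mapped, inserts
    )
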