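"""Tests for breakpoint mapping, mate-pair validation and insert statistics."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

import shearscape as ss
from shearscape.break_mapping import estimate_mean_insert, pair_reads

PL = ss.DEFAULT_POLYLINKER


@pytest.fixture(scope="module")
def reference():
    return ss.random_molecule("ref", 5000, "linear", np.random.default_rng(11))


def _read(seq, clone="c0", mate="left"):
    return ss.ReadRecord(clone, mate, seq)


class TestLocateInsertStart:
    def test_forward_unique_hit(self, reference):
        read = _read(PL + reference.sequence[1234 : 1234 + 40])
        m = ss.locate_insert_start(read, reference, ss.MapperParams())
        assert (m.status, m.insert_start, m.strand) == ("mapped", 1234, "+")

    def test_reverse_hit_reports_outer_boundary(self, reference):
        read = _read(PL + reverse_complement(reference.sequence[800:1200]))
        m = ss.locate_insert_start(read, reference, ss.MapperParams())
        assert (m.status, m.insert_start, m.strand) == ("mapped", 1200, "-")

    def test_repeated_anchor_is_ambiguous(self):
        core = ss.random_sequence(200, np.random.default_rng(4))
        seq = core + ss.random_sequence(400, np.random.default_rng(5)) + core
        ref = ss.MoleculeSpec("r", len(seq), "linear", seq)
        read = _read(PL + core[:60])
        m = ss.locate_insert_start(read, ref, ss.MapperParams())
        assert m.status == "ambiguous"
        assert m.insert_start is None

    def test_missing_polylinker(self, reference):
        read = _read("AAAATTTT" + reference.sequence[100:160])
        m = ss.locate_insert_start(read, reference, ss.MapperParams())
        assert m.status == "no_polylinker"

    def test_foreign_sequence_unmapped(self, reference):
        read = _read(PL + "ACGT" * 20)
        m = ss.locate_insert_start(read, reference, ss.MapperParams())
        # a random 24-mer almost surely absent from a 5 kb reference
        assert m.status in ("unmapped", "ambiguous")

    def test_reference_without_sequence_rejected(self):
        bare = ss.MoleculeSpec("r", 1000, "linear")
        with pytest.raises(ss.ConfigurationError):
            ss.locate_insert_start(_read(PL + "A" * 30), bare, ss.MapperParams())

    def test_circular_reference_maps_across_origin(self):
        seq = ss.random_sequence(3000, np.random.default_rng(12))
        ref = ss.MoleculeSpec("r", 3000, "circular", seq)
        spanning = seq[2990:] + seq[:30]  # crosses the origin
        m = ss.locate_insert_start(_read(PL + spanning), ref, ss.MapperParams())
        assert (m.status, m.insert_start, m.strand) == ("mapped", 2990, "+")

    def test_matches_brute_force_scan(self, reference):
        """Mapping equals an independent exhaustive scan of every offset/strand."""
        params = ss.MapperParams()
        rng = np.random.default_rng(13)
        seq, L, k = reference.sequence, reference.length_bp, params.anchor_k
        for _ in range(150):
            pos = int(rng.integers(0, L - 100))
            if rng.random() < 0.5:
                read = _read(PL + seq[pos : pos + 80])
            else:
                read = _read(PL + reverse_complement(seq[pos : pos + 80]))
            m = ss.locate_insert_start(read, reference, params)
            anchor = read.sequence[len(PL) : len(PL) + k]
            hits = []
            for i in range(L - k + 1):
                if seq[i : i + k] == anchor:
                    hits.append((i, "+"))
                if seq[i : i + k] == reverse_complement(anchor):
                    hits.append((i + k, "-"))
            if len(hits) == 1:
                assert (m.status, m.insert_start, m.strand) == ("mapped", hits[0][0], hits[0][1])
            elif hits:
                assert m.status == "ambiguous"
            else:
                assert m.status == "unmapped"


def _mapped(clone, mate, pos, strand, status="mapped"):
    return ss.MappedRead(f"{clone}/{1 if mate == 'left' else 2}", clone, mate, pos, strand, status)


class TestValidateClonePair:
    def test_valid_pair(self):
        ins = ss.validate_clone_pair(
            _mapped("c", "left", 100, "+"), _mapped("c", "right", 4100, "-"), 4000, ss.MapperParams()
        )
        assert (ins.status, ins.start, ins.end, ins.size_bp) == ("valid", 100, 4100, 4000)

    def test_same_strand_is_orientation_chimera(self):
        ins = ss.validate_clone_pair(
            _mapped("c", "left", 100, "+"), _mapped("c", "right", 4100, "+"), 4000, ss.MapperParams()
        )
        assert ins.status == "chimera_orientation"

    def test_just_over_twice_mean_is_size_chimera(self):
        ins = ss.validate_clone_pair(
            _mapped("c", "left", 0, "+"), _mapped("c", "right", 8001, "-"), 4000, ss.MapperParams()
        )
        assert ins.status == "chimera_size"

    def test_exactly_twice_mean_is_valid(self):
        ins = ss.validate_clone_pair(
            _mapped("c", "left", 0, "+"), _mapped("c", "right", 8000, "-"), 4000, ss.MapperParams()
        )
        assert ins.status == "valid"

    def test_unmapped_mate_is_incomplete(self):
        ins = ss.validate_clone_pair(
            _mapped("c", "left", 100, "+"),
            _mapped("c", "right", None, None, "unmapped"),
            4000,
            ss.MapperParams(),
        )
        assert ins.status == "incomplete"

    def test_outward_facing_pair_is_orientation_chimera(self):
        ins = ss.validate_clone_pair(
            _mapped("c", "left", 4100, "+"), _mapped("c", "right", 100, "-"), 4000, ss.MapperParams()
        )
        assert ins.status == "chimera_orientation"


class TestBreaksAndStats:
    def test_single_insert_yields_both_boundaries(self):
        ins = [ss.CloneInsert("c", 100, 4100, "valid")]
        bs = ss.breaks_from_inserts(ins)
        assert bs.coordinates.tolist() == [100, 4100]

    def test_empty_input_yields_empty_breakset(self):
        assert len(ss.breaks_from_inserts([])) == 0

    def test_duplicates_retained(self):
        ins = [ss.CloneInsert("a", 100, 4100, "valid"), ss.CloneInsert("b", 100, 4200, "valid")]
        assert ss.breaks_from_inserts(ins).coordinates.tolist() == [100, 100, 4100, 4200]

    @pytest.mark.parametrize(
        "sizes,mean,sd",
        [([4000, 4000], 4000.0, 0.0), ([3000, 5000], 4000.0, 1414.2135623730951)],
    )
    def test_insert_size_stats_closed_form(self, sizes, mean, sd):
        ins = [ss.CloneInsert(f"c{i}", 0, s, "valid") for i, s in enumerate(sizes)]
        m, s, n = ss.insert_size_stats(ins)
        assert (m, n) == (mean, len(sizes))
        assert s == pytest.approx(sd)

    def test_fewer_than_two_inserts_rejected(self):
        with pytest.raises(ss.InsufficientDataError):
            ss.insert_size_stats([ss.CloneInsert("c", 0, 4000, "valid")])


class TestPipelineRoundTrip:
    def test_break_multiset_equals_fragment_boundaries(self, library_run):
        """With no chimeras, recovered breaks = size-selected fragment boundaries."""
        valid = [i for i in library_run.inserts if i.status == "valid"]
        assert len(valid) == len(library_run.selected)
        recovered = ss.breaks_from_inserts(valid).coordinates
        truth = ss.fragment_boundaries(library_run.selected)
        assert recovered.tolist() == truth.tolist()

    def test_insert_mean_inside_selection_window(self, library_run):
        mean, _, n = ss.insert_size_stats(library_run.inserts)
        assert n == len(library_run.selected)
        assert 3800 <= mean <= 4200

    def test_two_pass_mean_is_fixed_point_on_clean_data(self, library_run):
        first = estimate_mean_insert(library_run.mapped)
        inserts = ss.validate_clones(library_run.mapped, library_run.map_params, first)
        sizes = [i.size_bp for i in inserts if i.status == "valid"]
        assert float(np.mean(sizes)) == pytest.approx(first)

    def test_mapping_is_deterministic(self, library_run):
        again = [
            ss.locate_insert_start(r, library_run.molecule, library_run.map_params)
            for r in library_run.reads[:200]
        ]
        assert again == library_run.mapped[:200]


@pytest.fixture(scope="module")
def chimeric_run(library_run):
    """Reinject chimeras at rate 0.1 into the clean library and re-map."""
    reads = ss.inject_chimeras(
        library_run.reads, 0.1, np.random.default_rng(909),
        polylinker_len=len(library_run.lib_params.polylinker),
    )
    mapped = [
        ss.locate_insert_start(r, library_run.molecule, library_run.map_params)
        for r in reads
    ]
    inserts = ss.validate_clones(mapped, library_run.map_params)
    truth = {}
    for r in reads:
        truth.setdefault(r.clone_id, r.truth_chimera)
        if r.truth_chimera is not None:
            truth[r.clone_id] = r.truth_chimera
    return mapped, {i.clone_id: i for i in inserts}, truth


class TestChimeraFilter:
    def test_orientation_chimeras_all_flagged(self, chimeric_run):
        mapped, inserts, truth = chimeric_run
        flagged = [cid for cid, kind in truth.items() if kind == "orientation"]
        assert flagged
        for cid in flagged:
            assert inserts[cid].status == "chimera_orientation"

    def test_size_chimeras_above_threshold_flagged(self, chimeric_run):
        mapped, inserts, truth = chimeric_run
        mean = estimate_mean_insert(mapped)
        pairs = pair_reads(mapped)
        n_checked = 0
        for cid, kind in truth.items():
            if kind != "size":
                continue
            left, right = pairs[cid]["left"], pairs[cid]["right"]
            implied = right.insert_start - left.insert_start
            if implied > 2.0 * mean:
                assert inserts[cid].status == "chimera_size"
                n_checked += 1
        assert n_checked > 0

    def test_clean_clones_stay_valid(self, chimeric_run):
        _, inserts, truth = chimeric_run
        clean = [cid for cid, kind in truth.items() if kind is None]
        assert clean
        for cid in clean:
            assert inserts[cid].status == "valid"
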