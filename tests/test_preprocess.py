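"""ITS trimming, 5.8S excision, intron localization, primer tools."""

import numpy as np
import pytest

from mycobarcode import preprocess as pp
from mycobarcode.io import SequenceRecord

from conftest import random_dna, record


class TestTrimIts:
    def test_keeps_first_start_to_last_end_motif(self):
        rec = record("r", "GGATCATTAAAAAGACCTCAAA")
        assert pp.trim_its(rec).residues == "CATTAAAAAGACCT"

    def test_last_end_motif_wins(self):
        rec = record("r", "CATTAAGACCTTGACCT")
        assert pp.trim_its(rec).residues == "CATTAAGACCTTGACCT"

    def test_distinct_errors(self):
        with pytest.raises(pp.StartMotifAbsentError):
            pp.trim_its(record("r", "GGGGGGACCT"))
        with pytest.raises(pp.EndMotifAbsentError):
            pp.trim_its(record("r", "GGCATTAGGG"))
        with pytest.raises(pp.MotifOrderError):
            pp.trim_its(record("r", "GACCTGGGGGGGGCATTA"))

    def test_idempotent(self, rng):
        for _ in range(20):
            inner = random_dna(rng, int(rng.integers(30, 120)))
            rec = record("r", random_dna(rng, 10) + "CATTA" + inner + "GACCT" + random_dna(rng, 10))
            once = pp.trim_its(rec)
            assert pp.trim_its(once).residues == once.residues


class TestExcise58s:
    def test_concatenates_its1_and_its2(self, rng):
        seq = random_dna(rng, 300)
        out = pp.excise_58s(record("r", seq), its1_end=100, its2_start=221)
        assert out.residues == seq[:100] + seq[220:]
        assert len(out) == 180

    @pytest.mark.parametrize("its1_end,its2_start", [(0, 100), (100, 100), (100, 301), (150, 120)])
    def test_invalid_coordinates_rejected(self, rng, its1_end, its2_start):
        rec = record("r", random_dna(rng, 300))
        with pytest.raises(pp.PreprocessError):
            pp.excise_58s(rec, its1_end, its2_start)

    def test_length_arithmetic(self, rng):
        for _ in range(20):
            L = int(rng.integers(50, 400))
            e1 = int(rng.integers(1, L - 1))
            s2 = int(rng.integers(e1 + 1, L + 1))
            out = pp.excise_58s(record("r", random_dna(rng, L)), e1, s2)
            assert len(out) == e1 + (L - s2 + 1)


def _insert(ref: str, pos: int, rng, length: int) -> str:
    """Insert `length` random bases after 1-based ref position `pos`, pinning the
    junction so the insertion point is unambiguous."""
    while True:
        block = random_dna(rng, length)
        left_ok = pos == 0 or block[-1] != ref[pos - 1]
        right_ok = pos == len(ref) or block[0] != ref[pos]
        if left_ok and right_ok:
            return ref[:pos] + block + ref[pos:]


class TestDetectIntrons:
    def test_identical_query_yields_no_calls(self, rng):
        ref = record("ref", random_dna(rng, 450))
        assert pp.detect_introns(ref, ref) == []

    def test_single_insertion_located_exactly(self, rng):
        ref_seq = random_dna(rng, 450)
        qry = record("q", _insert(ref_seq, 101, rng, 1500))
        calls = pp.detect_introns(qry, record("ref", ref_seq))
        assert [(c.position, c.length) for c in calls] == [(101, 1500)]

    def test_two_insertions(self, rng):
        ref_seq = random_dna(rng, 450)
        # insert at 160 first, then at 64 (upstream, coordinates unaffected)
        qry_seq = _insert(ref_seq, 160, rng, 300)
        qry_seq = _insert(qry_seq, 64, rng, 200)
        calls = pp.detect_introns(record("q", qry_seq), record("ref", ref_seq))
        assert [c.position for c in calls] == [64, 160]
        assert [c.length for c in calls] == [200, 300]

    def test_unalignable_query_rejected(self, rng):
        ref = record("ref", random_dna(rng, 200))
        qry = record("q", random_dna(rng, 200))
        with pytest.raises(pp.PreprocessError, match="unalignable"):
            pp.detect_introns(qry, ref, anchor_len=30)

    def test_round_trip_restores_reference(self, rng):
        ref_seq = random_dna(rng, 450)
        ref = record("ref", ref_seq)
        for _ in range(20):
            n_introns = int(rng.integers(1, 4))
            positions = sorted(rng.choice(np.arange(30, 420), size=n_introns, replace=False),
                               reverse=True)
            if min(abs(np.diff(positions)), default=100) < 15:
                continue
            qry_seq = ref_seq
            lengths = {}
            for pos in positions:  # downstream first: upstream coordinates stay valid
                length = int(rng.integers(100, 2000))
                qry_seq = _insert(qry_seq, int(pos), rng, length)
                lengths[int(pos)] = length
            calls = pp.detect_introns(record("q", qry_seq), ref)
            assert sorted(c.position for c in calls) == sorted(lengths)
            assert {c.position: c.length for c in calls} == lengths
            restored = pp.excise_introns(record("q", qry_seq), calls)
            assert restored.residues == ref_seq

    def test_overlapping_calls_rejected(self, rng):
        qry = record("q", random_dna(rng, 300))
        calls = [
            pp.IntronCall(query_id="q", position=10, length=50, query_start=20),
            pp.IntronCall(query_id="q", position=30, length=50, query_start=40),
        ]
        with pytest.raises(pp.PreprocessError, match="overlap"):
            pp.excise_introns(qry, calls)

    def test_no_calls_is_identity(self, rng):
        qry = record("q", random_dna(rng, 100))
        assert pp.excise_introns(qry, []) is qry


class TestPrimers:
    def test_degeneracy_of_exact_primer_is_one(self):
        primer = pp.Primer(name="p", sequence="ACGTACGTAC", direction="forward")
        assert pp.primer_degeneracy(primer) == 1

    @pytest.mark.parametrize("name,seq,expected", [
        ("5F", "TGRTTAAATTCHACHAAYGC", 36),       # R*H*H*Y = 2*3*3*2
        ("COXBOL1-F", "GACGGCATTTTCWGTTCTTATTAG", 2),
        ("2eR", "CYTCNGGRTGACCRAARAAYC", 128),     # Y*N*R*R*R*Y = 2*4*2*2*2*2
    ])
    def test_degeneracy_of_panel_primers(self, name, seq, expected):
        primer = pp.Primer(name=name, sequence=seq, direction="forward")
        assert pp.primer_degeneracy(primer) == expected

    def test_degeneracy_at_least_one(self):
        for primer in pp.load_primer_table():
            deg = pp.primer_degeneracy(primer)
            assert deg >= 1
            if all(ch in "ACGT" for ch in primer.sequence):
                assert deg == 1

    def test_packaged_panel_loads(self):
        primers = pp.load_primer_table()
        assert len(primers) == 17
        by_name = {p.name: p for p in primers}
        assert by_name["11F"].start_position == 70
        assert by_name["2eR"].direction == "reverse"

    def test_forward_hit(self):
        primer = pp.Primer(name="p", sequence="ACGTACGTAC", direction="forward")
        tpl = record("t", "TTACGTACGTACTT")
        assert pp.map_primer(primer, tpl) == [(3, "+", 0)]

    def test_reverse_hit_matches_reverse_complement(self):
        primer = pp.Primer(name="p", sequence="GTACGTACGT", direction="reverse")
        tpl = record("t", "TTACGTACGTACTT")
        # revcomp(GTACGTACGT) = ACGTACGTAC found at template position 3
        assert pp.map_primer(primer, tpl) == [(3, "-", 0)]

    def test_degenerate_symbols_match_their_class(self):
        primer = pp.Primer(name="p", sequence="ARGTARGTAR", direction="forward")
        hits_a = pp.map_primer(primer, record("t", "CCAAGTAAGTAACC"))
        hits_g = pp.map_primer(primer, record("t", "CCAGGTAGGTAGCC"))
        assert hits_a == [(3, "+", 0)] and hits_g == [(3, "+", 0)]

    def test_primer_longer_than_template_rejected(self):
        primer = pp.Primer(name="p", sequence="ACGTACGTACGT", direction="forward")
        with pytest.raises(pp.PreprocessError):
            pp.map_primer(primer, record("t", "ACGT"))

    def test_agrees_with_expansion_oracle(self, rng):
        """Every reported hit must be reachable by some exact expansion of the
        primer, and windows with no expansion match must not be reported."""
        from itertools import product

        for _ in range(10):
            tpl_seq = random_dna(rng, 80)
            core = random_dna(rng, 10)
            degenerate = core[:3] + "R" + core[4:7] + "Y" + core[8:]
            for direction in ("forward", "reverse"):
                primer = pp.Primer(name="p", sequence=degenerate, direction=direction)
                hits = {h[0] for h in pp.map_primer(primer, record("t", tpl_seq))}
                expansions = []
                for r, y in product("AG", "CT"):
                    exact = degenerate.replace("R", r).replace("Y", y)
                    if direction == "reverse":
                        exact = pp.reverse_complement(exact)
                    expansions.append(exact)
                oracle = {
                    start + 1
                    for start in range(len(tpl_seq) - 10 + 1)
                    for exact in expansions
                    if tpl_seq[start:start + 10] == exact
                }
                assert hits == oracle


class TestAmplicon:
    def test_arithmetic_includes_both_primers(self):
        assert pp.predict_amplicon(1, 91, 10) == 100

    def test_panel_coordinates(self):
        # forward start 70, reverse window start 724, reverse primer 21 nt
        assert pp.predict_amplicon(70, 724, 21) == 675

    def test_reverse_upstream_rejected(self):
        with pytest.raises(pp.PreprocessError):
            pp.predict_amplicon(100, 50, 20)
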