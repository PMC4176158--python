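"""Sequence primitives: complementation, site scanning, digestion, Tm, hairpins."""

import pytest
from hypothesis import given, settings, strategies as st

from gcweld.errors import NoCutSiteError, SequenceAlphabetError, TopologyError
from gcweld.seq_core import (
    CIRCULAR,
    ENZYMES,
    LINEAR,
    NucleotideSequence,
    blunt_digest,
    cut_linear,
    hairpin_screen,
    least_rotation_offset,
    nearest_neighbor_tm,
    reverse_complement,
    revcomp_str,
    scan_sites,
    wallace_tm,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestNucleotideSequence:
    def test_normalizes_case(self):
        assert NucleotideSequence("acgT").bases == "ACGT"

    @pytest.mark.parametrize("bad", ["", "ACGN", "ACGU", "AC-GT"])
    def test_rejects_bad_alphabet(self, bad):
        with pytest.raises(SequenceAlphabetError):
            NucleotideSequence(bad)

    def test_rejects_unknown_topology(self):
        with pytest.raises(TopologyError):
            NucleotideSequence("ACGT", "supercoiled")

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GACGTC", "GACGTC"),  # palindromic release site
            # the two orientations of the G5C5 core are mutual reverse complements
            ("GGGGGCCCCCGGGGG", "CCCCCGGGGGCCCCC"),
            ("GAT", "ATC"),
        ],
    )
    def test_reverse_complement_examples(self, seq, expected):
        assert reverse_complement(seq).bases == expected

    @given(dna)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_reverse_complement_is_involutive(self, bases):
        s = NucleotideSequence(bases)
        assert s.reverse_complement().reverse_complement() == s


def _scan_oracle_circular(bases: str, recognition: str) -> list[int]:
    """Brute force: union over all rotations of linear scans, mapped back."""
    n = len(bases)
    found = set()
    for r in range(n):
        rotated = bases[r:] + bases[:r]
        for i in range(n):
            if rotated[i : i + len(recognition)] == recognition:
                found.add((i + r) % n)
    return sorted(found)


class TestScanSites:
    def test_linear_single_site(self):
        assert scan_sites(NucleotideSequence("GATATC"), ENZYMES["EcoRV"]) == [0]

    def test_zrai_flank_is_invisible_to_ecorv(self):
        flank = NucleotideSequence("GACGTCGGGGGCCCCCGGGGGGATTCTAGA")
        assert scan_sites(flank, ENZYMES["EcoRV"]) == []
        assert scan_sites(flank, ENZYMES["ZraI"]) == [0]

    def test_origin_spanning_site(self):
        s = NucleotideSequence("ATCAAAAAAGAT", CIRCULAR)
        assert scan_sites(s, ENZYMES["EcoRV"]) == [9]

    @given(dna)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_circular_scan_matches_rotation_oracle(self, bases):
        s = NucleotideSequence(bases, CIRCULAR)
        for enzyme in (ENZYMES["EcoRV"], ENZYMES["ZraI"]):
            assert scan_sites(s, enzyme) == _scan_oracle_circular(
                bases, enzyme.recognition
            )


class TestBluntDigest:
    def test_requires_circular(self):
        with pytest.raises(TopologyError):
            blunt_digest(NucleotideSequence("GATATCGATATC"), ENZYMES["EcoRV"])

    def test_no_site_error_names_enzyme(self):
        with pytest.raises(NoCutSiteError, match="SwaI"):
            blunt_digest(NucleotideSequence("ACGT" * 10, CIRCULAR), ENZYMES["SwaI"])

    def test_single_site_yields_full_length_linear(self):
        s = NucleotideSequence("AAAGATATCAAA", CIRCULAR)
        frags = blunt_digest(s, ENZYMES["EcoRV"])
        assert len(frags) == 1
        assert len(frags[0].seq) == len(s)
        assert frags[0].seq.topology == LINEAR

    def test_two_sites_conserve_length(self):
        s = NucleotideSequence("GATATC" + "A" * 20 + "GATATC" + "C" * 30, CIRCULAR)
        frags = blunt_digest(s, ENZYMES["EcoRV"])
        assert len(frags) == 2
        assert sum(len(f.seq) for f in frags) == len(s)
        assert {f.left_enzyme for f in frags} == {"EcoRV"}

    def test_cut_position_splits_recognition_site(self):
        # EcoRV cuts GAT^ATC: each fragment starts with ATC and ends with GAT
        s = NucleotideSequence("GATATC" + "A" * 10 + "GATATC" + "C" * 10, CIRCULAR)
        for f in blunt_digest(s, ENZYMES["EcoRV"]):
            assert f.seq.bases.startswith("ATC")
            assert f.seq.bases.endswith("GAT")

    @given(st.text(alphabet="ACGT", min_size=10, max_size=60))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_conservation_and_reconstruction(self, filler):
        bases = "GATATC" + filler
        s = NucleotideSequence(bases, CIRCULAR)
        frags = blunt_digest(s, ENZYMES["EcoRV"])
        assert sum(len(f.seq) for f in frags) == len(s)
        rejoined = NucleotideSequence("".join(f.seq.bases for f in frags), CIRCULAR)
        # cut-order concatenation reproduces a rotation of the input
        assert rejoined.bases in (bases + bases)

    def test_cut_linear_trims_terminal_sites(self):
        amplicon = NucleotideSequence("GATATC" + "A" * 30 + "GATATC")
        pieces = cut_linear(amplicon, ENZYMES["EcoRV"])
        assert [len(p.seq) for p in pieces] == [3, 36, 3]
        central = pieces[1]
        assert central.left_enzyme == central.right_enzyme == "EcoRV"
        assert central.seq.bases.startswith("ATC")
        assert central.seq.bases.endswith("GAT")


class TestMeltingTemperature:
    @pytest.mark.parametrize(
        "seq,tm",
        [
            ("GACGTC", 20),
            ("GTCGGGGGCCCCCGGGGGGAT", 78),  # ZraI-released G5C5 21-mer
            ("TAGTCGGCCAATAACCCAGGGATTT", 74),  # printed cassette adaptor
        ],
    )
    def test_wallace_examples(self, seq, tm):
        assert wallace_tm(seq) == tm

    @given(st.text(alphabet="ACGT", min_size=2, max_size=60))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_wallace_invariant_under_reverse_complement(self, bases):
        assert wallace_tm(bases) == wallace_tm(revcomp_str(bases))

    def test_nearest_neighbor_clears_bound_for_gc_cores(self):
        assert nearest_neighbor_tm("GTCGGGGGCCCCCGGGGGGAT") > 50.0


class TestHairpinScreen:
    def test_detects_stem_at_relaxed_threshold(self):
        report = hairpin_screen("GGGGAAAACCCC", min_stem=4, min_loop=3)
        assert not report.passed
        stem = report.stems[0]
        assert (stem.start, stem.partner_start, stem.stem) == (0, 8, "GGGG")

    @pytest.mark.parametrize(
        "seq",
        [
            "TAGTCGGCCAATAACCCAGGGATTT",  # both printed cassette adaptors are
            "CTCCTGCCGGGGAGCTCCTTCATTT",  # designed to be structure-free
            "AAAAAAAAAA",
        ],
    )
    def test_structure_free_sequences_pass_defaults(self, seq):
        assert hairpin_screen(seq).passed

    def test_loop_shorter_than_minimum_is_ignored(self):
        # GGGGG / CCCCC separated by only 2 bases: not reportable at min_loop=3
        assert hairpin_screen("GGGGGAACCCCC", min_stem=5, min_loop=3).passed
        assert not hairpin_screen("GGGGGAAACCCCC", min_stem=5, min_loop=3).passed


@given(st.text(alphabet="ACGT", min_size=1, max_size=40))
@settings(derandomize=True, max_examples=100, deadline=None)
def test_least_rotation_is_minimal(bases):
    k = least_rotation_offset(bases)
    best = bases[k:] + bases[:k]
    assert all(best <= bases[i:] + bases[:i] for i in range(len(bases)))
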