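"""Vector grammars, fragment release, junction finding and circle assembly."""

import itertools
import random

import pytest

from gcweld.adaptors import FACES, junction_21mer
from gcweld.assembly import (
    TEMPLATES,
    AssemblyFragment,
    FragmentEnd,
    assemble_circle,
    find_junctions,
    plan_vector,
    release_fragments,
)
from gcweld.catalog import Catalog, DeviceRecord, embed_in_donor
from gcweld.errors import (
    AdaptorIncompatibilityError,
    AmbiguousAssemblyError,
    CategoryMismatchError,
    MissingSlotError,
    OpenAssemblyError,
)
from gcweld.seq_core import ENZYMES, NucleotideSequence, revcomp_str


class TestTemplates:
    def test_grammar_slot_counts(self):
        t = TEMPLATES
        assert t["self_replicating_strain_specific"].device_slot_count == 4
        assert t["broad_host_range"].device_slot_count == 3
        assert t["neutral_site_integration"].device_slot_count == 3
        assert t["knockout"].device_slot_count == 2
        assert t["knockout"].custom_slot_count == 2

    def test_plan_orders_devices_by_grammar_not_input(self, kit, core_devices):
        shuffled = list(reversed(core_devices))
        plan = plan_vector("self_replicating_strain_specific", shuffled)
        assert [s.slot_name for s in plan.slots] == [
            "cyanobacterial_replicon", "ecoli_origin", "antibiotic_marker",
            "functional_module",
        ]
        assert plan.slots[0].device_id == "repA7120"

    def test_missing_slot_is_named(self, core_devices):
        with pytest.raises(MissingSlotError, match="antibiotic_marker"):
            plan_vector(
                "self_replicating_strain_specific",
                [d for d in core_devices if d.category != "antibiotic_marker"],
            )

    def test_unplaceable_device_rejected(self, kit, core_devices):
        with pytest.raises(CategoryMismatchError):
            plan_vector(
                "self_replicating_strain_specific",
                core_devices + [kit.devices["ns1Syn"]],
            )

    def test_adaptor_incompatibility_detected(self, kit, core_devices):
        # corrupt the marker's right face so it cannot meet the functional module
        marker = kit.devices["aadA1"]
        broken = DeviceRecord(
            marker.id, marker.category, marker.payload, marker.left_face,
            FACES["GC-NheI"].with_enzyme(marker.release_enzyme),
            marker.release_enzyme, marker.parts,
        )
        devices = [broken if d.id == "aadA1" else d for d in core_devices]
        with pytest.raises(AdaptorIncompatibilityError):
            plan_vector("self_replicating_strain_specific", devices)


class TestReleaseFragments:
    def test_four_donors_yield_four_adaptor_flanked_fragments(self, core_fragments):
        assert len(core_fragments) == 4
        for frag in core_fragments:
            assert len(frag.left_end.overlap) == len(frag.right_end.overlap) == 21
            assert frag.left_end.adaptor_class is not None

    def test_hundred_nt_payload_releases_as_154(self, core_fragments, kit):
        for frag in core_fragments:
            payload = kit.devices[frag.id].payload
            assert len(frag) == len(payload) + 54 == 154


class TestFindJunctions:
    def _edge(self, graph, up, down):
        return [
            e.report
            for e in graph.edges
            if e.report.upstream_fragment == up
            and e.report.downstream_fragment == down
            and not e.up_flipped
            and not e.down_flipped
        ]

    def test_ecorv_ecorv_junction_is_exact(self, core_fragments):
        graph = find_junctions(core_fragments)
        reports = self._edge(graph, "oriEc1", "aadA1")  # GC junction, both EcoRV
        assert len(reports) == 1
        assert (reports[0].overlap_length, reports[0].mismatch_count) == (21, 0)

    def test_zrai_ecorv_junction_has_one_half_site_mismatch(self, core_fragments):
        graph = find_junctions(core_fragments)
        into_zrai = self._edge(graph, "exprGFP1", "repA7120")[0]
        out_of_zrai = self._edge(graph, "repA7120", "oriEc1")[0]
        assert into_zrai.mismatch_positions == (1,)
        assert out_of_zrai.mismatch_positions == (21,)
        for report in (into_zrai, out_of_zrai):
            assert report.overlap_length == 21
            assert report.mismatch_count == 1

    def test_different_classes_share_no_edge(self, core_fragments):
        graph = find_junctions(core_fragments)
        assert not self._edge(graph, "aadA1", "repA7120")  # C2G end vs G5C5 end


def _synthetic_fragment(fid, left_21, right_21, filler):
    return AssemblyFragment(
        fid,
        NucleotideSequence(left_21 + filler + right_21),
        FragmentEnd(left_21, "EcoRV", "X"),
        FragmentEnd(right_21, "EcoRV", "X"),
    )


def _brute_force_cycles(fragments, max_mismatch=1):
    """Independent oracle: enumerate orderings/orientations by direct string
    comparison of terminal 21-mers; first fragment fixed forward."""

    def ends(frag, flipped):
        seq = revcomp_str(frag.seq.bases) if flipped else frag.seq.bases
        return seq[:21], seq[-21:]

    def joins(a_right, b_left):
        return sum(x != y for x, y in zip(a_right, b_left)) <= max_mismatch

    n = len(fragments)
    cycles = []
    for order in itertools.permutations(range(1, n)):
        seq_order = (0,) + order
        for flips in itertools.product((False, True), repeat=n - 1):
            fl = (False,) + flips
            ok = True
            for k in range(n):
                _, a_right = ends(fragments[seq_order[k]], fl[k])
                b_left, _ = ends(fragments[seq_order[(k + 1) % n]], fl[(k + 1) % n])
                if not joins(a_right, b_left):
                    ok = False
                    break
            if ok:
                cycles.append((seq_order, fl))
    return cycles


class TestAssembleCircle:
    def test_four_fragment_circle_length_and_junctions(self, core_assembly, core_fragments):
        assert len(core_assembly.sequence) == 4 * 154 - 4 * 21 == 532
        assert core_assembly.sequence.is_circular
        assert len(core_assembly.junctions) == len(core_fragments)

    def test_mixed_enzyme_kit_has_two_single_mismatch_junctions(self, core_assembly):
        """The ZraI-released replicon touches two EcoRV neighbours, so exactly
        two junctions carry one half-site mismatch each."""
        mismatched = [j for j in core_assembly.junctions if j.mismatch_count]
        assert len(mismatched) == 2
        assert all(j.mismatch_count == 1 for j in mismatched)
        assert {j.mismatch_positions for j in mismatched} == {(1,), (21,)}

    def test_all_junction_tms_clear_the_reaction_threshold(self, core_assembly):
        assert all(j.wallace_tm_C >= 50 for j in core_assembly.junctions)

    def test_order_and_rotation_invariance(self, core_fragments, core_assembly):
        rng = random.Random(42)
        for _ in range(5):
            shuffled = core_fragments[:]
            rng.shuffle(shuffled)
            # keep the canonical anchor fragment first
            shuffled.sort(key=lambda f: f.id != core_fragments[0].id)
            result = assemble_circle(shuffled)
            assert result.sequence.bases == core_assembly.sequence.bases

    def test_flipped_input_fragment_is_auto_oriented(self, core_fragments, core_assembly):
        flipped = [core_fragments[0]] + [
            f.flipped() if f.id == "aadA1" else f for f in core_fragments[1:]
        ]
        result = assemble_circle(flipped)
        assert result.sequence.bases == core_assembly.sequence.bases

    def test_open_assembly_names_unpaired_ends(self, core_fragments):
        with pytest.raises(OpenAssemblyError) as err:
            assemble_circle([f for f in core_fragments if f.id != "oriEc1"])
        # the replicon's C3G3 right end and the marker's GC left end dangle
        assert "C3G3" in str(err.value) and "GC" in str(err.value)

    def test_two_interchangeable_fragments_are_ambiguous(self):
        left = junction_21mer(FACES["G5C5-XbaI"], ENZYMES["EcoRV"]).bases
        right = revcomp_str(junction_21mer(FACES["SacI-C3G3"], ENZYMES["EcoRV"]).bases)
        back_left = junction_21mer(FACES["C3G3-MfeI"], ENZYMES["EcoRV"]).bases
        back_right = revcomp_str(junction_21mer(FACES["XbaI-G5C5"], ENZYMES["EcoRV"]).bases)
        frags = [
            _synthetic_fragment("r1", left, right, "AAAT" * 10),
            _synthetic_fragment("b1", back_left, back_right, "CCCT" * 10),
            _synthetic_fragment("r2", left, right, "GGAT" * 10),
            _synthetic_fragment("b2", back_left, back_right, "TTCA" * 10),
        ]
        with pytest.raises(AmbiguousAssemblyError):
            assemble_circle(frags)

    def test_uniqueness_verdict_matches_brute_force(self, core_fragments):
        assert len(_brute_force_cycles(core_fragments)) == 1
        assemble_circle(core_fragments)  # must succeed

        trimmed = [f for f in core_fragments if f.id != "oriEc1"]
        assert len(_brute_force_cycles(trimmed)) == 0
        with pytest.raises(OpenAssemblyError):
            assemble_circle(trimmed)

    def test_enzyme_dialect_normalization_is_idempotent(self, kit, core_devices):
        """Re-releasing the marker with ZraI instead of EcoRV changes the
        junction mismatches but not the normalized product sequence."""
        marker = kit.devices["aadA1"]
        donor = kit.donor_for_device("aadA1")
        backbone = donor.sequence.bases[: len(donor.sequence) - len(marker.device_sequence)]
        zrai = ENZYMES["ZraI"]
        marker_z = DeviceRecord(
            marker.id, marker.category, marker.payload,
            marker.left_face.with_enzyme(zrai),
            marker.right_face.with_enzyme(zrai), zrai, marker.parts,
        )
        alt = Catalog(dict(kit.parts), dict(kit.devices), dict(kit.donors))
        alt.devices["aadA1"] = marker_z
        alt.donors["pDON-aadA1"] = embed_in_donor(marker_z, backbone, "pDON-aadA1")
        devices = [marker_z if d.id == "aadA1" else d for d in core_devices]
        plan = plan_vector("self_replicating_strain_specific", devices)
        alt_assembly = assemble_circle(release_fragments(plan, alt), plan=plan)

        baseline = assemble_circle(
            release_fragments(
                plan_vector("self_replicating_strain_specific", core_devices), kit
            )
        )
        assert alt_assembly.sequence.bases == baseline.sequence.bases
        assert sum(j.mismatch_count for j in alt_assembly.junctions) == 4

    def test_feature_lifting_preserves_part_sequences(self, core_assembly, kit):
        doubled = core_assembly.sequence.bases * 2
        n = len(core_assembly.sequence)
        for feat in core_assembly.features:
            part = kit.parts[feat.part_id]
            start = feat.start - 1
            length = feat.length_on(n)
            assert doubled[start : start + length] == part.sequence.bases
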