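"""Device/donor data model, enzyme choice, validation, manifest round-trips."""

import json

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from gcweld.adaptors import FACES, junction_21mer
from gcweld.catalog import (
    ANTIBIOTIC_MARKER,
    Catalog,
    DeviceRecord,
    canonical_manifest,
    choose_enzyme,
    device_from_genbank,
    load_catalog,
    load_parts_tsv,
    save_catalog,
    validate_device,
)
from gcweld.errors import (
    CatalogSchemaError,
    DuplicateIdError,
    FlankParseError,
    MissingFileError,
    NoCompatibleEnzymeError,
)
from gcweld.seq_core import ENZYMES, NucleotideSequence, blunt_digest, revcomp_str


class TestChooseEnzyme:
    def test_clean_payload_defaults_to_ecorv(self):
        assert choose_enzyme("AAATTTAAATTTAAATTT").name == "EcoRV"

    def test_internal_ecorv_site_forces_zrai(self):
        assert choose_enzyme("AAAA" + "GATATC" + "TTTT").name == "ZraI"

    def test_both_sites_present_is_fatal(self):
        with pytest.raises(NoCompatibleEnzymeError):
            choose_enzyme("GATATC" + "AAAA" + "GACGTC")


def _marker_device(payload="AAATTTCCCGGGAAATTTCC", faces=("GC-NheI", "AgeI-C2G"),
                   enzyme="EcoRV"):
    return DeviceRecord(
        "m1",
        ANTIBIOTIC_MARKER,
        NucleotideSequence(payload),
        FACES[faces[0]].with_enzyme(ENZYMES[enzyme]),
        FACES[faces[1]].with_enzyme(ENZYMES[enzyme]),
        ENZYMES[enzyme],
    )


class TestValidateDevice:
    def test_clean_marker_is_valid(self):
        assert validate_device(_marker_device()).ok

    def test_wrong_flank_classes_flagged(self):
        report = validate_device(_marker_device(faces=("G5C5-XbaI", "SacI-C3G3")))
        assert any(v.code == "flank_class_mismatch" for v in report.violations)

    def test_internal_release_site_flagged_with_position(self):
        report = validate_device(_marker_device(payload="AAAA" + "GATATC" + "TTTT"))
        offender = [v for v in report.violations if v.code == "internal_release_site"]
        assert offender and "position 4" in offender[0].message

    def test_face_enzyme_disagreement_flagged(self):
        device = _marker_device()
        bad = DeviceRecord(
            device.id, device.category, device.payload,
            device.left_face.with_enzyme(ENZYMES["ZraI"]),
            device.right_face, device.release_enzyme,
        )
        report = validate_device(bad)
        assert any(v.code == "face_enzyme_mismatch" for v in report.violations)


class TestReleasedFragmentGeometry:
    def test_released_fragment_is_payload_plus_54(self, kit):
        for device in kit.devices.values():
            assert len(device.released_sequence) == len(device.payload) + 54

    def test_terminal_21mers_match_junction_arithmetic(self, kit):
        """Digesting each donor exposes exactly the face junction 21-mers."""
        for device in kit.devices.values():
            donor = kit.donor_for_device(device.id)
            frags = blunt_digest(donor.sequence, device.release_enzyme)
            assert len(frags) == 2
            released = next(f for f in frags if device.payload.bases in f.seq.bases)
            assert released.seq.bases == device.released_sequence.bases
            left, right = released.seq.bases[:21], released.seq.bases[-21:]
            assert left == junction_21mer(device.left_face, device.release_enzyme).bases
            assert right == revcomp_str(
                junction_21mer(device.right_face, device.release_enzyme).bases
            )

    def test_table_dialects_imply_release_enzyme(self, kit):
        for device in kit.devices.values():
            prefix = device.left_face.flank_string[:6]
            assert prefix == device.release_enzyme.recognition


class TestManifestRoundTrip:
    def test_save_load_is_identity_on_canonical_manifests(self, kit, tmp_path):
        save_catalog(kit, tmp_path / "kit")
        loaded = load_catalog(tmp_path / "kit")
        assert canonical_manifest(loaded) == canonical_manifest(kit)

    def test_second_save_is_byte_identical(self, kit, tmp_path):
        p1 = save_catalog(kit, tmp_path / "a")
        loaded = load_catalog(p1)
        p2 = save_catalog(loaded, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()

    def test_long_sequences_go_to_sibling_genbank_files(self, kit, tmp_path):
        target = tmp_path / "kit"
        save_catalog(kit, target)
        manifest = json.loads((target / "manifest.json").read_text())
        assert all("sequence_file" in d for d in manifest["donor_plasmids"])
        assert (target / manifest["donor_plasmids"][0]["sequence_file"]).exists()

    def test_duplicate_device_id_rejected(self, kit, tmp_path):
        target = tmp_path / "kit"
        save_catalog(kit, target)
        manifest = json.loads((target / "manifest.json").read_text())
        manifest["devices"].append(dict(manifest["devices"][0]))
        (target / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(DuplicateIdError):
            load_catalog(target)

    def test_missing_referenced_file_reported(self, kit, tmp_path):
        target = tmp_path / "kit"
        save_catalog(kit, target)
        manifest = json.loads((target / "manifest.json").read_text())
        manifest["donor_plasmids"][0]["sequence_file"] = "nope.gb"
        (target / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(MissingFileError):
            load_catalog(target)

    def test_schema_violation_names_the_field(self, tmp_path):
        (tmp_path / "manifest.json").write_text(json.dumps({"format_version": 1}))
        with pytest.raises(CatalogSchemaError, match="parts"):
            load_catalog(tmp_path)


class TestDeviceFromGenbank:
    def _record(self, device, lowercase=False):
        bases = device.device_sequence.bases
        rec = SeqRecord(
            Seq(bases.lower() if lowercase else bases), id=device.id, name=device.id
        )
        for ann in device.parts:
            rec.features.append(
                SeqFeature(
                    SimpleLocation(ann.start + 30, ann.end + 30, 1),
                    type="misc_feature",
                    qualifiers={"part_id": [ann.part_id]},
                )
            )
        return rec

    def test_faces_and_payload_recovered(self, kit):
        device = kit.devices["aadA1"]
        parsed = device_from_genbank(self._record(device), ANTIBIOTIC_MARKER)
        assert parsed.payload == device.payload
        assert parsed.left_face == device.left_face
        assert parsed.right_face == device.right_face
        assert parsed.parts == device.parts

    def test_lowercase_flanks_are_normalized(self, kit):
        device = kit.devices["aadA1"]
        parsed = device_from_genbank(self._record(device, lowercase=True), ANTIBIOTIC_MARKER)
        assert parsed.left_face == device.left_face

    def test_missing_right_flank_is_an_error(self, kit):
        device = kit.devices["aadA1"]
        rec = SeqRecord(Seq(device.device_sequence.bases[:-30] + "A" * 30), id="x")
        with pytest.raises(FlankParseError, match="right flank"):
            device_from_genbank(rec, ANTIBIOTIC_MARKER)


def test_parts_tsv_round_trip(tmp_path, kit):
    path = tmp_path / "parts.tsv"
    lines = ["id\tname\trole\tsequence"] + [
        f"{p.id}\t{p.name}\t{p.role}\t{p.sequence.bases}"
        for p in kit.parts.values()
    ]
    path.write_text("\n".join(lines) + "\n")
    loaded = load_parts_tsv(path)
    assert {p.id: p for p in loaded} == kit.parts
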