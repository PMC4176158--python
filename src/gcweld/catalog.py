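"""Device / donor-plasmid / parts data model and manifest I/O.

This is the in-silico counterpart of a donor-plasmid library: categorized
devices (replicons, origins, markers, functional modules) with their adaptor
faces, the circular donor plasmids they are released from, and a flat parts
database used for annotation.  A catalog round-trips through a JSON manifest
(long sequences as sibling GenBank files) and every device is validated
against the assembly grammar's flank-class rules on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .adaptors import (
    ADAPTOR_CLASSES,
    FACES,
    AdaptorClass,
    AdaptorFace,
    face_label,
    junction_21mer,
    parse_flank,
)
from .errors import (
    CatalogSchemaError,
    DeviceValidationError,
    DuplicateIdError,
    FlankParseError,
    MissingFileError,
    NoCompatibleEnzymeError,
)
from .seq_core import (
    CIRCULAR,
    ENZYMES,
    LINEAR,
    EnzymeSpec,
    NucleotideSequence,
    SeqLike,
    as_sequence,
    revcomp_str,
    scan_sites,
)

# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------

CYANO_REPLICON = "cyano_replicon"
ECOLI_ORIGIN_KNOCKOUT = "ecoli_origin_knockout"
ECOLI_ORIGIN_PAIRED = "ecoli_origin_paired"
BHR_REPLICON = "bhr_replicon"
NEUTRAL_SITE = "neutral_site"
ANTIBIOTIC_MARKER = "antibiotic_marker"
CLONING_CASSETTE = "cloning_cassette"
EXPRESSION_CASSETTE = "expression_cassette"
REPORTER_CASSETTE = "reporter_cassette"
PROMOTER_REPORTER = "promoter_reporter"
CUSTOM_PCR_FRAGMENT = "custom_pcr_fragment"

#: Functional modules all share the same flank classes and fill the same
#: grammar slot.
FUNCTIONAL_CATEGORIES = frozenset(
    {CLONING_CASSETTE, EXPRESSION_CASSETTE, REPORTER_CASSETTE, PROMOTER_REPORTER}
)

DEVICE_CATEGORIES = frozenset(
    {
        CYANO_REPLICON,
        ECOLI_ORIGIN_KNOCKOUT,
        ECOLI_ORIGIN_PAIRED,
        BHR_REPLICON,
        NEUTRAL_SITE,
        ANTIBIOTIC_MARKER,
        CUSTOM_PCR_FRAGMENT,
    }
    | FUNCTIONAL_CATEGORIES
)

#: (left, right) adaptor classes per category.  Custom PCR fragments have no
#: fixed classes — their tails depend on the slot they fill.
CATEGORY_FLANK_CLASSES: dict[str, tuple[AdaptorClass, AdaptorClass]] = {
    CYANO_REPLICON: (ADAPTOR_CLASSES["G5C5"], ADAPTOR_CLASSES["C3G3"]),
    ECOLI_ORIGIN_KNOCKOUT: (ADAPTOR_CLASSES["G5C5"], ADAPTOR_CLASSES["C3G3"]),
    ECOLI_ORIGIN_PAIRED: (ADAPTOR_CLASSES["C3G3"], ADAPTOR_CLASSES["GC"]),
    BHR_REPLICON: (ADAPTOR_CLASSES["G5C5"], ADAPTOR_CLASSES["GC"]),
    NEUTRAL_SITE: (ADAPTOR_CLASSES["G5C5"], ADAPTOR_CLASSES["GC"]),
    ANTIBIOTIC_MARKER: (ADAPTOR_CLASSES["GC"], ADAPTOR_CLASSES["C2G"]),
    **{c: (ADAPTOR_CLASSES["C2G"], ADAPTOR_CLASSES["G5C5"]) for c in FUNCTIONAL_CATEGORIES},
}

#: Default bundled face labels per category (the printed flank table rows).
CATEGORY_FACE_LABELS: dict[str, tuple[str, str]] = {
    CYANO_REPLICON: ("G5C5-XbaI", "SacI-C3G3"),
    ECOLI_ORIGIN_KNOCKOUT: ("G5C5-XbaI", "SacI-C3G3"),
    ECOLI_ORIGIN_PAIRED: ("C3G3-MfeI", "NheI-GC"),
    BHR_REPLICON: ("G5C5-XbaI", "NheI-GC"),
    NEUTRAL_SITE: ("G5C5-XbaI", "NheI-GC"),
    ANTIBIOTIC_MARKER: ("GC-NheI", "AgeI-C2G"),
    **{c: ("C2G-AgeI", "XbaI-G5C5") for c in FUNCTIONAL_CATEGORIES},
}

PART_ROLES = frozenset(
    {"promoter", "RBS", "CDS", "terminator", "replicon", "marker", "other"}
)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartRecord:
    """A named functional part used for annotation."""

    id: str
    name: str
    role: str
    sequence: NucleotideSequence

    def __post_init__(self) -> None:
        if self.role not in PART_ROLES:
            raise CatalogSchemaError(
                f"part {self.id!r}: role {self.role!r} not in {sorted(PART_ROLES)}"
            )


@dataclass(frozen=True)
class PartAnnotation:
    """A part occurrence, payload-relative, 0-based half-open."""

    part_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CatalogSchemaError(f"strand must be +/-, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise CatalogSchemaError("annotation coordinates must satisfy 0 <= start < end")


@dataclass(frozen=True)
class DeviceRecord:
    """A categorized device: payload plus its two adaptor faces.

    The device as it sits in a donor plasmid reads (top strand)::

        left flank (30) | payload | revcomp(right flank) (30)

    Both faces carry the same release enzyme, and the payload must be free of
    that enzyme's recognition site on either strand.
    """

    id: str
    category: str
    payload: NucleotideSequence
    left_face: AdaptorFace
    right_face: AdaptorFace
    release_enzyme: EnzymeSpec
    parts: tuple[PartAnnotation, ...] = ()

    @property
    def device_sequence(self) -> NucleotideSequence:
        """Top strand of the flanked device (payload + 60 nt)."""
        return NucleotideSequence(
            self.left_face.flank_string
            + self.payload.bases
            + revcomp_str(self.right_face.flank_string)
        )

    @property
    def released_sequence(self) -> NucleotideSequence:
        """The fragment released by blunt digestion (payload + 54 nt): each end
        keeps a 3-nt half-site, the 15-nt core, GAT and the secondary site."""
        return NucleotideSequence(self.device_sequence.bases[3:-3])

    def terminal_21mers(self) -> tuple[str, str]:
        left = junction_21mer(self.left_face, self.release_enzyme).bases
        right = revcomp_str(junction_21mer(self.right_face, self.release_enzyme).bases)
        return left, right


@dataclass(frozen=True)
class DonorPlasmid:
    """A circular donor: backbone + flanked device."""

    id: str
    device_id: str
    sequence: NucleotideSequence

    def __post_init__(self) -> None:
        if not self.sequence.is_circular:
            raise CatalogSchemaError(f"donor {self.id!r}: sequence must be circular")


def embed_in_donor(
    device: DeviceRecord, backbone: SeqLike, donor_id: str
) -> DonorPlasmid:
    """Circularize backbone + flanked device into a donor plasmid."""
    bb = as_sequence(backbone)
    return DonorPlasmid(
        donor_id,
        device.id,
        NucleotideSequence(bb.bases + device.device_sequence.bases, CIRCULAR),
    )


# ---------------------------------------------------------------------------
# Enzyme selection & validation
# ---------------------------------------------------------------------------


def choose_enzyme(payload: SeqLike) -> EnzymeSpec:
    """Pick the release enzyme for a payload.

    EcoRV is the default; ZraI is used instead when an EcoRV site is present
    within the payload.  A payload carrying both sites cannot be released
    bluntly and is rejected.  Both strands are screened, although the two
    recognition sites are palindromic.
    """
    seq = as_sequence(payload)

    def _hits(enzyme: EnzymeSpec) -> bool:
        return bool(scan_sites(seq, enzyme)) or bool(
            scan_sites(seq.reverse_complement(), enzyme)
        )

    if not _hits(ENZYMES["EcoRV"]):
        return ENZYMES["EcoRV"]
    if not _hits(ENZYMES["ZraI"]):
        return ENZYMES["ZraI"]
    raise NoCompatibleEnzymeError(
        "payload contains both EcoRV and ZraI sites; no compatible release enzyme"
    )


@dataclass(frozen=True)
class Violation:
    code: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    device_id: str
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_device(device: DeviceRecord) -> ValidationReport:
    """Check a device against the grammar rules; an empty report is valid."""
    v: list[Violation] = []
    if device.category not in DEVICE_CATEGORIES:
        v.append(Violation("unknown_category", f"unknown category {device.category!r}"))
    classes = CATEGORY_FLANK_CLASSES.get(device.category)
    if classes is not None:
        left_cls, right_cls = classes
        if device.left_face.adaptor_class != left_cls or (
            device.right_face.adaptor_class != right_cls
        ):
            v.append(
                Violation(
                    "flank_class_mismatch",
                    f"category {device.category} requires flank classes "
                    f"({left_cls.name}, {right_cls.name}); device has "
                    f"({device.left_face.adaptor_class.name}, "
                    f"{device.right_face.adaptor_class.name})",
                )
            )
    for face, side in ((device.left_face, "left"), (device.right_face, "right")):
        if face.release_enzyme != device.release_enzyme:
            v.append(
                Violation(
                    "face_enzyme_mismatch",
                    f"{side} face uses {face.release_enzyme.name}, device is "
                    f"released with {device.release_enzyme.name}",
                )
            )
    for strand_name, seq in (
        ("top", device.payload),
        ("bottom", device.payload.reverse_complement()),
    ):
        for pos in scan_sites(seq, device.release_enzyme):
            v.append(
                Violation(
                    "internal_release_site",
                    f"payload contains {device.release_enzyme.name} site on "
                    f"{strand_name} strand at position {pos}",
                )
            )
    for ann in device.parts:
        if ann.end > len(device.payload):
            v.append(
                Violation(
                    "part_out_of_bounds",
                    f"part {ann.part_id} annotation {ann.start}..{ann.end} exceeds "
                    f"payload length {len(device.payload)}",
                )
            )
    return ValidationReport(device.id, tuple(v))


def validate_donor(donor: DonorPlasmid, device: DeviceRecord) -> ValidationReport:
    """A donor must yield the intact device payload on digestion."""
    from .seq_core import blunt_digest  # local import to keep module header lean

    v: list[Violation] = []
    try:
        frags = blunt_digest(donor.sequence, device.release_enzyme)
    except Exception as exc:  # no cut site
        return ValidationReport(donor.id, (Violation("digest_failed", str(exc)),))
    carriers = [f for f in frags if device.payload.bases in f.seq.bases]
    if len(carriers) != 1:
        v.append(
            Violation(
                "payload_not_released",
                f"digestion with {device.release_enzyme.name} yields {len(frags)} "
                f"fragments, {len(carriers)} of which carry the intact payload",
            )
        )
    return ValidationReport(donor.id, tuple(v))


# ---------------------------------------------------------------------------
# Catalog container
# ---------------------------------------------------------------------------

MANIFEST_VERSION = 1
#: sequences longer than this are stored as sibling GenBank files on save
INLINE_SEQUENCE_LIMIT = 200


@dataclass
class Catalog:
    parts: dict[str, PartRecord] = field(default_factory=dict)
    devices: dict[str, DeviceRecord] = field(default_factory=dict)
    donors: dict[str, DonorPlasmid] = field(default_factory=dict)

    def add_part(self, part: PartRecord) -> None:
        if part.id in self.parts:
            raise DuplicateIdError(f"duplicate part id {part.id!r}")
        self.parts[part.id] = part

    def add_device(self, device: DeviceRecord, donor: DonorPlasmid | None = None) -> None:
        if device.id in self.devices:
            raise DuplicateIdError(f"duplicate device id {device.id!r}")
        report = validate_device(device)
        if not report.ok:
            raise DeviceValidationError(
                f"device {device.id!r} invalid: "
                + "; ".join(viol.message for viol in report.violations)
            )
        self.devices[device.id] = device
        if donor is not None:
            if donor.id in self.donors:
                raise DuplicateIdError(f"duplicate donor id {donor.id!r}")
            self.donors[donor.id] = donor

    def donor_for_device(self, device_id: str) -> DonorPlasmid:
        for donor in self.donors.values():
            if donor.device_id == device_id:
                return donor
        raise CatalogSchemaError(f"no donor plasmid carries device {device_id!r}")

    def devices_by_category(self, category: str) -> list[DeviceRecord]:
        return [d for d in self.devices.values() if d.category == category]


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------


def _require(obj: Mapping, key: str, typ, where: str):
    if key not in obj:
        raise CatalogSchemaError(f"{where}: missing required key {key!r}")
    val = obj[key]
    if not isinstance(val, typ):
        raise CatalogSchemaError(
            f"{where}: key {key!r} must be {typ.__name__}, got {type(val).__name__}"
        )
    return val


def canonical_manifest(catalog: Catalog) -> dict:
    """The catalog as a canonical (sorted, fully inline) JSON-ready dict."""
    return {
        "format_version": MANIFEST_VERSION,
        "adaptor_flanks": {label: f.flank_string for label, f in sorted(FACES.items())},
        "parts": [
            {
                "id": p.id,
                "name": p.name,
                "role": p.role,
                "sequence": p.sequence.bases,
            }
            for p in sorted(catalog.parts.values(), key=lambda p: p.id)
        ],
        "devices": [
            {
                "id": d.id,
                "category": d.category,
                "release_enzyme": d.release_enzyme.name,
                "left_flank": d.left_face.flank_string,
                "right_flank": d.right_face.flank_string,
                "payload": d.payload.bases,
                "parts": [
                    {
                        "part_id": a.part_id,
                        "start": a.start,
                        "end": a.end,
                        "strand": a.strand,
                    }
                    for a in d.parts
                ],
            }
            for d in sorted(catalog.devices.values(), key=lambda d: d.id)
        ],
        "donor_plasmids": [
            {"id": don.id, "device_id": don.device_id, "sequence": don.sequence.bases}
            for don in sorted(catalog.donors.values(), key=lambda x: x.id)
        ],
    }


def save_catalog(catalog: Catalog, directory: str | Path) -> Path:
    """Write ``manifest.json`` (+ sibling GenBank files for long sequences).

    Sequences longer than :data:`INLINE_SEQUENCE_LIMIT` are written as
    GenBank files next to the manifest and referenced by file name.
    """
    from . import io_formats

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = canonical_manifest(catalog)
    for entry in manifest["devices"]:
        if len(entry["payload"]) > INLINE_SEQUENCE_LIMIT:
            fname = f"device_{entry['id']}.gb"
            io_formats.write_genbank(
                io_formats.PlasmidRecord(
                    name=entry["id"],
                    sequence=NucleotideSequence(entry["payload"], LINEAR),
                    features=[],
                ),
                directory / fname,
            )
            entry["payload_file"] = fname
            del entry["payload"]
    for entry in manifest["donor_plasmids"]:
        if len(entry["sequence"]) > INLINE_SEQUENCE_LIMIT:
            fname = f"donor_{entry['id']}.gb"
            io_formats.write_genbank(
                io_formats.PlasmidRecord(
                    name=entry["id"],
                    sequence=NucleotideSequence(entry["sequence"], CIRCULAR),
                    features=[],
                ),
                directory / fname,
            )
            entry["sequence_file"] = fname
            del entry["sequence"]
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _load_sequence(
    entry: Mapping, inline_key: str, file_key: str, topology: str, base: Path, where: str
) -> NucleotideSequence:
    from . import io_formats

    if inline_key in entry:
        return NucleotideSequence(_require(entry, inline_key, str, where), topology)
    if file_key in entry:
        fname = _require(entry, file_key, str, where)
        path = base / fname
        if not path.exists():
            raise MissingFileError(f"{where}: referenced file {fname!r} not found")
        record = io_formats.read_genbank(path)
        return NucleotideSequence(record.sequence.bases, topology)
    raise CatalogSchemaError(f"{where}: needs {inline_key!r} or {file_key!r}")


def load_catalog(source: str | Path) -> Catalog:
    """Load and validate a catalog from a manifest file or its directory."""
    path = Path(source)
    if path.is_dir():
        path = path / "manifest.json"
    if not path.exists():
        raise MissingFileError(f"manifest not found at {path}")
    base = path.parent
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CatalogSchemaError(f"manifest is not valid JSON: {exc}") from exc
    if not isinstance(manifest, dict):
        raise CatalogSchemaError("manifest root must be a JSON object")
    version = _require(manifest, "format_version", int, "manifest")
    if version != MANIFEST_VERSION:
        raise CatalogSchemaError(f"unsupported manifest version {version}")

    catalog = Catalog()
    for entry in _require(manifest, "parts", list, "manifest"):
        where = f"part {entry.get('id', '?')!r}"
        part = PartRecord(
            _require(entry, "id", str, where),
            _require(entry, "name", str, where),
            _require(entry, "role", str, where),
            NucleotideSequence(_require(entry, "sequence", str, where)),
        )
        catalog.add_part(part)
    devices = _require(manifest, "devices", list, "manifest")
    for entry in devices:
        where = f"device {entry.get('id', '?')!r}"
        dev_id = _require(entry, "id", str, where)
        category = _require(entry, "category", str, where)
        if category not in DEVICE_CATEGORIES:
            raise CatalogSchemaError(f"{where}: unknown category {category!r}")
        enzyme_name = _require(entry, "release_enzyme", str, where)
        if enzyme_name not in ENZYMES:
            raise CatalogSchemaError(f"{where}: unknown enzyme {enzyme_name!r}")
        try:
            left = parse_flank(_require(entry, "left_flank", str, where))
            right = parse_flank(_require(entry, "right_flank", str, where))
        except FlankParseError as exc:
            raise CatalogSchemaError(f"{where}: {exc.message}") from exc
        payload = _load_sequence(entry, "payload", "payload_file", LINEAR, base, where)
        anns = tuple(
            PartAnnotation(
                _require(a, "part_id", str, where),
                _require(a, "start", int, where),
                _require(a, "end", int, where),
                a.get("strand", "+"),
            )
            for a in entry.get("parts", [])
        )
        for a in anns:
            if a.part_id not in catalog.parts:
                raise CatalogSchemaError(f"{where}: unknown part {a.part_id!r}")
        device = DeviceRecord(
            dev_id, category, payload, left, right, ENZYMES[enzyme_name], anns
        )
        catalog.add_device(device)
    for entry in _require(manifest, "donor_plasmids", list, "manifest"):
        where = f"donor {entry.get('id', '?')!r}"
        don_id = _require(entry, "id", str, where)
        device_id = _require(entry, "device_id", str, where)
        if device_id not in catalog.devices:
            raise CatalogSchemaError(f"{where}: unknown device {device_id!r}")
        seq = _load_sequence(entry, "sequence", "sequence_file", CIRCULAR, base, where)
        donor = DonorPlasmid(don_id, device_id, seq)
        if donor.id in catalog.donors:
            raise DuplicateIdError(f"duplicate donor id {donor.id!r}")
        report = validate_donor(donor, catalog.devices[device_id])
        if not report.ok:
            raise CatalogSchemaError(
                f"{where}: " + "; ".join(v.message for v in report.violations)
            )
        catalog.donors[donor.id] = donor
    return catalog


# ---------------------------------------------------------------------------
# Imports from other formats
# ---------------------------------------------------------------------------


def device_from_genbank(record, category: str) -> DeviceRecord:
    """Build a :class:`DeviceRecord` from a Biopython ``SeqRecord`` whose
    termini carry the two 30-nt adaptor flanks (case-insensitive).

    Features with a ``part_id`` (or ``label``) qualifier inside the payload
    are mapped to part annotations.
    """
    text = str(record.seq).upper()
    if len(text) < 60:
        raise FlankParseError("record too short to carry two 30-nt flanks")
    left = parse_flank(text[:30])
    try:
        right = parse_flank(revcomp_str(text[-30:]))
    except FlankParseError as exc:
        raise FlankParseError(f"right flank unparseable: {exc.message}") from exc
    payload = NucleotideSequence(text[30:-30], LINEAR)
    anns = []
    for feat in getattr(record, "features", []):
        quals = feat.qualifiers
        part_id = (quals.get("part_id") or quals.get("label") or [None])[0]
        if part_id is None:
            continue
        start = int(feat.location.start) - 30
        end = int(feat.location.end) - 30
        if start < 0 or end > len(payload):
            continue  # feature lies (partly) in the flanks; not a payload part
        strand = "-" if feat.location.strand == -1 else "+"
        anns.append(PartAnnotation(part_id, start, end, strand))
    enzyme = left.release_enzyme
    if right.release_enzyme != enzyme:
        raise FlankParseError(
            f"flank release enzymes disagree: {enzyme.name} vs {right.release_enzyme.name}"
        )
    return DeviceRecord(record.id or record.name, category, payload, left, right, enzyme, tuple(anns))


def load_parts_tsv(path: str | Path) -> list[PartRecord]:
    """Parts from a TSV with columns id, name, role, sequence (header optional)."""
    parts = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if lineno == 1 and cols[0].lower() in ("id", "part_id"):
            continue
        if len(cols) != 4:
            raise CatalogSchemaError(f"{path}:{lineno}: expected 4 tab-separated columns")
        parts.append(PartRecord(cols[0], cols[1], cols[2], NucleotideSequence(cols[3])))
    return parts


def load_parts_fasta(path: str | Path) -> list[PartRecord]:
    """Parts from FASTA whose headers read ``>id role [name...]``."""
    from Bio import SeqIO

    parts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        if len(tokens) < 2:
            raise CatalogSchemaError(
                f"{path}: header {rec.description!r} must read '>id role [name]'"
            )
        role = tokens[1]
        name = " ".join(tokens[2:]) or rec.id
        parts.append(PartRecord(rec.id, name, role, NucleotideSequence(str(rec.seq))))
    return parts
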