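"""Seeded synthetic fixture generator: devices, donor plasmids, parts.

Everything here is synthetic stand-in material — short random payloads with
small made-up parts embedded — so the whole design engine is exercisable and
testable without downloading any real donor-plasmid sequence.  Defaults are
desk-scale: 100-nt payloads and a ~2.7-kb donor backbone (pUC19-scale).

Determinism: a named stable PRNG (Python's Mersenne Twister,
``random.Random``) seeded with ``"<seed>:<stream>"`` strings; identical seed
and spec give byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .assembly import CASSETTE_ADAPTORS
from .catalog import (
    ANTIBIOTIC_MARKER,
    BHR_REPLICON,
    CATEGORY_FACE_LABELS,
    CLONING_CASSETTE,
    CYANO_REPLICON,
    ECOLI_ORIGIN_KNOCKOUT,
    ECOLI_ORIGIN_PAIRED,
    EXPRESSION_CASSETTE,
    NEUTRAL_SITE,
    Catalog,
    DeviceRecord,
    DonorPlasmid,
    PartAnnotation,
    PartRecord,
    choose_enzyme,
    embed_in_donor,
)
from .adaptors import FACES
from .errors import FixtureError
from .seq_core import (
    ENZYMES,
    LINEAR,
    NucleotideSequence,
    revcomp_str,
    scan_sites,
)

#: sites that must not appear by accident in generated material
FORBIDDEN_SITES = ("GATATC", "GACGTC", "ATTTAAAT")

DEFAULT_PAYLOAD_LENGTH = 100
DEFAULT_BACKBONE_LENGTH = 2700
DEFAULT_GC_FRACTION = 0.5
DEFAULT_MAX_RETRIES = 200


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic device + donor plasmid."""

    seed: int
    device_id: str
    category: str
    payload_length: int = DEFAULT_PAYLOAD_LENGTH
    gc_fraction: float = DEFAULT_GC_FRACTION
    parts_to_embed: tuple[PartRecord, ...] = ()
    plant_internal_ecorv: bool = False  # forces the ZraI release path
    backbone_length: int = DEFAULT_BACKBONE_LENGTH
    max_retries: int = DEFAULT_MAX_RETRIES

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise FixtureError("gc_fraction must lie in [0, 1]")
        if self.payload_length < 1:
            raise FixtureError("payload_length must be positive")


def _random_bases(rng: random.Random, length: int, gc_fraction: float) -> str:
    out = []
    for _ in range(length):
        if rng.random() < gc_fraction:
            out.append("G" if rng.random() < 0.5 else "C")
        else:
            out.append("A" if rng.random() < 0.5 else "T")
    return "".join(out)


def _count_sites(text: str, site: str) -> int:
    count = pos = 0
    pos = text.find(site)
    while pos != -1:
        count += 1
        pos = text.find(site, pos + 1)
    return count


def _clean(text: str, allow_ecorv: int = 0, allow_swai: int = 0) -> bool:
    return (
        _count_sites(text, "GACGTC") == 0
        and _count_sites(text, "GATATC") == allow_ecorv
        and _count_sites(text, "ATTTAAAT") == allow_swai
    )


def _compose_payload(
    rng: random.Random, spec: FixtureSpec
) -> tuple[str, tuple[PartAnnotation, ...]]:
    """Random filler with the requested parts embedded in order, resampled
    until free of cutter sites (one planted EcoRV site when requested)."""
    parts = spec.parts_to_embed
    fixed = sum(len(p.sequence) for p in parts) + (6 if spec.plant_internal_ecorv else 0)
    filler_total = spec.payload_length - fixed
    if filler_total < len(parts) + 1:
        raise FixtureError(
            f"payload_length {spec.payload_length} too small for the embedded parts"
        )
    for _ in range(spec.max_retries):
        n_gaps = len(parts) + 1
        base = filler_total // n_gaps
        gaps = [base] * n_gaps
        gaps[-1] += filler_total - base * n_gaps
        segments = []
        annotations = []
        cursor = 0
        for i, part in enumerate(parts):
            filler = _random_bases(rng, gaps[i], spec.gc_fraction)
            segments.append(filler)
            cursor += len(filler)
            segments.append(part.sequence.bases)
            annotations.append(
                PartAnnotation(part.id, cursor, cursor + len(part.sequence), "+")
            )
            cursor += len(part.sequence)
        last = _random_bases(rng, gaps[-1], spec.gc_fraction)
        if spec.plant_internal_ecorv:
            mid = len(last) // 2
            last = last[:mid] + "GATATC" + last[mid:]
        segments.append(last)
        payload = "".join(segments)
        assert len(payload) == spec.payload_length
        if _clean(payload, allow_ecorv=1 if spec.plant_internal_ecorv else 0):
            return payload, tuple(annotations)
    raise FixtureError(
        f"could not generate a cutter-free payload for {spec.device_id!r} in "
        f"{spec.max_retries} attempts"
    )


def _compose_backbone(
    rng: random.Random, spec: FixtureSpec, marker: PartRecord
) -> tuple[str, int]:
    """Synthetic donor backbone carrying one marker part; cutter-free."""
    marker_seq = marker.sequence.bases
    filler_total = spec.backbone_length - len(marker_seq)
    if filler_total < 2:
        raise FixtureError("backbone_length too small for the marker part")
    for _ in range(spec.max_retries):
        a = filler_total // 2
        left = _random_bases(rng, a, spec.gc_fraction)
        right = _random_bases(rng, filler_total - a, spec.gc_fraction)
        backbone = left + marker_seq + right
        if _clean(backbone):
            return backbone, a
    raise FixtureError(
        f"could not generate a cutter-free backbone for {spec.device_id!r}"
    )


def _random_part(
    rng: random.Random, part_id: str, name: str, role: str, length: int
) -> PartRecord:
    for _ in range(DEFAULT_MAX_RETRIES):
        seq = _random_bases(rng, length, 0.5)
        if _clean(seq):
            return PartRecord(part_id, name, role, NucleotideSequence(seq))
    raise FixtureError(f"could not generate part {part_id!r}")


def synthetic_parts(seed: int) -> dict[str, PartRecord]:
    """The bundled synthetic parts database (all sequences are made up)."""
    rng = random.Random(f"{seed}:parts")
    parts = [
        _random_part(rng, "pSyn1", "synthetic promoter 1", "promoter", 35),
        _random_part(rng, "rbsSyn1", "synthetic RBS 1", "RBS", 12),
        _random_part(rng, "gfpSyn1", "synthetic reporter CDS stub", "CDS", 30),
        _random_part(rng, "terSyn1", "synthetic terminator 1", "terminator", 28),
        _random_part(rng, "repSyn1", "synthetic replicon protein stub", "CDS", 30),
        _random_part(rng, "oriVSyn1", "synthetic origin stub", "replicon", 40),
        _random_part(rng, "aadASyn1", "synthetic Sp/Sm marker stub", "marker", 30),
        _random_part(rng, "sacBSyn1", "synthetic sacB stub", "marker", 30),
        _random_part(rng, "ccdBSyn1", "synthetic ccdB stub", "CDS", 45),
        _random_part(rng, "ampRSyn1", "synthetic backbone AmpR stub", "marker", 60),
    ]
    return {p.id: p for p in parts}


def generate_device(
    spec: FixtureSpec, backbone_marker: PartRecord
) -> tuple[DeviceRecord, DonorPlasmid]:
    """One synthetic device plus the donor plasmid carrying it.

    The payload is random at the requested GC fraction with the requested
    parts embedded; the flanks follow the device category's adaptor classes,
    with the release enzyme chosen by the standard payload rule.
    """
    rng = random.Random(f"{spec.seed}:{spec.device_id}")
    payload_bases, annotations = _compose_payload(rng, spec)
    payload = NucleotideSequence(payload_bases, LINEAR)
    enzyme = choose_enzyme(payload)
    left_label, right_label = CATEGORY_FACE_LABELS[spec.category]
    device = DeviceRecord(
        spec.device_id,
        spec.category,
        payload,
        FACES[left_label].with_enzyme(enzyme),
        FACES[right_label].with_enzyme(enzyme),
        enzyme,
        annotations,
    )
    backbone, _ = _compose_backbone(rng, spec, backbone_marker)
    donor = embed_in_donor(device, backbone, f"pDON-{spec.device_id}")
    return device, donor


def cassette_payload(seed: int, ccdb_part: PartRecord) -> tuple[str, tuple[PartAnnotation, ...]]:
    """The cloning-cassette payload: printed adaptor, SwaI half-sites, ccdB
    stuffer, second printed adaptor (on the bottom strand)."""
    a1, a2 = CASSETTE_ADAPTORS
    payload = a1 + "AAAT" + ccdb_part.sequence.bases + "ATTT" + revcomp_str(a2)
    if not _clean(payload, allow_swai=2):
        raise FixtureError("cassette payload acquired a stray cutter site")
    start = len(a1) + 4
    return payload, (
        PartAnnotation(ccdb_part.id, start, start + len(ccdb_part.sequence), "+"),
    )


def tailed_cassette_insert(core: str | NucleotideSequence) -> NucleotideSequence:
    """Attach the printed 25-nt cassette adaptors to an insert core, ready for
    isothermal cloning into a SwaI-opened backbone."""
    a1, a2 = CASSETTE_ADAPTORS
    bases = core.bases if isinstance(core, NucleotideSequence) else core.upper()
    return NucleotideSequence(a1 + bases + revcomp_str(a2), LINEAR)


#: device ids of the 4-device self-replicating demonstration set, in grammar
#: order (replicon / E. coli origin / marker / functional module)
KIT_CORE_DEVICES = ("repA7120", "oriEc1", "aadA1", "exprGFP1")


def generate_kit(
    seed: int, payload_length: int = DEFAULT_PAYLOAD_LENGTH
) -> Catalog:
    """A full synthetic catalog: parts DB, 8 devices and their donors.

    Covers every vector grammar: a ZraI-released strain-specific replicon
    (its payload carries a planted internal EcoRV site, forcing the ZraI
    fallback), an E. coli origin, an antibiotic marker, an expression
    cassette, a broad-host-range replicon, a knockout backbone, a neutral
    site, and a SwaI/ccdB cloning cassette.
    """
    parts = synthetic_parts(seed)
    catalog = Catalog()
    for part in parts.values():
        catalog.add_part(part)

    def spec(device_id: str, category: str, embed=(), plant=False, length=None):
        return FixtureSpec(
            seed,
            device_id,
            category,
            payload_length=length or payload_length,
            parts_to_embed=tuple(parts[p] for p in embed),
            plant_internal_ecorv=plant,
        )

    recipes = [
        spec("repA7120", CYANO_REPLICON, ["repSyn1"], plant=True),
        spec("oriEc1", ECOLI_ORIGIN_PAIRED, ["oriVSyn1"]),
        spec("aadA1", ANTIBIOTIC_MARKER, ["aadASyn1"]),
        spec("exprGFP1", EXPRESSION_CASSETTE, ["pSyn1", "rbsSyn1", "gfpSyn1"]),
        spec("bhrRSF1", BHR_REPLICON, ["oriVSyn1"]),
        spec("oriKO1", ECOLI_ORIGIN_KNOCKOUT, ["oriVSyn1", "sacBSyn1"]),
        spec("ns1Syn", NEUTRAL_SITE),
    ]
    for recipe in recipes:
        device, donor = generate_device(recipe, parts["ampRSyn1"])
        catalog.add_device(device, donor)

    # the cloning cassette has a constructed (not random) payload
    payload_bases, annotations = cassette_payload(seed, parts["ccdBSyn1"])
    payload = NucleotideSequence(payload_bases, LINEAR)
    enzyme = choose_enzyme(payload)
    left_label, right_label = CATEGORY_FACE_LABELS[CLONING_CASSETTE]
    cassette = DeviceRecord(
        "ccdBcas1",
        CLONING_CASSETTE,
        payload,
        FACES[left_label].with_enzyme(enzyme),
        FACES[right_label].with_enzyme(enzyme),
        enzyme,
        annotations,
    )
    rng = random.Random(f"{seed}:ccdBcas1:backbone")
    backbone_spec = FixtureSpec(seed, "ccdBcas1", CLONING_CASSETTE)
    backbone, _ = _compose_backbone(rng, backbone_spec, parts["ampRSyn1"])
    catalog.add_device(cassette, embed_in_donor(cassette, backbone, "pDON-ccdBcas1"))
    return catalog


def generate_homology_arm(seed: int, name: str, length: int = 300) -> NucleotideSequence:
    """A synthetic chromosomal homology arm for knockout planning."""
    rng = random.Random(f"{seed}:homology:{name}")
    for _ in range(DEFAULT_MAX_RETRIES):
        seq = _random_bases(rng, length, 0.5)
        if _clean(seq):
            return NucleotideSequence(seq, LINEAR)
    raise FixtureError(f"could not generate homology arm {name!r}")
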