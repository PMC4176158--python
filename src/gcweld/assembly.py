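"""Vector grammars, fragment release and overlap-directed assembly.

The assembly model: devices are released from their circular donors by blunt
digestion (EcoRV or ZraI), every released fragment exposes a 21-nt GC-adaptor
at each end, and adjacent fragments share an identical terminal 21-mer that
guides their joining in the isothermal (Gibson-style) reaction.  Fragment
order and orientation around the final circle are therefore dictated entirely
by the adaptor classes — a vector-type grammar — not by the order in which
the user lists devices.

When a ZraI-released end meets an EcoRV-released end the two 21-mers differ
at exactly one half-site position (position 1 or 21 of the overlap, a G/A or
C/T pair on the top strand); the reaction tolerates it.  In the assembled
output the mismatched position is normalized to the EcoRV dialect so the
product sequence does not depend on which enzyme released each fragment; the
heteroduplex ambiguity is retained in the junction report.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .adaptors import (
    FACES,
    AdaptorFace,
    face_pairing,
    junction_21mer,
    parse_flank,
)
from .catalog import (
    ANTIBIOTIC_MARKER,
    BHR_REPLICON,
    CUSTOM_PCR_FRAGMENT,
    CYANO_REPLICON,
    ECOLI_ORIGIN_KNOCKOUT,
    ECOLI_ORIGIN_PAIRED,
    FUNCTIONAL_CATEGORIES,
    NEUTRAL_SITE,
    Catalog,
    DeviceRecord,
    DonorPlasmid,
    PartAnnotation,
    choose_enzyme,
)
from .errors import (
    AdaptorIncompatibilityError,
    AmbiguousAssemblyError,
    AssemblyError,
    CategoryMismatchError,
    LowJunctionTmError,
    MissingSlotError,
    NoCassetteError,
    OpenAssemblyError,
    PlanError,
    PrimerDesignError,
    ReleaseError,
    TailMismatchError,
)
from .io_formats import AnnotatedFeature, PlasmidRecord
from .seq_core import (
    CIRCULAR,
    ENZYMES,
    LINEAR,
    MeltingParams,
    NucleotideSequence,
    SeqLike,
    as_sequence,
    blunt_digest,
    cut_linear,
    least_rotation_offset,
    revcomp_str,
    scan_sites,
    wallace_tm,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 15
DEFAULT_MAX_MISMATCH = 1

#: The two printed cloning-cassette adaptors (25 nt, ending in the ATTT half
#: of a SwaI site).  Inserts destined for a SwaI-opened backbone carry the
#: first as their 5' tail and the reverse complement of the second as their
#: 3' tail.
CASSETTE_ADAPTORS = (
    "TAGTCGGCCAATAACCCAGGGATTT",
    "CTCCTGCCGGGGAGCTCCTTCATTT",
)


# ---------------------------------------------------------------------------
# Vector-type grammars
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Slot:
    """One position in a vector-type template."""

    name: str
    categories: frozenset[str] | None  # None for custom PCR fragment slots
    custom: bool = False


@dataclass(frozen=True)
class VectorTypeTemplate:
    name: str
    slots: tuple[Slot, ...]

    @property
    def device_slot_count(self) -> int:
        return sum(1 for s in self.slots if not s.custom)

    @property
    def custom_slot_count(self) -> int:
        return sum(1 for s in self.slots if s.custom)


def _slot(name: str, *cats: str) -> Slot:
    return Slot(name, frozenset(cats))


def _custom(name: str) -> Slot:
    return Slot(name, None, custom=True)


#: The four vector-type grammars.  Slot order is the fixed order around the
#: circle implied by the adaptor classes; the cycle closes from the last slot
#: back to the first.
TEMPLATES: dict[str, VectorTypeTemplate] = {
    t.name: t
    for t in (
        VectorTypeTemplate(
            "self_replicating_strain_specific",
            (
                _slot("cyanobacterial_replicon", CYANO_REPLICON),
                _slot("ecoli_origin", ECOLI_ORIGIN_PAIRED),
                _slot("antibiotic_marker", ANTIBIOTIC_MARKER),
                _slot("functional_module", *FUNCTIONAL_CATEGORIES),
            ),
        ),
        VectorTypeTemplate(
            "broad_host_range",
            (
                _slot("bhr_replicon", BHR_REPLICON),
                _slot("antibiotic_marker", ANTIBIOTIC_MARKER),
                _slot("functional_module", *FUNCTIONAL_CATEGORIES),
            ),
        ),
        VectorTypeTemplate(
            "neutral_site_integration",
            (
                _slot("neutral_site", NEUTRAL_SITE),
                _slot("antibiotic_marker", ANTIBIOTIC_MARKER),
                _slot("functional_module", *FUNCTIONAL_CATEGORIES),
            ),
        ),
        VectorTypeTemplate(
            "knockout",
            (
                _slot("backbone", ECOLI_ORIGIN_KNOCKOUT),
                _custom("upstream_homology"),
                _slot("antibiotic_marker", ANTIBIOTIC_MARKER),
                _custom("downstream_homology"),
            ),
        ),
    )
}


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CustomFragmentSpec:
    """An adaptor-tailed PCR fragment supplied by the user (not from a donor)."""

    id: str
    amplicon: NucleotideSequence
    left_face: AdaptorFace
    right_face: AdaptorFace


@dataclass(frozen=True)
class PlannedSlot:
    slot_name: str
    kind: str  # "device" | "custom"
    left_face: AdaptorFace
    right_face: AdaptorFace
    enzyme_name: str
    device_id: str | None = None
    custom: CustomFragmentSpec | None = None

    @property
    def label(self) -> str:
        return self.device_id if self.kind == "device" else self.custom.id


@dataclass(frozen=True)
class AssemblyPlan:
    id: str
    vector_type: str
    slots: tuple[PlannedSlot, ...]

    def to_json(self) -> dict:
        out: dict = {"id": self.id, "vector_type": self.vector_type, "slots": []}
        for slot in self.slots:
            entry: dict = {
                "slot": slot.slot_name,
                "kind": slot.kind,
                "enzyme": slot.enzyme_name,
                "left_flank": slot.left_face.flank_string,
                "right_flank": slot.right_face.flank_string,
            }
            if slot.kind == "device":
                entry["device_id"] = slot.device_id
            else:
                entry["custom_id"] = slot.custom.id
                entry["amplicon"] = slot.custom.amplicon.bases
            out["slots"].append(entry)
        return out


def plan_from_json(data: Mapping) -> AssemblyPlan:
    slots = []
    for entry in data["slots"]:
        left = parse_flank(entry["left_flank"])
        right = parse_flank(entry["right_flank"])
        if entry["kind"] == "device":
            slots.append(
                PlannedSlot(
                    entry["slot"], "device", left, right, entry["enzyme"],
                    device_id=entry["device_id"],
                )
            )
        else:
            slots.append(
                PlannedSlot(
                    entry["slot"], "custom", left, right, entry["enzyme"],
                    custom=CustomFragmentSpec(
                        entry["custom_id"],
                        NucleotideSequence(entry["amplicon"], LINEAR),
                        left,
                        right,
                    ),
                )
            )
    return AssemblyPlan(data["id"], data["vector_type"], tuple(slots))


def plan_vector(
    vector_type: str,
    devices: Iterable[DeviceRecord],
    custom_fragments: Sequence[CustomFragmentSpec] = (),
    plan_id: str | None = None,
) -> AssemblyPlan:
    """Fill a vector-type grammar with the chosen devices.

    Devices are matched to slots by category (the grammar orders them, not the
    input order); custom fragments are consumed in slot order.  The plan is
    rejected if a slot is unfilled, a device fits no slot, or any cyclically
    adjacent pair of faces fails adaptor pairing.
    """
    try:
        template = TEMPLATES[vector_type]
    except KeyError:
        raise PlanError(
            f"unknown vector type {vector_type!r}; known: {sorted(TEMPLATES)}"
        ) from None
    pool = list(devices)
    customs = list(custom_fragments)
    planned: list[PlannedSlot] = []
    for slot in template.slots:
        if slot.custom:
            if not customs:
                raise MissingSlotError(
                    f"missing custom PCR fragment for slot {slot.name!r}"
                )
            spec = customs.pop(0)
            planned.append(
                PlannedSlot(
                    slot.name,
                    "custom",
                    spec.left_face,
                    spec.right_face,
                    spec.left_face.release_enzyme.name,
                    custom=spec,
                )
            )
            continue
        matches = [d for d in pool if d.category in slot.categories]
        if not matches:
            raise MissingSlotError(
                f"no chosen device fills slot {slot.name!r} "
                f"(accepts {sorted(slot.categories)})"
            )
        if len(matches) > 1:
            raise CategoryMismatchError(
                f"slot {slot.name!r} is ambiguous: "
                + ", ".join(d.id for d in matches)
            )
        device = matches[0]
        pool.remove(device)
        planned.append(
            PlannedSlot(
                slot.name,
                "device",
                device.left_face,
                device.right_face,
                device.release_enzyme.name,
                device_id=device.id,
            )
        )
    if pool:
        raise CategoryMismatchError(
            "devices fit no slot of this vector type: "
            + ", ".join(f"{d.id} ({d.category})" for d in pool)
        )
    for i, cur in enumerate(planned):
        nxt = planned[(i + 1) % len(planned)]
        if not face_pairing(nxt.left_face, cur.right_face):
            raise AdaptorIncompatibilityError(
                f"adaptor mismatch between {cur.slot_name!r} "
                f"(right: {cur.right_face.adaptor_class.name}) and "
                f"{nxt.slot_name!r} (left: {nxt.left_face.adaptor_class.name})"
            )
    return AssemblyPlan(plan_id or f"{vector_type}-plan", vector_type, tuple(planned))


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentEnd:
    """One terminus of an assembly-ready fragment.

    ``overlap`` is the annealing sequence on the fragment's top strand (21 nt
    for adaptor ends; 15–30 nt for custom/cassette ends), ``provenance`` the
    enzyme that produced the end (or "PCR"), ``adaptor_class`` the class name
    for adaptor ends, ``None`` for free-form ends.
    """

    overlap: str
    provenance: str
    adaptor_class: str | None = None


@dataclass(frozen=True)
class AssemblyFragment:
    id: str
    seq: NucleotideSequence
    left_end: FragmentEnd
    right_end: FragmentEnd
    parts: tuple[PartAnnotation, ...] = ()  # fragment-relative coordinates

    def __len__(self) -> int:
        return len(self.seq)

    def flipped(self) -> "AssemblyFragment":
        n = len(self.seq)
        return AssemblyFragment(
            self.id,
            self.seq.reverse_complement(),
            FragmentEnd(
                revcomp_str(self.right_end.overlap),
                self.right_end.provenance,
                self.right_end.adaptor_class,
            ),
            FragmentEnd(
                revcomp_str(self.left_end.overlap),
                self.left_end.provenance,
                self.left_end.adaptor_class,
            ),
            tuple(
                PartAnnotation(
                    a.part_id, n - a.end, n - a.start, "-" if a.strand == "+" else "+"
                )
                for a in self.parts
            ),
        )


def _device_fragment(device: DeviceRecord, donor: DonorPlasmid) -> AssemblyFragment:
    enzyme = device.release_enzyme
    frags = blunt_digest(donor.sequence, enzyme)
    expected = device.released_sequence.bases
    carriers = [f for f in frags if device.payload.bases in f.seq.bases]
    if not carriers:
        positions = scan_sites(donor.sequence, enzyme)
        raise ReleaseError(
            f"donor {donor.id!r}: payload of device {device.id!r} is cut by "
            f"{enzyme.name} (sites at {positions}); no intact device fragment"
        )
    if len(carriers) > 1:
        raise ReleaseError(
            f"donor {donor.id!r}: device fragment for {device.id!r} is not unique"
        )
    released = carriers[0]
    if released.seq.bases != expected:
        raise ReleaseError(
            f"donor {donor.id!r}: released fragment does not match the flanked "
            f"device {device.id!r} (unexpected {enzyme.name} site near a flank)"
        )
    left21, right21 = device.terminal_21mers()
    return AssemblyFragment(
        device.id,
        released.seq,
        FragmentEnd(left21, enzyme.name, device.left_face.adaptor_class.name),
        FragmentEnd(right21, enzyme.name, device.right_face.adaptor_class.name),
        tuple(
            PartAnnotation(a.part_id, a.start + 27, a.end + 27, a.strand)
            for a in device.parts
        ),
    )


def _custom_fragment(spec: CustomFragmentSpec) -> AssemblyFragment:
    """Trim an adaptor-tailed amplicon to its assembly-ready form.

    The tails carry full 30-nt flanks whose outer release sites are cut away
    (in the wet protocol the outer bases are removed by the reaction's
    5'-exonuclease chew-back and polymerase proofreading; in silico we digest
    with the tail enzymes), leaving standard 21-mer adaptor ends.
    """
    enzymes = {spec.left_face.release_enzyme.name, spec.right_face.release_enzyme.name}
    pieces = cut_linear(spec.amplicon, [ENZYMES[n] for n in enzymes])
    internal = [p for p in pieces if p.left_enzyme and p.right_enzyme]
    if len(internal) != 1:
        raise ReleaseError(
            f"custom fragment {spec.id!r}: expected the two tail release sites "
            f"to excise one central fragment, got {len(internal)}"
        )
    trimmed = internal[0]
    left_expect = junction_21mer(spec.left_face, spec.left_face.release_enzyme).bases
    right_expect = revcomp_str(
        junction_21mer(spec.right_face, spec.right_face.release_enzyme).bases
    )
    if not trimmed.seq.bases.startswith(left_expect) or not trimmed.seq.bases.endswith(
        right_expect
    ):
        raise TailMismatchError(
            f"custom fragment {spec.id!r}: trimmed ends do not carry the "
            "expected adaptor 21-mers"
        )
    return AssemblyFragment(
        spec.id,
        trimmed.seq,
        FragmentEnd(left_expect, trimmed.left_enzyme, spec.left_face.adaptor_class.name),
        FragmentEnd(right_expect, trimmed.right_enzyme, spec.right_face.adaptor_class.name),
    )


def release_fragments(
    plan: AssemblyPlan, donors: Catalog | Mapping[str, DonorPlasmid]
) -> list[AssemblyFragment]:
    """Release every planned fragment, in plan slot order.

    ``donors`` is a catalog (devices found via their donor plasmids) or a
    mapping ``device_id -> DonorPlasmid``.  Backbone fragments are discarded;
    stray cutter sites in a donor backbone are tolerated as long as the device
    fragment itself is released intact and uniquely.
    """
    if isinstance(donors, Catalog):
        catalog = donors

        def lookup(device_id: str) -> tuple[DeviceRecord, DonorPlasmid]:
            if device_id not in catalog.devices:
                raise ReleaseError(f"device {device_id!r} not in catalog")
            return catalog.devices[device_id], catalog.donor_for_device(device_id)

    else:
        raise TypeError("donors must be a Catalog")

    fragments = []
    for slot in plan.slots:
        if slot.kind == "device":
            device, donor = lookup(slot.device_id)
            fragments.append(_device_fragment(device, donor))
        else:
            fragments.append(_custom_fragment(slot.custom))
    return fragments


# ---------------------------------------------------------------------------
# Junction graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionReport:
    upstream_fragment: str
    downstream_fragment: str
    adaptor_class: str  # class name, or "custom"
    overlap_length: int
    mismatch_count: int
    mismatch_positions: tuple[int, ...]  # 1-based within the overlap
    wallace_tm_C: int
    overlap: str  # normalized overlap as written into the product
    position: int | None = None  # 1-based start on the assembled circle


@dataclass(frozen=True)
class JunctionEdge:
    up_index: int
    up_flipped: bool
    down_index: int
    down_flipped: bool
    report: JunctionReport


@dataclass(frozen=True)
class AssemblyGraph:
    fragments: tuple[AssemblyFragment, ...]
    edges: tuple[JunctionEdge, ...]
    max_mismatch: int
    min_overlap: int


def _normalize_overlap(up: str, down: str) -> tuple[str, list[int]]:
    """Overlap as written into the product, plus 1-based mismatch positions.

    Mismatched half-site positions (G/A or C/T on the top strand) resolve to
    the EcoRV-dialect base (A and T respectively)."""
    out = []
    mismatches = []
    for k, (a, b) in enumerate(zip(up, down), start=1):
        if a == b:
            out.append(a)
            continue
        pair = {a, b}
        if pair == {"A", "G"}:
            out.append("A")
        elif pair == {"C", "T"}:
            out.append("T")
        else:
            raise AssemblyError(
                f"unresolvable overlap mismatch {a}/{b} at position {k}"
            )
        mismatches.append(k)
    return "".join(out), mismatches


def _match_ends(
    up: FragmentEnd, down: FragmentEnd, max_mismatch: int, min_overlap: int
) -> JunctionReport | None:
    a, b = up.overlap, down.overlap
    if len(a) != len(b) or len(a) < min_overlap:
        return None
    adaptor = up.adaptor_class is not None and down.adaptor_class is not None
    allowed = max_mismatch if adaptor else 0
    mismatches = [k for k in range(len(a)) if a[k] != b[k]]
    if len(mismatches) > allowed:
        return None
    try:
        overlap, positions = _normalize_overlap(a, b)
    except AssemblyError:
        return None
    cls = (
        up.adaptor_class
        if adaptor and up.adaptor_class == down.adaptor_class
        else "custom"
    )
    return JunctionReport(
        upstream_fragment="",
        downstream_fragment="",
        adaptor_class=cls,
        overlap_length=len(a),
        mismatch_count=len(positions),
        mismatch_positions=tuple(positions),
        wallace_tm_C=wallace_tm(overlap),
        overlap=overlap,
    )


def _oriented(frag: AssemblyFragment, flipped: bool) -> AssemblyFragment:
    return frag.flipped() if flipped else frag


def find_junctions(
    fragments: Sequence[AssemblyFragment],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> AssemblyGraph:
    """All pairwise end compatibilities, both fragment orientations included.

    An edge joins an (oriented) fragment's right end to another (oriented)
    fragment's left end when the two overlaps align with at most
    ``max_mismatch`` mismatches over at least ``min_overlap`` positions;
    free-form (custom) overlaps must match exactly.
    """
    if len(fragments) < 2:
        raise AssemblyError("junction finding requires at least 2 fragments")
    edges = []
    for i, j in itertools.permutations(range(len(fragments)), 2):
        for fi, fj in itertools.product((False, True), repeat=2):
            up = _oriented(fragments[i], fi)
            down = _oriented(fragments[j], fj)
            report = _match_ends(
                up.right_end, down.left_end, max_mismatch, min_overlap
            )
            if report is not None:
                edges.append(
                    JunctionEdge(
                        i,
                        fi,
                        j,
                        fj,
                        replace(
                            report,
                            upstream_fragment=up.id,
                            downstream_fragment=down.id,
                        ),
                    )
                )
    return AssemblyGraph(tuple(fragments), tuple(edges), max_mismatch, min_overlap)


# ---------------------------------------------------------------------------
# Circle assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssembledPlasmid:
    sequence: NucleotideSequence  # circular, canonical rotation
    junctions: tuple[JunctionReport, ...]
    features: tuple[AnnotatedFeature, ...]
    provenance: dict

    def as_record(self, name: str = "assembly") -> PlasmidRecord:
        return PlasmidRecord(name, self.sequence, list(self.features))


def _hamiltonian_cycles(graph: AssemblyGraph) -> list[list[tuple[int, bool]]]:
    """All Hamiltonian cycles over the fragments, one orientation per
    fragment, de-duplicated over rotation and global strand flip by anchoring
    fragment 0 in forward orientation."""
    n = len(graph.fragments)
    adj: dict[tuple[int, bool], list[tuple[int, bool]]] = {}
    for e in graph.edges:
        adj.setdefault((e.up_index, e.up_flipped), []).append((e.down_index, e.down_flipped))
    cycles = []

    def extend(path: list[tuple[int, bool]], used: set[int]) -> None:
        if len(path) == n:
            if (0, False) in adj.get(path[-1], []):
                cycles.append(list(path))
            return
        for nxt in adj.get(path[-1], []):
            if nxt[0] not in used:
                path.append(nxt)
                used.add(nxt[0])
                extend(path, used)
                used.remove(nxt[0])
                path.pop()

    extend([(0, False)], {0})
    return cycles


def _edge_lookup(graph: AssemblyGraph) -> dict:
    return {
        (e.up_index, e.up_flipped, e.down_index, e.down_flipped): e.report
        for e in graph.edges
    }


def _unpaired_ends(graph: AssemblyGraph) -> list[str]:
    out = []
    has_out = {(e.up_index, e.up_flipped) for e in graph.edges}
    has_in = {(e.down_index, e.down_flipped) for e in graph.edges}
    for i, frag in enumerate(graph.fragments):
        # the physical right end joins downstream when forward, or is joined
        # from upstream when the fragment is flipped (and vice versa)
        if (i, False) not in has_out and (i, True) not in has_in:
            out.append(f"{frag.id}.right ({frag.right_end.adaptor_class or 'custom'})")
        if (i, False) not in has_in and (i, True) not in has_out:
            out.append(f"{frag.id}.left ({frag.left_end.adaptor_class or 'custom'})")
    return out


def assemble_circle(
    source: AssemblyGraph | Sequence[AssemblyFragment],
    plan: AssemblyPlan | None = None,
    params: MeltingParams = MeltingParams(),
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> AssembledPlasmid:
    """Join the fragments into the unique circle their overlaps dictate.

    Succeeds iff the junction graph admits exactly one Hamiltonian cycle over
    all fragments (up to rotation and strand choice).  Each overlap is written
    once, mismatched half-site positions normalized to the EcoRV dialect; the
    output is canonicalized to the lexicographically minimal rotation of the
    strand on which the first fragment reads forward.  Every junction must
    melt above ``params.threshold_C``.
    """
    graph = (
        source
        if isinstance(source, AssemblyGraph)
        else find_junctions(source, max_mismatch, min_overlap)
    )
    cycles = _hamiltonian_cycles(graph)
    if not cycles:
        unpaired = _unpaired_ends(graph)
        raise OpenAssemblyError(
            "fragments do not close into a circle; unpaired ends: "
            + (", ".join(unpaired) if unpaired else "(all ends have partners, "
               "but no ordering closes)")
        )
    if len(cycles) > 1:
        orders = [
            " -> ".join(
                graph.fragments[i].id + ("(rc)" if f else "") for i, f in cycle
            )
            for cycle in cycles
        ]
        raise AmbiguousAssemblyError(
            "multiple distinct circular assemblies are possible: "
            + " | ".join(orders)
        )
    cycle = cycles[0]
    for i, f in cycle:
        if f:
            logger.info(
                "fragment %s supplied in flipped orientation; auto-reverse-complemented",
                graph.fragments[i].id,
            )
    lookup = _edge_lookup(graph)
    oriented = [_oriented(graph.fragments[i], f) for i, f in cycle]
    n = len(oriented)
    pieces = []
    features0: list[tuple[str, int, int, str]] = []  # part_id, gstart, gend, strand
    junctions0: list[tuple[JunctionReport, int]] = []
    cursor = 0
    for k, frag in enumerate(oriented):
        prev = cycle[(k - 1) % n]
        cur = cycle[k]
        report = lookup[(prev[0], prev[1], cur[0], cur[1])]
        l_len = len(frag.left_end.overlap)
        r_len = len(frag.right_end.overlap)
        piece = report.overlap + frag.seq.bases[l_len : len(frag.seq) - r_len]
        junctions0.append((report, cursor))
        for a in frag.parts:
            if a.end <= len(frag.seq) - r_len:
                features0.append((a.part_id, cursor + a.start, cursor + a.end, a.strand))
        pieces.append(piece)
        cursor += len(piece)
    sequence = "".join(pieces)
    total = len(sequence)
    if plan is not None:
        expected = sum(len(f.seq) for f in oriented) - sum(
            r.overlap_length for r, _ in junctions0
        )
        assert total == expected
    offset = least_rotation_offset(sequence)
    canonical = sequence[offset:] + sequence[:offset]
    junctions = []
    for report, pos in junctions0:
        if report.wallace_tm_C < params.threshold_C:
            raise LowJunctionTmError(
                f"junction {report.upstream_fragment}->{report.downstream_fragment} "
                f"melts at {report.wallace_tm_C} C, below the "
                f"{params.threshold_C} C assembly threshold"
            )
        junctions.append(replace(report, position=(pos - offset) % total + 1))
    features = []
    for part_id, gstart, gend, strand in features0:
        s0 = (gstart - offset) % total
        e0 = s0 + (gend - gstart)
        features.append(
            AnnotatedFeature(
                part_id,
                s0 + 1,
                e0 if e0 <= total else e0 - total,
                strand,
                label=part_id,
            )
        )
    features.sort(key=lambda f: (f.start, f.part_id or ""))
    junctions.sort(key=lambda j: j.position)
    return AssembledPlasmid(
        NucleotideSequence(canonical, CIRCULAR),
        tuple(junctions),
        tuple(features),
        {
            "plan_id": plan.id if plan else None,
            "fragments": [f.id for f in oriented],
        },
    )


def assemble_plan(
    plan: AssemblyPlan,
    catalog: Catalog,
    params: MeltingParams = MeltingParams(),
) -> AssembledPlasmid:
    """Release the planned fragments from the catalog and assemble them."""
    fragments = release_fragments(plan, catalog)
    return assemble_circle(fragments, plan=plan, params=params)


# ---------------------------------------------------------------------------
# Cloning-cassette insertion
# ---------------------------------------------------------------------------


def insert_into_cloning_cassette(
    vector: AssembledPlasmid | PlasmidRecord | NucleotideSequence,
    insert: SeqLike,
    params: MeltingParams = MeltingParams(),
    min_tail: int = DEFAULT_MIN_OVERLAP,
) -> AssembledPlasmid:
    """Replace a SwaI/ccdB cloning cassette's stuffer with a tailed insert.

    The vector must carry exactly two SwaI sites bracketing the ccdB stuffer;
    the insert's termini must exactly match the backbone's post-digestion
    terminal adaptors (the printed 25-nt cassette adaptors).  The stuffer —
    and with it the ccdB part — is discarded; the two new junctions require
    exact overlaps.
    """
    if isinstance(vector, AssembledPlasmid):
        seq, vec_features = vector.sequence, vector.features
    elif isinstance(vector, PlasmidRecord):
        seq, vec_features = vector.sequence, tuple(vector.features)
    else:
        seq, vec_features = as_sequence(vector, CIRCULAR), ()
    if not seq.is_circular:
        raise NoCassetteError("cassette insertion requires a circular vector")
    swai = ENZYMES["SwaI"]
    sites = scan_sites(seq, swai)
    if len(sites) != 2:
        raise NoCassetteError(
            f"expected exactly 2 SwaI sites bracketing the cassette, found {len(sites)}"
        )
    frags = blunt_digest(seq, swai)
    ins = as_sequence(insert)
    n_vec = len(seq)

    def tail_overlap(frag_bases: str) -> tuple[int, int] | None:
        k_left = next(
            (
                k
                for k in range(min(30, len(ins), len(frag_bases)), min_tail - 1, -1)
                if ins.bases[:k] == frag_bases[-k:]
            ),
            0,
        )
        k_right = next(
            (
                k
                for k in range(min(30, len(ins), len(frag_bases)), min_tail - 1, -1)
                if ins.bases[-k:] == frag_bases[:k]
            ),
            0,
        )
        if k_left and k_right:
            return k_left, k_right
        return None

    matches = [(f, tail_overlap(f.seq.bases)) for f in frags]
    matches = [(f, m) for f, m in matches if m is not None]
    if not matches:
        raise TailMismatchError(
            "insert tails do not match the SwaI-opened backbone ends"
        )
    if len(matches) > 1:
        raise AmbiguousAssemblyError("both SwaI fragments match the insert tails")
    backbone, (k_left, k_right) = matches[0]
    stuffer = next(f for f in frags if f is not backbone)
    sequence = backbone.seq.bases + ins.bases[k_left : len(ins) - k_right]
    total = len(sequence)
    junctions0 = [
        (
            JunctionReport(
                "backbone",
                "insert",
                "custom",
                k_left,
                0,
                (),
                wallace_tm(ins.bases[:k_left]),
                ins.bases[:k_left],
            ),
            len(backbone.seq) - k_left,
        ),
        (
            JunctionReport(
                "insert",
                "backbone",
                "custom",
                k_right,
                0,
                (),
                wallace_tm(ins.bases[-k_right:]),
                ins.bases[-k_right:],
            ),
            total - k_right,
        ),
    ]
    # lift vector features that lie fully on the retained backbone fragment
    features0 = []
    o = backbone.origin_offset
    m = len(backbone.seq)
    for feat in vec_features:
        start0 = feat.start - 1
        length = feat.length_on(n_vec)
        local = (start0 - o) % n_vec
        if local + length <= m:
            features0.append((feat.part_id, local, local + length, feat.strand, feat.label))
    offset = least_rotation_offset(sequence)
    canonical = sequence[offset:] + sequence[:offset]
    junctions = []
    for report, pos in junctions0:
        if report.wallace_tm_C < params.threshold_C:
            raise LowJunctionTmError(
                f"cassette junction melts at {report.wallace_tm_C} C, below "
                f"{params.threshold_C} C"
            )
        junctions.append(replace(report, position=(pos - offset) % total + 1))
    features = []
    for part_id, gstart, gend, strand, label in features0:
        s0 = (gstart - offset) % total
        e0 = s0 + (gend - gstart)
        features.append(
            AnnotatedFeature(
                part_id, s0 + 1, e0 if e0 <= total else e0 - total, strand, label
            )
        )
    features.sort(key=lambda f: (f.start, f.part_id or ""))
    junctions.sort(key=lambda j: j.position)
    return AssembledPlasmid(
        NucleotideSequence(canonical, CIRCULAR),
        tuple(junctions),
        tuple(features),
        {"plan_id": None, "fragments": ["backbone", "insert"],
         "stuffer_length": len(stuffer.seq)},
    )


# ---------------------------------------------------------------------------
# Tailed primers & knockout planning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TailedPrimer:
    tail: str
    target: str

    @property
    def full(self) -> str:
        return self.tail + self.target

    def __len__(self) -> int:
        return len(self.full)


@dataclass(frozen=True)
class TailedPrimerPair:
    forward: TailedPrimer
    reverse: TailedPrimer


def design_tailed_primers(
    target_specific_fwd: SeqLike,
    target_specific_rev: SeqLike,
    left_face: AdaptorFace,
    right_face: AdaptorFace,
) -> TailedPrimerPair:
    """Prepend adaptor flanks to a target-specific primer pair.

    The forward primer gets the left flank verbatim; the reverse primer gets
    the right flank verbatim, which — because right flanks are stored on the
    bottom strand — places the flank's reverse complement at the amplicon's
    right terminus, release site distal.
    """
    for primer in (target_specific_fwd, target_specific_rev):
        if not str(primer):
            raise PrimerDesignError("target-specific primers must be non-empty")
    fwd = as_sequence(target_specific_fwd)
    rev = as_sequence(target_specific_rev)
    return TailedPrimerPair(
        TailedPrimer(left_face.flank_string, fwd.bases),
        TailedPrimer(right_face.flank_string, rev.bases),
    )


def simulate_amplicon(pair: TailedPrimerPair, template: SeqLike) -> NucleotideSequence:
    """Naive PCR: exact priming sites, tails appended at both 5' ends."""
    tpl = as_sequence(template).bases
    i = tpl.find(pair.forward.target)
    if i == -1:
        raise PrimerDesignError("forward primer does not anneal to the template")
    rev_site = revcomp_str(pair.reverse.target)
    j = tpl.find(rev_site, i)
    if j == -1:
        raise PrimerDesignError(
            "reverse primer does not anneal downstream of the forward primer"
        )
    core = tpl[i : j + len(rev_site)]
    return NucleotideSequence(
        pair.forward.tail + core + revcomp_str(pair.reverse.tail), LINEAR
    )


@dataclass(frozen=True)
class KnockoutDesign:
    plan: AssemblyPlan
    primers: dict[str, TailedPrimerPair]
    custom_fragments: tuple[CustomFragmentSpec, ...]


#: Face labels for the two homology arms of a knockout vector, inferred from
#: the flank-class table: the arms bridge backbone(G5C5|C3G3) -> marker(GC|C2G)
#: -> backbone, so the upstream arm is C3G3|GC and the downstream arm C2G|G5C5.
KNOCKOUT_ARM_FACES = {
    "upstream_homology": ("C3G3-MfeI", "NheI-GC"),
    "downstream_homology": ("C2G-AgeI", "XbaI-G5C5"),
}

PRIMER_CORE_LENGTH = 20


def plan_knockout(
    upstream_homology: SeqLike,
    downstream_homology: SeqLike,
    marker: DeviceRecord,
    backbone: DeviceRecord,
    min_homology: int = 100,
    plan_id: str | None = None,
) -> KnockoutDesign:
    """Plan a suicide (knockout) vector: backbone + marker + two homology arms.

    The marker is flanked by the two custom PCR fragments carrying homology to
    the target locus; tailed primers for both arms are emitted.  Each arm's
    release enzyme is chosen by the standard payload rule.
    """
    if marker.category != ANTIBIOTIC_MARKER:
        raise CategoryMismatchError(
            f"marker slot requires an antibiotic_marker device, got {marker.category}"
        )
    if backbone.category != ECOLI_ORIGIN_KNOCKOUT:
        raise CategoryMismatchError(
            f"backbone slot requires an ecoli_origin_knockout device, got "
            f"{backbone.category}"
        )
    arms = {
        "upstream_homology": as_sequence(upstream_homology),
        "downstream_homology": as_sequence(downstream_homology),
    }
    customs = []
    primers = {}
    for name, hom in arms.items():
        if len(hom) < min_homology:
            raise PlanError(
                f"{name} is {len(hom)} nt; at least {min_homology} nt of homology "
                "is required for recombination"
            )
        enzyme = choose_enzyme(hom)
        left_label, right_label = KNOCKOUT_ARM_FACES[name]
        left = FACES[left_label].with_enzyme(enzyme)
        right = FACES[right_label].with_enzyme(enzyme)
        pair = design_tailed_primers(
            hom.bases[:PRIMER_CORE_LENGTH],
            revcomp_str(hom.bases[-PRIMER_CORE_LENGTH:]),
            left,
            right,
        )
        amplicon = NucleotideSequence(
            left.flank_string + hom.bases + revcomp_str(right.flank_string), LINEAR
        )
        customs.append(CustomFragmentSpec(name, amplicon, left, right))
        primers[name] = pair
    plan = plan_vector("knockout", [backbone, marker], customs, plan_id)
    return KnockoutDesign(plan, primers, tuple(customs))
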