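"""GenBank/FASTA read-write, parts-database annotation, protocol generation.

The on-disk interchange format for plasmids and devices is the GenBank flat
file: circular topology is flagged on the LOCUS line, features are emitted as
``misc_feature`` entries (1-based inclusive coordinates, origin-spanning
features written with the ``join(a..N,1..b)`` convention) and round-trips are
lossless for sequence, topology and features.  The module also renders the
bench protocol for an assembly plan: donors pooled by release enzyme, the
digestion constants (5 U enzyme per µg plasmid, 3–5 h, reaction volume at
least 50× the enzyme volume), cleanup, and the isothermal-assembly step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import GCWeldError, ProtocolError, SequenceAlphabetError
from .seq_core import (
    CIRCULAR,
    LINEAR,
    NucleotideSequence,
    SeqLike,
    as_sequence,
    revcomp_str,
)

#: Digestion constants used by every generated protocol.
DIGEST_UNITS_PER_UG = 5
DIGEST_HOURS = (3, 5)
MIN_VOLUME_MULTIPLE = 50

#: Fixed LOCUS date so identical inputs give byte-identical GenBank output.
_GENBANK_DATE = "01-JAN-1980"


@dataclass(frozen=True)
class AnnotatedFeature:
    """A feature on a plasmid, GenBank-style 1-based inclusive coordinates.

    ``start > end`` marks a feature spanning the origin of a circular
    sequence; it is serialized as ``join(start..N,1..end)``.
    """

    part_id: str | None
    start: int
    end: int
    strand: str = "+"
    label: str | None = None
    feature_type: str = "misc_feature"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GCWeldError(f"feature strand must be +/-, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise GCWeldError("feature coordinates are 1-based and positive")

    @property
    def spans_origin(self) -> bool:
        return self.start > self.end

    def length_on(self, plasmid_length: int) -> int:
        if not self.spans_origin:
            return self.end - self.start + 1
        return plasmid_length - self.start + 1 + self.end


@dataclass
class PlasmidRecord:
    """A named sequence with features — the unit of GenBank I/O."""

    name: str
    sequence: NucleotideSequence
    features: list[AnnotatedFeature] = field(default_factory=list)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------


def _to_seqrecord(record: PlasmidRecord):
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    n = len(record.sequence)
    rec = SeqRecord(
        Seq(record.sequence.bases),
        id=record.name[:16] or "plasmid",
        name=record.name[:16] or "plasmid",
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.sequence.is_circular else "linear",
            "data_file_division": "SYN",
            "date": _GENBANK_DATE,
        },
    )
    for feat in record.features:
        strand = -1 if feat.strand == "-" else 1
        if feat.spans_origin:
            location = CompoundLocation(
                [
                    SimpleLocation(feat.start - 1, n, strand),
                    SimpleLocation(0, feat.end, strand),
                ]
            )
        else:
            location = SimpleLocation(feat.start - 1, feat.end, strand)
        qualifiers: dict[str, list[str]] = {}
        if feat.label:
            qualifiers["label"] = [feat.label]
        if feat.part_id:
            qualifiers["part_id"] = [feat.part_id]
        rec.features.append(
            SeqFeature(location, type=feat.feature_type, qualifiers=qualifiers)
        )
    return rec


def write_genbank(record: PlasmidRecord, path: str | Path) -> Path:
    """Write a plasmid as a GenBank flat file (deterministic output)."""
    from Bio import SeqIO

    path = Path(path)
    with path.open("w") as handle:
        SeqIO.write([_to_seqrecord(record)], handle, "genbank")
    return path


def _from_seqrecord(rec) -> PlasmidRecord:
    bases = str(rec.seq).upper()
    if not bases or set(bases) - set("ACGT"):
        raise SequenceAlphabetError(
            f"record {rec.id!r}: sequence is empty or not plain DNA"
        )
    topology = rec.annotations.get("topology", "linear")
    seq = NucleotideSequence(bases, CIRCULAR if topology == "circular" else LINEAR)
    features = []
    for feat in rec.features:
        if feat.type == "source":
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        parts = getattr(feat.location, "parts", [feat.location])
        # origin-spanning join; biopython lists the parts in reverse order for
        # minus-strand compound locations
        if len(parts) == 2 and int(parts[0].end) == len(seq) and int(parts[1].start) == 0:
            start, end = int(parts[0].start) + 1, int(parts[1].end)
        elif len(parts) == 2 and int(parts[1].end) == len(seq) and int(parts[0].start) == 0:
            start, end = int(parts[1].start) + 1, int(parts[0].end)
        else:
            start, end = int(feat.location.start) + 1, int(feat.location.end)
        quals = feat.qualifiers
        label = (quals.get("label") or [None])[0]
        part_id = (quals.get("part_id") or [None])[0]
        features.append(
            AnnotatedFeature(part_id, start, end, strand, label, feat.type)
        )
    return PlasmidRecord(rec.name, seq, features)


def read_genbank(path: str | Path) -> PlasmidRecord:
    """Read a GenBank flat file written by this package (or compatible)."""
    from Bio import SeqIO

    return _from_seqrecord(SeqIO.read(str(path), "genbank"))


def write_fasta(record: PlasmidRecord, path: str | Path) -> Path:
    path = Path(path)
    lines = [f">{record.name}"]
    bases = record.sequence.bases
    lines += [bases[i : i + 70] for i in range(0, len(bases), 70)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_fasta_sequence(path: str | Path) -> NucleotideSequence:
    """First record of a FASTA file as a linear sequence."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return NucleotideSequence(str(rec.seq), LINEAR)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _occurrences(text: str, probe: str) -> Iterable[int]:
    pos = text.find(probe)
    while pos != -1:
        yield pos
        pos = text.find(probe, pos + 1)  # overlapping hits included


def annotate_with_parts(sequence: SeqLike, parts) -> list[AnnotatedFeature]:
    """Exact-match part annotation on both strands of a (circular) sequence.

    Every occurrence of every part is reported, including overlapping hits
    and multiple part ids sharing a sequence; occurrences spanning the origin
    of a circular molecule are found via sequence doubling.  Palindromic parts
    are reported once per locus, on the plus strand.
    """
    seq = as_sequence(sequence)
    n = len(seq)
    text = seq.bases + (seq.bases if seq.is_circular else "")
    hits: list[AnnotatedFeature] = []
    for part in parts:
        probe = part.sequence.bases
        if len(probe) > n:
            continue
        strands = [("+", probe)]
        rc = revcomp_str(probe)
        if rc != probe:
            strands.append(("-", rc))
        for strand, needle in strands:
            for pos in _occurrences(text, needle):
                if pos >= n:
                    break  # duplicates of wrap-around hits
                end = pos + len(needle)
                hits.append(
                    AnnotatedFeature(
                        part.id,
                        pos + 1,
                        end if end <= n else end - n,
                        strand,
                        label=part.name,
                    )
                )
    hits.sort(key=lambda f: (f.start, f.part_id or "", f.strand))
    return hits


# ---------------------------------------------------------------------------
# Protocol generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigestionPool:
    enzyme: str
    donors: tuple[str, ...]  # donor plasmid ids (or device ids when no donor known)


@dataclass(frozen=True)
class ProtocolDocument:
    plan_id: str
    vector_type: str
    pools: tuple[DigestionPool, ...]
    custom_inputs: tuple[str, ...]
    units_per_ug: int = DIGEST_UNITS_PER_UG
    hours: tuple[int, int] = DIGEST_HOURS
    min_volume_multiple: int = MIN_VOLUME_MULTIPLE

    def render(self) -> str:
        lines = [
            f"Bench protocol — plan {self.plan_id} ({self.vector_type})",
            "=" * 60,
        ]
        step = 1
        if self.custom_inputs:
            lines.append(f"Step {step}: PCR of custom fragments")
            for cid in self.custom_inputs:
                lines.append(
                    f"  - {cid}: amplify with the adaptor-tailed primer pair;"
                    " verify a single product of the expected size."
                )
            step += 1
        lines.append(f"Step {step}: Restriction digestion (donors pooled by enzyme)")
        for pool in self.pools:
            lines.append(f"  Pool [{pool.enzyme}]: " + ", ".join(pool.donors))
        lines.append(
            f"  Digest with {self.units_per_ug} U of enzyme per ug of plasmid DNA"
            f" for {self.hours[0]} to {self.hours[1]} h at 37 C, in a final volume"
            f" at least {self.min_volume_multiple} times greater than the volume"
            " of enzyme added."
        )
        lines.append(
            "  (Reaction volume and DNA mass are laboratory-adjustable"
            " placeholders; scale to the preparation at hand.)"
        )
        step += 1
        lines.append(f"Step {step}: Cleanup")
        lines.append(
            "  Clean the pooled digests (and PCR products, if any) of enzymes,"
            " salts and buffer components with a DNA clean-up/concentration kit."
        )
        step += 1
        lines.append(f"Step {step}: Isothermal assembly")
        lines.append(
            "  Combine the released fragments and assemble with Gibson"
            " isothermal assembly at 50 C; every designed junction melts above"
            " the reaction temperature."
        )
        return "\n".join(lines) + "\n"


def generate_protocol(plan, catalog=None) -> ProtocolDocument:
    """Render the bench protocol for an assembly plan.

    Donor plasmids are grouped into one digestion pool per release enzyme;
    custom PCR fragments are listed as PCR inputs.  When a catalog is given,
    donors are named by their donor-plasmid ids, otherwise by device ids.
    """
    slots = getattr(plan, "slots", None)
    if not slots:
        raise ProtocolError("cannot generate a protocol for an empty plan")
    pools: dict[str, list[str]] = {}
    custom: list[str] = []
    for slot in slots:
        if slot.kind == "device":
            name = slot.device_id
            if catalog is not None:
                try:
                    name = catalog.donor_for_device(slot.device_id).id
                except Exception:
                    pass
            pools.setdefault(slot.enzyme_name, []).append(name)
        else:
            custom.append(slot.custom.id)
    return ProtocolDocument(
        plan_id=plan.id,
        vector_type=plan.vector_type,
        pools=tuple(
            DigestionPool(enz, tuple(names)) for enz, names in sorted(pools.items())
        ),
        custom_inputs=tuple(custom),
    )
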