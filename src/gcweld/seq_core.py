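"""Exact nucleotide-sequence primitives.

This layer is pure sequence algebra: strict A/C/G/T strings with linear or
circular topology, recognition-site scanning that is aware of sites spanning
the origin of a circle, blunt-end digestion, melting-temperature estimates and
a single-strand hairpin screen.  Everything downstream (adaptor parsing,
device release, isothermal-assembly simulation) is built on these primitives,
so they are deliberately deterministic and free of heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Union

from .errors import (
    NoCutSiteError,
    SequenceAlphabetError,
    TopologyError,
)

LINEAR = "linear"
CIRCULAR = "circular"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")


def _normalize_bases(bases: str) -> str:
    """Uppercase and validate a raw base string (ambiguity codes rejected)."""
    if not isinstance(bases, str) or not bases:
        raise SequenceAlphabetError("sequence must be a non-empty string")
    up = bases.upper()
    bad = set(up) - _VALID_BASES
    if bad:
        raise SequenceAlphabetError(
            f"sequence contains characters outside A/C/G/T: {sorted(bad)!r}"
        )
    return up


@dataclass(frozen=True)
class NucleotideSequence:
    """An exact DNA sequence over {A,C,G,T} with explicit topology.

    Lowercase input is canonicalized to uppercase; IUPAC ambiguity codes are
    rejected because the assembly arithmetic requires exact bases.
    """

    bases: str
    topology: str = LINEAR

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _normalize_bases(self.bases))
        if self.topology not in (LINEAR, CIRCULAR):
            raise TopologyError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __iter__(self) -> Iterator[str]:
        return iter(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(
            self.bases.translate(_COMPLEMENT)[::-1], self.topology
        )

    def rotated(self, offset: int) -> "NucleotideSequence":
        """Rotate a circular sequence so position ``offset`` becomes position 0."""
        if not self.is_circular:
            raise TopologyError("only circular sequences can be rotated")
        offset %= len(self)
        return NucleotideSequence(
            self.bases[offset:] + self.bases[:offset], CIRCULAR
        )

    def as_linear(self) -> "NucleotideSequence":
        return NucleotideSequence(self.bases, LINEAR)

    def gc_count(self) -> int:
        return self.bases.count("G") + self.bases.count("C")


SeqLike = Union[NucleotideSequence, str]


def as_sequence(s: SeqLike, topology: str = LINEAR) -> NucleotideSequence:
    """Coerce a plain string to a :class:`NucleotideSequence`."""
    if isinstance(s, NucleotideSequence):
        return s
    return NucleotideSequence(s, topology)


def reverse_complement(s: SeqLike) -> NucleotideSequence:
    """Watson-Crick reverse complement; topology is preserved."""
    return as_sequence(s).reverse_complement()


def revcomp_str(s: str) -> str:
    """Reverse complement of a raw (already validated) base string."""
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Restriction enzymes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnzymeSpec:
    """A blunt-cutting (or site-only) restriction enzyme.

    ``cut_offset`` is the 0-based position within the recognition sequence at
    which both strands are cut; ``None`` marks site-only entries that the
    package scans for but never uses to cut (the secondary sites kept on the
    adaptors for traditional-cloning rescue).
    """

    name: str
    recognition: str
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", _normalize_bases(self.recognition))
        if not 6 <= len(self.recognition) <= 8:
            raise ValueError(f"{self.name}: recognition must be 6-8 nt")
        if self.cut_offset is not None and not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset out of range")

    @property
    def cuts(self) -> bool:
        return self.cut_offset is not None

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp_str(self.recognition)


#: Bundled enzyme registry.  EcoRV, ZraI and SwaI are the blunt cutters the
#: assembly scheme actually digests with; the rest are the secondary sites
#: carried on the adaptors.
ENZYMES: dict[str, EnzymeSpec] = {
    e.name: e
    for e in (
        EnzymeSpec("EcoRV", "GATATC", 3),
        EnzymeSpec("ZraI", "GACGTC", 3),
        EnzymeSpec("SwaI", "ATTTAAAT", 4),
        EnzymeSpec("XbaI", "TCTAGA"),
        EnzymeSpec("SacI", "GAGCTC"),
        EnzymeSpec("MfeI", "CAATTG"),
        EnzymeSpec("NheI", "GCTAGC"),
        EnzymeSpec("AgeI", "ACCGGT"),
    )
}

assert all(e.is_palindromic for e in ENZYMES.values())


def get_enzyme(name: str) -> EnzymeSpec:
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; bundled: {sorted(ENZYMES)}") from None


def scan_sites(s: SeqLike, enzyme: EnzymeSpec) -> list[int]:
    """All top-strand occurrences of ``enzyme.recognition``, 0-based starts.

    On a circular sequence, occurrences spanning the origin are reported at
    their start position mod length.  Overlapping/nested occurrences are each
    reported.  Palindromic sites occupy a single locus and are reported once.
    """
    seq = as_sequence(s)
    rec = enzyme.recognition
    text = seq.bases
    limit = len(text)
    if seq.is_circular and len(text) >= len(rec):
        text = text + text[: len(rec) - 1]
    hits = []
    pos = text.find(rec)
    while pos != -1:
        if pos < limit:
            hits.append(pos)
        pos = text.find(rec, pos + 1)
    return hits


@dataclass(frozen=True)
class Fragment:
    """A linear piece produced by blunt digestion.

    Each end records the enzyme that produced it (``None`` for the native
    terminus of a linear substrate).  ``origin_offset`` is the cut position on
    the parent molecule at which this fragment starts.
    """

    seq: NucleotideSequence
    left_enzyme: str | None
    right_enzyme: str | None
    origin_offset: int = 0

    def __len__(self) -> int:
        return len(self.seq)


def blunt_digest(s: SeqLike, enzyme: EnzymeSpec) -> list[Fragment]:
    """Digest a circular molecule; n sites yield exactly n linear fragments.

    Fragments are returned in cut order starting from the first cut position;
    their lengths always sum to the substrate length.
    """
    seq = as_sequence(s, CIRCULAR)
    if not seq.is_circular:
        raise TopologyError("blunt_digest requires a circular substrate")
    if not enzyme.cuts:
        raise ValueError(f"{enzyme.name} is a site-only entry and cannot cut")
    sites = scan_sites(seq, enzyme)
    if not sites:
        raise NoCutSiteError(f"no {enzyme.name} site on substrate")
    n = len(seq)
    cuts = sorted({(p + enzyme.cut_offset) % n for p in sites})
    doubled = seq.bases + seq.bases
    frags = []
    for i, start in enumerate(cuts):
        end = cuts[(i + 1) % len(cuts)]
        length = (end - start) % n or n
        frags.append(
            Fragment(
                NucleotideSequence(doubled[start : start + length], LINEAR),
                left_enzyme=enzyme.name,
                right_enzyme=enzyme.name,
                origin_offset=start,
            )
        )
    return frags


def cut_linear(s: SeqLike, enzymes: "EnzymeSpec | list[EnzymeSpec]") -> list[Fragment]:
    """Cut a linear molecule with one or more blunt cutters.

    n distinct cut positions yield n+1 fragments; the two outermost ends keep
    ``None`` provenance.  Used to trim adaptor-tailed PCR amplicons to their
    assembly-ready form.
    """
    seq = as_sequence(s)
    if seq.is_circular:
        raise TopologyError("cut_linear requires a linear substrate")
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    cuts: dict[int, str] = {}
    for e in enzymes:
        if not e.cuts:
            raise ValueError(f"{e.name} is a site-only entry and cannot cut")
        for p in scan_sites(seq, e):
            cuts[p + e.cut_offset] = e.name
    positions = sorted(cuts)
    bounds = [0] + positions + [len(seq)]
    frags = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        if a == b:
            continue
        frags.append(
            Fragment(
                NucleotideSequence(seq.bases[a:b], LINEAR),
                left_enzyme=cuts.get(a),
                right_enzyme=cuts.get(b),
                origin_offset=a,
            )
        )
    return frags


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeltingParams:
    """How overlap melting temperatures are computed and judged.

    The isothermal assembly reaction runs at 50 °C, so every overlap must melt
    above ``threshold_C``.  The Wallace rule (2 °C per A/T, 4 °C per G/C) is
    the default estimator: deterministic integer arithmetic, and for the 15/15
    G+C adaptor cores any standard formula clears the bound anyway.
    """

    method: str = "wallace"
    threshold_C: float = 50.0

    def __post_init__(self) -> None:
        if self.method not in ("wallace", "nearest_neighbor"):
            raise ValueError(f"unknown Tm method {self.method!r}")
        if self.threshold_C <= 0:
            raise ValueError("threshold_C must be positive")


def wallace_tm(s: SeqLike) -> int:
    """Wallace-rule melting temperature: 4·(G+C) + 2·(A+T), integer °C."""
    seq = as_sequence(s)
    if seq.is_circular:
        raise TopologyError("Tm is defined for linear oligonucleotides")
    if len(seq) < 2:
        raise ValueError("Tm requires length >= 2")
    gc = seq.gc_count()
    return 4 * gc + 2 * (len(seq) - gc)


def nearest_neighbor_tm(s: SeqLike, Na: float = 50.0, dnac: float = 250.0) -> float:
    """Nearest-neighbor Tm (SantaLucia unified parameters, via Biopython).

    ``Na`` in mM monovalent salt, ``dnac`` strand concentration in nM.
    """
    from Bio.SeqUtils import MeltingTemp as _mt

    seq = as_sequence(s)
    if len(seq) < 2:
        raise ValueError("Tm requires length >= 2")
    return float(_mt.Tm_NN(seq.bases, Na=Na, dnac1=dnac, dnac2=dnac))


def melting_temperature(s: SeqLike, params: MeltingParams = MeltingParams()) -> float:
    if params.method == "wallace":
        return float(wallace_tm(s))
    return nearest_neighbor_tm(s)


# ---------------------------------------------------------------------------
# Hairpin screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HairpinStem:
    """One offending stem: ``s[start:start+length]`` pairs with
    ``s[partner_start:partner_start+length]`` (its reverse complement)."""

    start: int
    partner_start: int
    length: int
    stem: str


@dataclass(frozen=True)
class HairpinReport:
    passed: bool
    stems: tuple[HairpinStem, ...] = field(default=())

    def __bool__(self) -> bool:
        return self.passed


def hairpin_screen(
    s: SeqLike, min_stem: int = 5, min_loop: int = 3
) -> HairpinReport:
    """Screen a single strand for self-complementary stems.

    Fails iff two reverse-complementary substrings of length >= ``min_stem``
    occur with at least ``min_loop`` intervening bases; every seed stem of
    length exactly ``min_stem`` is reported with its coordinates.  The default
    stem of 5 reflects what can actually nucleate at the 50 °C reaction
    temperature (a 4-bp stem is not stable there; see the methods note).
    This is a combinatorial screen, not a thermodynamic fold.
    """
    seq = as_sequence(s)
    if seq.is_circular:
        raise TopologyError("hairpin screen operates on single linear strands")
    text = seq.bases
    stems = []
    k = min_stem
    for i in range(len(text) - k + 1):
        probe = revcomp_str(text[i : i + k])
        j = text.find(probe, i + k + min_loop)
        while j != -1:
            stems.append(HairpinStem(i, j, k, text[i : i + k]))
            j = text.find(probe, j + 1)
    return HairpinReport(passed=not stems, stems=tuple(stems))


# ---------------------------------------------------------------------------
# Canonical rotation
# ---------------------------------------------------------------------------


def least_rotation_offset(text: str) -> int:
    """Index of the lexicographically minimal rotation (Booth's algorithm)."""
    doubled = text + text
    f = [-1] * len(doubled)
    k = 0
    for j in range(1, len(doubled)):
        sj = doubled[j]
        i = f[j - k - 1]
        while i != -1 and sj != doubled[k + i + 1]:
            if sj < doubled[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != doubled[k + i + 1]:
            if sj < doubled[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k
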