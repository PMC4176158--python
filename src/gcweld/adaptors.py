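"""The four GC-adaptor classes and the bundled adaptor flank table.

A GC-adaptor is the 21-nt overlap unit that guides isothermal assembly:
a 3-nt blunt-cutter half-site (ATC for EcoRV, GTC for ZraI), a 15-bp core of
pure G/C, and the fixed GAT half of an EcoRV site.  On a device in its donor
plasmid the adaptor is embedded in a 30-nt flank::

    release site (6) | G/C core (15) | GAT (3) | secondary site (6)

The release site is where EcoRV or ZraI cuts the device out of the donor; the
secondary site (XbaI/SacI/MfeI/NheI/AgeI) is a rescue handle for traditional
cloning.  Four core classes exist (G5C5, C3G3, GC, C2G); each class is used in
both orientations, and the two facing flanks of a junction carry mutually
reverse-complementary cores so that the released fragments share an identical
21-mer end.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (
    MissingHalfSiteError,
    UnknownCoreError,
    UnknownReleaseSiteError,
    UnknownSecondarySiteError,
    UnsupportedEnzymeError,
)
from .seq_core import (
    ENZYMES,
    EnzymeSpec,
    NucleotideSequence,
    SeqLike,
    as_sequence,
    revcomp_str,
)

FORWARD = "forward"
REVCOMP = "revcomp"

HALF_SITE = "GAT"

#: Half-site left on a fragment end by each release enzyme (second half of the
#: recognition site: GAT^ATC, GAC^GTC).
RELEASE_HALF_SITES = {"EcoRV": "ATC", "ZraI": "GTC"}

RELEASE_ENZYMES = {"GATATC": ENZYMES["EcoRV"], "GACGTC": ENZYMES["ZraI"]}

SECONDARY_ENZYMES = {
    ENZYMES[n].recognition: ENZYMES[n] for n in ("XbaI", "SacI", "MfeI", "NheI", "AgeI")
}


@dataclass(frozen=True)
class AdaptorClass:
    """One of the four GC-adaptor core classes."""

    name: str
    canonical_core: str

    def __post_init__(self) -> None:
        assert len(self.canonical_core) == 15
        assert set(self.canonical_core) <= {"G", "C"}


ADAPTOR_CLASSES: dict[str, AdaptorClass] = {
    c.name: c
    for c in (
        AdaptorClass("G5C5", "GGGGGCCCCCGGGGG"),
        AdaptorClass("C3G3", "GGGCCCGGGCCCGGG"),
        AdaptorClass("GC", "CGCGCGCGCGCGCGC"),
        AdaptorClass("C2G", "CGGCGGCGGCGGCGG"),
    )
}

#: core string (either orientation) -> (class, orientation)
_CORE_LOOKUP: dict[str, tuple[AdaptorClass, str]] = {}
for _cls in ADAPTOR_CLASSES.values():
    _CORE_LOOKUP[_cls.canonical_core] = (_cls, FORWARD)
    _CORE_LOOKUP[revcomp_str(_cls.canonical_core)] = (_cls, REVCOMP)


@dataclass(frozen=True)
class AdaptorFace:
    """One flank of a device, as written in the adaptor table.

    A device's right flank is stored as the table string located on the
    *bottom* strand, so on the device's top strand it reads as the reverse
    complement with the release site distal to the payload — the only
    arrangement that yields identical facing 21-mers between adjacent devices.
    """

    adaptor_class: AdaptorClass
    core_orientation: str
    release_enzyme: EnzymeSpec
    secondary_site: EnzymeSpec

    def __post_init__(self) -> None:
        if self.core_orientation not in (FORWARD, REVCOMP):
            raise ValueError(f"bad orientation {self.core_orientation!r}")
        if self.release_enzyme.name not in RELEASE_HALF_SITES:
            raise UnsupportedEnzymeError(
                f"release enzyme must be EcoRV or ZraI, got {self.release_enzyme.name}"
            )

    @property
    def core(self) -> str:
        """The 15-nt core in this face's stated orientation."""
        if self.core_orientation == FORWARD:
            return self.adaptor_class.canonical_core
        return revcomp_str(self.adaptor_class.canonical_core)

    @property
    def half_site(self) -> str:
        return HALF_SITE

    @property
    def flank_string(self) -> str:
        """The full 30-nt flank: release site + core + GAT + secondary site."""
        return (
            self.release_enzyme.recognition
            + self.core
            + HALF_SITE
            + self.secondary_site.recognition
        )

    def with_enzyme(self, enzyme: EnzymeSpec) -> "AdaptorFace":
        """Same adaptor with the other release enzyme (swaps the 6-nt prefix)."""
        return AdaptorFace(
            self.adaptor_class, self.core_orientation, enzyme, self.secondary_site
        )


def parse_flank(flank: SeqLike) -> AdaptorFace:
    """Decompose a 30-nt adaptor flank into its four segments.

    Each failure mode (unknown release site, core not matching any class in
    either orientation, missing GAT half-site, unknown secondary site) raises
    a distinct parse error.
    """
    seq = as_sequence(flank)
    if len(seq) != 30:
        raise UnknownReleaseSiteError(
            f"adaptor flank must be 30 nt, got {len(seq)}"
        )
    text = seq.bases
    release, core, half, secondary = text[:6], text[6:21], text[21:24], text[24:30]
    if release not in RELEASE_ENZYMES:
        raise UnknownReleaseSiteError(
            f"flank does not begin with an EcoRV/ZraI site: {release}"
        )
    if core not in _CORE_LOOKUP:
        raise UnknownCoreError(f"core {core} matches no adaptor class in either orientation")
    if half != HALF_SITE:
        raise MissingHalfSiteError(f"expected GAT half-site after core, found {half}")
    if secondary not in SECONDARY_ENZYMES:
        raise UnknownSecondarySiteError(f"unknown secondary site {secondary}")
    cls, orientation = _CORE_LOOKUP[core]
    return AdaptorFace(cls, orientation, RELEASE_ENZYMES[release], SECONDARY_ENZYMES[secondary])


#: The adaptor table shipped with the package: every distinct printed flank
#: string, keyed by its label (class-then-secondary for left flanks,
#: secondary-then-class for right flanks).
TABLE_FLANKS: dict[str, str] = {
    "G5C5-XbaI": "GACGTCGGGGGCCCCCGGGGGGATTCTAGA",
    "SacI-C3G3": "GACGTCGGGCCCGGGCCCGGGGATGAGCTC",
    "C3G3-MfeI": "GATATCCCCGGGCCCGGGCCCGATCAATTG",
    "NheI-GC": "GATATCCGCGCGCGCGCGCGCGATGCTAGC",
    "GC-NheI": "GATATCGCGCGCGCGCGCGCGGATGCTAGC",
    "AgeI-C2G": "GATATCCGGCGGCGGCGGCGGGATACCGGT",
    "C2G-AgeI": "GATATCCCGCCGCCGCCGCCGGATACCGGT",
    "XbaI-G5C5": "GATATCCCCCCGGGGGCCCCCGATTCTAGA",
}

FACES: dict[str, AdaptorFace] = {label: parse_flank(s) for label, s in TABLE_FLANKS.items()}


def face_label(face: AdaptorFace) -> str:
    """Label of the bundled face with the same class/orientation/secondary
    site (release-enzyme dialect is ignored)."""
    for label, bundled in FACES.items():
        if (
            bundled.adaptor_class == face.adaptor_class
            and bundled.core_orientation == face.core_orientation
            and bundled.secondary_site == face.secondary_site
        ):
            return label
    raise KeyError("face does not correspond to a bundled adaptor flank")


def face_pairing(left: AdaptorFace, right: AdaptorFace) -> bool:
    """Can a device's ``left`` face join the preceding device's ``right`` face?

    True iff both faces carry the same adaptor class with mutually
    reverse-complementary cores (i.e. opposite stored orientations).  Because
    the right flank sits on the bottom strand, this is exactly the condition
    under which the two released fragments expose identical facing 21-mers.
    """
    return (
        left.adaptor_class == right.adaptor_class
        and left.core_orientation != right.core_orientation
    )


def junction_21mer(face: AdaptorFace, enzyme: EnzymeSpec) -> NucleotideSequence:
    """The 21-nt overlap a released fragment exposes at this face.

    Release-enzyme half-site (ATC for EcoRV, GTC for ZraI) + 15-nt core in the
    face's stated orientation + the fixed GAT half of an EcoRV site.
    """
    try:
        half = RELEASE_HALF_SITES[enzyme.name]
    except KeyError:
        raise UnsupportedEnzymeError(
            f"junctions are defined for EcoRV/ZraI release only, got {enzyme.name}"
        ) from None
    return NucleotideSequence(half + face.core + HALF_SITE)
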