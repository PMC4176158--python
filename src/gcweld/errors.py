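"""Exception hierarchy shared across the package.

Every domain error carries a stable machine-readable ``code`` so the CLI can
emit it verbatim and scripts can branch on it.
"""

from __future__ import annotations


class GCWeldError(Exception):
    """Base class for all domain errors raised by this package."""

    code: str = "error"

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message


class SequenceAlphabetError(GCWeldError):
    code = "invalid_alphabet"


class TopologyError(GCWeldError):
    code = "topology"


class NoCutSiteError(GCWeldError):
    code = "no_cut_site"


class FlankParseError(GCWeldError):
    code = "flank_parse"


class UnknownReleaseSiteError(FlankParseError):
    code = "flank_parse.release_site"


class UnknownCoreError(FlankParseError):
    code = "flank_parse.core"


class MissingHalfSiteError(FlankParseError):
    code = "flank_parse.half_site"


class UnknownSecondarySiteError(FlankParseError):
    code = "flank_parse.secondary_site"


class UnsupportedEnzymeError(GCWeldError):
    code = "unsupported_enzyme"


class NoCompatibleEnzymeError(GCWeldError):
    code = "no_compatible_enzyme"


class CatalogError(GCWeldError):
    code = "catalog"


class CatalogSchemaError(CatalogError):
    code = "catalog.schema"


class DuplicateIdError(CatalogError):
    code = "catalog.duplicate_id"


class MissingFileError(CatalogError):
    code = "catalog.missing_file"


class DeviceValidationError(GCWeldError):
    code = "device_invalid"


class PlanError(GCWeldError):
    code = "plan"


class MissingSlotError(PlanError):
    code = "plan.missing_slot"


class CategoryMismatchError(PlanError):
    code = "plan.category_mismatch"


class AdaptorIncompatibilityError(PlanError):
    code = "plan.adaptor_incompatible"


class ReleaseError(GCWeldError):
    code = "release"


class AssemblyError(GCWeldError):
    code = "assembly"


class OpenAssemblyError(AssemblyError):
    code = "assembly.open"


class AmbiguousAssemblyError(AssemblyError):
    code = "assembly.ambiguous"


class LowJunctionTmError(AssemblyError):
    code = "assembly.low_tm"


class NoCassetteError(AssemblyError):
    code = "assembly.no_cassette"


class TailMismatchError(AssemblyError):
    code = "assembly.tail_mismatch"


class PrimerDesignError(GCWeldError):
    code = "primer_design"


class FixtureError(GCWeldError):
    code = "fixture"


class ProtocolError(GCWeldError):
    code = "protocol"
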