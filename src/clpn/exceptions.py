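"""Exception hierarchy for the clpn package."""


class ClpnError(Exception):
    """Base class for all clpn-specific errors."""


class SchemaError(ClpnError):
    """A required column is absent or the input schema is malformed."""


class ValidationError(ClpnError):
    """Input data violate a structural invariant (duplicate ids, negative
    subscale scores, missing stage, ...)."""


class MappingError(ClpnError):
    """An item-to-subscale map is not total or not disjoint."""


class DomainError(ClpnError):
    """A scalar argument lies outside its mathematical domain."""


class EmptyDataError(ClpnError):
    """An operation left zero subjects (or zero edges) to work with."""


class DegenerateDataError(ClpnError):
    """Data are structurally degenerate for the requested computation
    (constant outcome, a single missingness pattern, ...)."""


class InsufficientDataError(ClpnError):
    """Too few subjects for a stable fit."""


class SpecError(ClpnError):
    """A synthetic-cohort specification violates its invariants."""


class PartitionError(ClpnError):
    """A node partition is not a two-coloring of the node set."""


class SubgroupError(ClpnError):
    """A subgroup split produced an empty group."""


class RenderError(ClpnError):
    """A mandatory report section is missing."""


class FixtureLookupError(ClpnError, KeyError):
    """Unknown fixture name."""
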