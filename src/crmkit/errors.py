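"""Exception hierarchy shared across crmkit modules."""


class CRMError(Exception):
    """Base class for all crmkit errors."""


class ParseError(CRMError):
    """A file row or header does not match the declared schema."""


class StructureError(CRMError):
    """Parsed data violates a structural invariant (frame gaps, overlaps, ...)."""


class GeometryError(CRMError):
    """A geometric operation hit a degenerate configuration."""


class FitError(CRMError):
    """A least-squares fit is singular or under-determined."""


class InsufficientSamplesError(CRMError):
    """Too few subjects/samples for the requested statistic."""
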