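"""Exception hierarchy shared across the library."""


class SeegPlanError(Exception):
    """Base class for all seegplan errors."""


class ValidationError(SeegPlanError):
    """An input violates a documented invariant (bad mesh, bad config, ...)."""


class ParseError(SeegPlanError):
    """A file could not be parsed; message names the offending line."""


class SchemaError(SeegPlanError):
    """A plan / config document does not match its schema."""


class GeometryError(SeegPlanError):
    """A geometric query has no defined answer (e.g. ray misses the surface)."""


class GenerationError(SeegPlanError):
    """Phantom generation could not satisfy its constraints within bounded retries."""
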