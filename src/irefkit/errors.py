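"""Exception hierarchy for irefkit.

All library errors derive from :class:`IrefkitError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class IrefkitError(Exception):
    """Base class for all irefkit errors."""


class DialectError(IrefkitError):
    """The input header does not correspond to a known MITAB column dialect."""


class MitabParseError(IrefkitError):
    """A data line could not be parsed under the active dialect."""


class IntegrityError(IrefkitError):
    """Cross-record consistency violated (e.g. one ROGID with two cROGIDs)."""


class FixtureConfigError(IrefkitError):
    """A synthetic-table configuration is internally inconsistent."""


class DegenerateSampleError(IrefkitError):
    """A degree sample has no variation and cannot constrain a fit."""


class PowerLawFitError(IrefkitError):
    """No admissible xmin candidate (tail everywhere below the minimum size)."""


class FetchError(IrefkitError):
    """A remote retrieval failed after the configured retries."""
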