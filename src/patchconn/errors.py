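"""Exception hierarchy."""


class PatchconnError(Exception):
    """Base class for all package-specific errors."""


class SizingError(PatchconnError):
    """A volume, mask, or patch geometry cannot accommodate the request."""


class ParameterError(PatchconnError):
    """A numeric parameter is outside its admissible range."""


class DesignError(PatchconnError):
    """The group design is degenerate (e.g. a group with < 2 subjects)."""


class DegenerateDataError(PatchconnError):
    """The data admit no test statistic (e.g. an all-zero distance matrix)."""


class ValidationError(PatchconnError):
    """An input file or in-memory object failed strict validation."""
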