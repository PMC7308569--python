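"""Exception types shared across the pipeline stages."""


class FldsError(Exception):
    """Base class for pipeline errors."""


class ParameterError(FldsError, ValueError):
    """Contradictory or out-of-range parameters."""


class FormatError(FldsError, ValueError):
    """Malformed input file or sequence."""


class ConsistencyError(FldsError, ValueError):
    """Inputs that disagree with each other (e.g. missing profile, roster mismatch)."""
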