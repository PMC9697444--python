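"""Exception hierarchy shared across the pipeline stages."""


class PbrsurfError(Exception):
    """Base class for all package errors."""


class InputError(PbrsurfError):
    """Invalid or malformed input data (bad CSV row, missing column,
    out-of-range angle, too few measurements). CLI maps this to exit code 2."""


class SolverError(PbrsurfError):
    """A numerical stage failed (singular liquid system, zero Zisman slope,
    unphysical component set). CLI maps this to exit code 3."""
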