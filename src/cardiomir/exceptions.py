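"""Error taxonomy shared across the pipeline.

The CLI maps these onto distinct exit codes so that configuration mistakes,
malformed inputs and numerical failures can be told apart in batch runs.
"""


class CardiomirError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardiomirError):
    """A parameter value is outside its allowed domain."""


class InputError(CardiomirError):
    """An input table/graph violates a structural precondition."""


class NumericalError(CardiomirError):
    """A computation could not be carried out (degenerate data)."""
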