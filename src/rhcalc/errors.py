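"""Exception hierarchy shared across the package.

``DomainError`` means an input lies outside the physical domain of a model
(e.g. a mass fraction of 1.5); ``RangeError`` means a requested output is
unattainable (e.g. inverting for an RH above 100%).  The command-line
interface maps both to exit code 2.
"""


class RHCalcError(Exception):
    """Base class for all rhcalc errors."""


class DomainError(RHCalcError, ValueError):
    """An input value is outside the model's physical domain."""


class RangeError(RHCalcError, ValueError):
    """A requested target is outside the attainable range of a model."""


class RegistryError(RHCalcError, ValueError):
    """A solute registry file or record is invalid."""


class TruncationError(RHCalcError, ValueError):
    """A truncated level sum retains too much tail weight to be trusted."""
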