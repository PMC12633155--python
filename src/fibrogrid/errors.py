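"""Exception types shared across fibrogrid."""


class FibrogridError(Exception):
    """Base class for all fibrogrid errors."""


class SchemaError(FibrogridError, ValueError):
    """A network or scenario file violates the documented schema."""


class ContractError(FibrogridError, ValueError):
    """An argument violates a documented precondition."""


class IntegrationError(FibrogridError, RuntimeError):
    """The integrator produced a non-finite derivative."""
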