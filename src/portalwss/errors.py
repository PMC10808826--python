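"""Exception hierarchy shared across the pipeline."""


class PortalWSSError(Exception):
    """Base class for all package errors."""


class ValidationError(PortalWSSError):
    """A domain object violates one of its invariants."""


class StateError(PortalWSSError):
    """An operation was applied to a tree in the wrong pre/postoperative state."""


class DiscretizationError(PortalWSSError):
    """The requested surface step is incompatible with the geometry."""


class TopologyError(PortalWSSError):
    """The vessel network is not a rooted tree (cycle, missing outlet, ...)."""


class ParseError(PortalWSSError):
    """A serialized tree or config file does not conform to the schema."""


class ConfigError(PortalWSSError):
    """A configuration block is inconsistent or incomplete."""


class DomainError(PortalWSSError):
    """An argument is outside the mathematical domain of an operation."""


class NumericalError(PortalWSSError):
    """Root finding or quadrature failed to converge."""
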