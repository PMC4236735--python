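"""Exception hierarchy.

Every error raised by the package derives from :class:`KindraftError`, so
callers (and the CLI) can catch one base class.
"""


class KindraftError(Exception):
    """Base class for all kindraft errors."""


class SBMLReadError(KindraftError):
    """Malformed SBML, missing file, or an unsupported construct."""


class NetworkValidationError(KindraftError):
    """A network violates its structural invariants (duplicate ids, ...)."""


class MatchError(KindraftError):
    """An identifier in a table resolves to no (or more than one) model entity."""


class TableFormatError(KindraftError):
    """Malformed value table, removal list, or SBtab file."""


class FBAError(KindraftError):
    """Linear-programming failure (infeasible, unbounded, solver breakdown)."""


class ReductionError(KindraftError):
    """Metabolite elimination cannot proceed (zero throughput, hub cap, ...)."""


class RateLawError(KindraftError):
    """Invalid rate-law request or a reaction the law family cannot express."""


class AssemblyError(KindraftError):
    """Draft-model assembly gap: missing concentrations, laws, or fluxes."""


class LogDomainError(AssemblyError):
    """A logarithm was evaluated at a non-positive concentration."""


class FixtureError(KindraftError):
    """Infeasible synthetic-network specification."""
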