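"""Exception hierarchy for oglysite."""


class OglysiteError(Exception):
    """Base class for all package errors."""


class FormatError(OglysiteError):
    """A file could not be parsed (malformed FASTA, bad table schema)."""


class ValidationError(OglysiteError):
    """Parsed data violates a data-model invariant (coordinates, coverage,
    residue mismatches, duplicates)."""


class ConfigError(OglysiteError):
    """An infeasible or inconsistent configuration was supplied."""


class IcaConvergenceError(OglysiteError):
    """Fixed-point ICA failed to converge within the iteration budget."""

    def __init__(self, max_iter: int):
        self.max_iter = max_iter
        super().__init__(
            f"ICA did not converge within {max_iter} iterations; the input may be "
            "close to Gaussian (independent components are then not identifiable)"
        )
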