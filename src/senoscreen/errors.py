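"""Exception hierarchy shared across the package."""


class SenoscreenError(Exception):
    """Base class for all package errors."""


class SmilesParseError(SenoscreenError):
    """A SMILES string could not be parsed.

    Carries the offending string in ``smiles``.
    """

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"could not parse SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class CapabilityError(SenoscreenError):
    """A requested optional backend is unavailable in this installation."""


class CurationError(SenoscreenError):
    """Inconsistent input compound tables (e.g. one id, conflicting structures)."""


class FeatureMismatchError(SenoscreenError):
    """Feature scheme/shape of a query does not match the fitted model or fingerprint."""
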