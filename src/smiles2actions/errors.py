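"""Exception hierarchy shared across the package."""


class Smiles2ActionsError(Exception):
    """Base class for all package errors."""


class ActionRenderError(Smiles2ActionsError):
    """A mandatory property is missing when serializing an action.

    Carries ``action_index`` (0-based position in the sequence).
    """

    def __init__(self, action_index: int, reason: str):
        self.action_index = action_index
        self.reason = reason
        super().__init__(f"action {action_index}: {reason}")


class ActionParseError(Smiles2ActionsError):
    """A clause of the semi-structured action text cannot be parsed.

    Carries ``clause_index`` (0-based) and a human-readable reason; this
    error drives the validity metric.
    """

    def __init__(self, clause_index: int, reason: str):
        self.clause_index = clause_index
        self.reason = reason
        super().__init__(f"clause {clause_index}: {reason}")


class NameStrippingError(Smiles2ActionsError):
    """Compound-name stripping left nothing behind."""


class QuantityParseError(Smiles2ActionsError):
    """A temperature/duration/pH string cannot be converted to a number."""

    def __init__(self, kind: str, text: str):
        self.kind = kind
        self.text = text
        super().__init__(f"cannot parse {kind} value from {text!r}")


class TokenizationError(Smiles2ActionsError):
    """A numeric value falls outside the admissible token range, or an
    interval-token index is invalid."""


class ReactionSmilesError(Smiles2ActionsError):
    """Invalid reaction SMILES (missing '>>', empty side, ...)."""


class MoleculeSmilesError(Smiles2ActionsError):
    """A molecule SMILES cannot be parsed by the chemistry backend."""
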