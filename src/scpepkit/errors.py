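"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: ValidationError -> 2, IOFailure -> 3,
anything else -> 4.
"""


class ScpepkitError(Exception):
    """Base class for all scpepkit errors."""


class ValidationError(ScpepkitError):
    """Invalid input values or parameters (bad sequence, bad threshold...)."""


class SchemaError(ValidationError):
    """A tabular input is missing mandatory columns or has malformed rows."""


class ReferenceMismatchError(ValidationError):
    """A variant's stated reference residue disagrees with the database.

    Usually signals a stale SNV table against a newer protein database.
    """


class VocabularyError(ValidationError):
    """A modification tag outside the configured UniMod vocabulary."""


class IOFailure(ScpepkitError):
    """File-system level failure (unreadable/unwritable path)."""
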