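"""Exception hierarchy.

``SchemaError``   — an input file is structurally wrong (missing column).
``ValidationError`` — a record violates a domain invariant (bad residue,
duplicate identifier, out-of-range length without override).
``ConsistencyError`` — two pipeline artefacts disagree (a hit refers to a
peptide or protein that is not in the library / fragment map).
"""


class BiopepscanError(Exception):
    """Base class for all package errors."""


class SchemaError(BiopepscanError):
    pass


class ValidationError(BiopepscanError):
    pass


class ConsistencyError(BiopepscanError):
    pass
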