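"""Exception types shared across the package."""


class ZincbiasError(Exception):
    """Base class for all operational errors raised by zincbias.

    The CLI maps these to exit status 1; anything else is a bug.
    """


class ParseError(ZincbiasError):
    """A text input (PDB, BPF, DLG, SMILES, ...) could not be parsed."""


class GeometryError(ZincbiasError):
    """A coordination-geometry precondition was violated."""


class ChemistryError(ZincbiasError):
    """A ligand lacks the required functional group or cannot be edited."""
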