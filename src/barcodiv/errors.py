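"""Exception hierarchy used across the toolkit."""


class BarcodivError(Exception):
    """Base class for all toolkit errors."""


class ParseError(BarcodivError):
    """Malformed input file or string (FASTA, Newick, TSV)."""


class DataError(BarcodivError):
    """Structurally valid input that violates a domain invariant."""


class NumericalError(BarcodivError):
    """Optimisation or numerical routine failed to produce a finite result."""
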