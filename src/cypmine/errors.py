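"""Exception hierarchy for cypmine."""


class CypmineError(Exception):
    """Base class for all cypmine errors."""


class FastaParseError(CypmineError):
    """Malformed FASTA input (bad header, empty sequence, bad residue)."""


class SchemaError(CypmineError):
    """Tabular input is missing required columns or violates uniqueness."""


class ValidationError(CypmineError):
    """A record violates its structural invariants (e.g. gene coordinates)."""


class ConfigurationError(CypmineError):
    """Invalid configuration or an empty reference set."""


class UndefinedStatisticError(CypmineError):
    """A statistic was requested with a zero denominator."""


class GenerationError(CypmineError):
    """The synthetic generator cannot satisfy a requested constraint."""


class NotAFerredoxinError(CypmineError):
    """No Fe-S binding motif was found in the sequence."""


class AmbiguousClusterTypeError(CypmineError):
    """The combination of Fe-S motifs does not map to a known cluster type."""


class ConsistencyError(CypmineError):
    """Cross-stage inputs disagree (e.g. unknown species code in annotations)."""
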