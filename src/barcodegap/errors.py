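"""Exception hierarchy for the barcode-gap evaluation pipeline."""


class BarcodeGapError(Exception):
    """Base class for all package errors."""


class AlignmentError(BarcodeGapError):
    """Rows of an alignment are inconsistent (e.g. unequal lengths)."""


class AlphabetError(BarcodeGapError):
    """A sequence contains a character outside IUPAC DNA + gap."""


class MetadataError(BarcodeGapError):
    """Sample/species bookkeeping is inconsistent or incomplete."""


class InsufficientDataError(BarcodeGapError):
    """Too few samples/sites for the requested computation."""


class UndefinedDistanceError(BarcodeGapError):
    """A pair of sequences shares no comparable sites."""


class SaturationError(BarcodeGapError):
    """The K2P logarithm argument is non-positive for a pair."""


class EvaluationError(BarcodeGapError):
    """A discrimination-rate computation received an empty or invalid input."""


class TreeError(BarcodeGapError):
    """Tree construction or interrogation failed."""


class BootstrapError(TreeError):
    """Bootstrap resampling could not produce enough valid replicates."""


class NewickParseError(TreeError):
    """A Newick string could not be parsed."""
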