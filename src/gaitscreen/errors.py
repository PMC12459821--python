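"""Exception hierarchy for the gaitscreen pipeline."""


class GaitScreenError(Exception):
    """Base class for all gaitscreen errors."""


class FormatError(GaitScreenError):
    """An input file does not have the expected tabular layout."""


class IntegrityError(GaitScreenError):
    """Input data violates a uniqueness or referential constraint."""


class DegenerateDataError(GaitScreenError):
    """A dataset has been reduced to the point where analysis is impossible."""


class NormalizationError(GaitScreenError):
    """Baseline normalization cannot be carried out as requested."""
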