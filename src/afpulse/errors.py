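"""Named exceptions raised across the pulse-analysis pipeline.

Every failure mode the readers and analysis stages can hit maps to a
distinct class so callers (and tests) can discriminate between, say, a
malformed CSV and a physiologically unanalyzable window.
"""


class AfPulseError(Exception):
    """Base class for all package errors."""


class FormatError(AfPulseError):
    """A sensor or label file violates the documented CSV contract."""


class MonotonicityError(FormatError):
    """Timestamps are not strictly increasing."""


class MissingValueError(FormatError):
    """A stream contains NaN/empty cells; readers never impute."""


class VocabularyError(FormatError):
    """A rhythm label is outside {AF, PAC_PVC, NSR, NOISE}."""


class ParameterError(AfPulseError):
    """An operation was called with an invalid parameter combination."""


class ConfigError(ParameterError):
    """A simulation configuration is physiologically inconsistent."""


class UnanalyzableSegmentError(AfPulseError):
    """Too few pulse peaks / RR intervals to compute rhythm statistics.

    Distinct from motion-noise rejection: the segment may be clean but
    degenerate (flat line, extreme bradycardia, massive RR dropout).
    """


class AlignmentError(AfPulseError):
    """Predicted and reference label tables do not share a key set."""


class ConsistencyError(AfPulseError):
    """Internal pipeline contract violated (e.g. an irregular window
    reached label assembly without an ectopy result)."""
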