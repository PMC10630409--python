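"""Exception hierarchy shared across the package."""


class TrialMatchError(Exception):
    """Base class for all package errors."""


class TerminologyError(TrialMatchError):
    """Malformed terminology table (bad category, missing column, ...)."""


class CycleError(TerminologyError):
    """Parent links in a terminology form a cycle.

    The offending cycle (list of entry ids) is stored on ``.cycle``.
    """

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("cycle in parent links: " + " -> ".join(self.cycle))


class LookupError_(TrialMatchError):
    """Unknown entry id."""


class TrialParseError(TrialMatchError):
    """Trial record does not validate against the record schema.

    ``.pointer`` holds a JSON-pointer path to the first offending field.
    """

    def __init__(self, message, pointer=""):
        self.pointer = pointer
        super().__init__(f"{message} (at {pointer or '/'})")


class MetadataError(TrialMatchError):
    """Unparseable metadata value (e.g. an age string)."""


class ConsistencyError(TrialMatchError):
    """A mention does not belong to the passage it was classified against."""


class QueryError(TrialMatchError):
    """Advanced-search condition references an unknown entry."""


class AnnotationError(TrialMatchError):
    """Protein position outside the gene model, or similar."""


class ProfileError(TrialMatchError):
    """Patient profile invalid (missing cancer type, bad VCF, ...)."""


class VCFParseError(ProfileError):
    """Malformed VCF body line; ``.line_number`` is 1-based."""

    def __init__(self, message, line_number):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class MatchJobError(TrialMatchError):
    """Match job cannot run (e.g. the profile has nothing to match on)."""


class RefineError(TrialMatchError):
    """Refinement condition references an unknown entry."""


class GenerationError(TrialMatchError):
    """Synthetic-corpus spec is inconsistent or a target profile is unsatisfiable."""
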