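"""Exception types raised by the pipeline stages."""

from __future__ import annotations


class InfoveilError(Exception):
    """Base class for all pipeline errors."""


class LexiconError(InfoveilError):
    """Base class for lexicon loading/validation failures."""


class UnknownCategoryError(LexiconError):
    """A lexicon row names a category outside the 17-name registry."""


class UnresolvedCanonicalError(LexiconError):
    """A colloquial entry's canonical term is missing or not a medical entry."""


class EmptyLexiconError(LexiconError):
    """The lexicon file contained no entries."""


class LexiconFormatError(LexiconError):
    """Malformed lexicon row (missing columns, conflicting duplicates, ...)."""


class CorpusError(InfoveilError):
    """Base class for corpus I/O and filtering failures."""


class EmptyCorpusError(CorpusError):
    """No parseable record was found in the corpus file."""


class MissingBotScoreError(CorpusError):
    """An available account reached the bot filter without a precomputed score."""


class EmptySeedListError(CorpusError):
    """The seed-term filter was invoked with no seed terms."""


class ValidationError(InfoveilError):
    """Base class for sampling/annotation/agreement failures."""


class AllocationError(ValidationError):
    """A sampling allocation names an unknown stratum or exceeds its population."""


class AnnotationMismatchError(ValidationError):
    """The two coders' annotation sets do not cover the same posts."""


class MissingResolutionError(ValidationError):
    """A coder disagreement has no adjudicated resolution."""


class MissingStratumError(ValidationError):
    """An adjudicated post has no recorded sampling stratum."""


class SimulationError(InfoveilError):
    """Invalid simulation configuration or inconsistent ground truth request."""


class FixtureError(InfoveilError):
    """A packaged reference fixture is missing or fails its checksum."""


class PipelineError(InfoveilError):
    """A pipeline stage aborted; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
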