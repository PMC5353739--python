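"""Exception hierarchy for the gliadin analysis pipeline."""


class GliadinError(Exception):
    """Base class for all package errors."""


class InputError(GliadinError, ValueError):
    """Malformed or empty input data (bad alphabet, empty sequence, ...)."""


class ConfigError(GliadinError, ValueError):
    """Invalid or infeasible configuration (empty profile list, bad bands, ...)."""


class SegmentationError(GliadinError):
    """The domain grammar of a type profile cannot be satisfied on a protein."""


class SubtypeError(GliadinError):
    """A subtype discriminator could not be applied or produced a tie."""


class ConflictError(GliadinError):
    """Contradictory locus evidence (spot assignment vs PCR mapping, ...)."""
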