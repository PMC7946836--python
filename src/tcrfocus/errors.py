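"""Exception hierarchy shared across the package."""


class TcrFocusError(Exception):
    """Base class for all package errors."""


class RepertoireError(TcrFocusError, ValueError):
    """Invalid clone or repertoire state."""


class FormatError(TcrFocusError, ValueError):
    """A clonotype table does not conform to its declared dialect."""


class EmptyRepertoireError(FormatError):
    """A clonotype table contains no data rows."""


class DepthError(TcrFocusError, ValueError):
    """Requested subsampling depth exceeds the available reads."""


class PairingError(TcrFocusError, ValueError):
    """Two repertoires cannot be compared (chain or patient mismatch)."""


class KeyModeError(TcrFocusError, ValueError):
    """Requested clonotype key mode cannot be formed from the available fields."""


class SimilarityError(TcrFocusError, ValueError):
    """CDR3 too short (or otherwise invalid) for triplet-kernel similarity."""


class ConfigurationError(TcrFocusError, ValueError):
    """Infeasible simulation or pipeline configuration."""


class DegenerateInputError(TcrFocusError, ValueError):
    """Statistical test input with no variance (undefined statistic)."""


class ManifestError(TcrFocusError, ValueError):
    """Cohort manifest is malformed or pairs do not resolve."""
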