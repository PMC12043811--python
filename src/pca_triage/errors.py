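"""Exception types shared across the pipeline."""


class PcaTriageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PcaTriageError):
    """A configuration value is invalid or inconsistent (e.g. gland does not fit grid)."""


class DegenerateVolumeError(PcaTriageError):
    """A volume is degenerate for the requested operation (e.g. zero variance)."""


class GridMismatchError(PcaTriageError):
    """Two volumes expected on the same grid have different shape/spacing/origin."""


class CaseIOError(PcaTriageError):
    """A case directory is missing files or contains inconsistent data."""
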