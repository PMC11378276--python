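"""Exception hierarchy for naquant."""


class NaquantError(Exception):
    """Base class for all naquant errors."""


class FormatError(NaquantError):
    """A spectrum or manifest file could not be parsed."""


class UnsupportedModeError(FormatError):
    """mzML spectra are profile mode; only centroided data is supported."""


class EmptyMatrixError(NaquantError):
    """No peaks fell inside the alignment m/z window for any spectrum."""


class DegenerateRowError(NaquantError):
    """A row cannot be normalized (all-zero / zero total)."""


class NotFittedError(NaquantError):
    """A scaler or model was used before fitting."""


class RankError(NaquantError):
    """Requested latent variables exceed what the data can support."""


class DegenerateResponseError(NaquantError):
    """X carries no covariance with y (zero-norm weight vector)."""


class UndefinedCorrelationError(NaquantError):
    """Pearson correlation is undefined (zero variance)."""


class AlignmentError(NaquantError):
    """New data does not match the model's bin grid / retained columns."""


class ManifestError(NaquantError):
    """The sample manifest is missing required information."""
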