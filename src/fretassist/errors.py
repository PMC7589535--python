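"""Exception hierarchy shared across the package."""


class FretAssistError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FretAssistError):
    """A structure file could not be parsed."""


class TopologyError(FretAssistError):
    """Conformers do not share the same (chain, residue, atom) topology."""


class EmptyVolumeError(FretAssistError):
    """An accessible volume is empty (fully buried labeling site)."""


class UndefinedQualityError(FretAssistError):
    """A quality statistic is undefined because N_dof <= 0.

    Raised instead of silently dividing: with as many fitted parameters as
    measurements the model is (at least) critically determined and
    chi2_r / chi2_n carry no information.  Add cross-validation pairs that
    were not used for fitting to make N_dof positive.
    """


class UndefinedScoreError(FretAssistError):
    """A similarity score has no defined value (e.g. no pairs in radius)."""
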