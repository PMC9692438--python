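"""Exception hierarchy shared by all phagekit modules."""


class PhagekitError(Exception):
    """Base class for all phagekit errors."""


class InputError(PhagekitError, ValueError):
    """Invalid or inconsistent input data."""


class FitError(PhagekitError, RuntimeError):
    """A nonlinear fit failed to converge or produced an unusable optimum."""


class DegenerateFitError(FitError):
    """The data carry no information about the model (e.g. a flat series)."""


class NotApplicableError(PhagekitError, RuntimeError):
    """A statistical procedure cannot be applied to the given design."""
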