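"""Exception types raised by the crosstalk model."""


class DimensionError(ValueError):
    """Vector or grid dimensions do not match."""


class IntegrationError(RuntimeError):
    """A state variable became non-finite during forward integration."""


class DegenerateBaselineError(ValueError):
    """The no-signal reference run produced a zero LacZ readout."""


class NonIdentifiableError(ValueError):
    """Dose-response data carry no dose dependence; (f, theta) cannot be fit."""


class NoCompatibleWeightError(ValueError):
    """No scanned crosstalk weight reproduces the observed activation landscape."""
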