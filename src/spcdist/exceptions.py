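"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Invalid input data or arguments."""


class DomainError(ValidationError):
    """A time point lies outside the curve domain [T_L, T_U]."""


class DegenerateDesignError(RuntimeError):
    """The fixed-effect design is singular (e.g. coincident time points)."""


class SmoothingBoundaryWarning(UserWarning):
    """The REML optimizer hit the search-box boundary; theta was clipped."""
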