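"""Exception types shared across the package."""


class InputDomainError(ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class GridConstructionError(ValueError):
    """A radiosensitivity grid could not be built (support crosses beta<=0, empty support, ...)."""


class FitError(RuntimeError):
    """Assay fitting failed (under-determined problem or optimizer breakdown)."""
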