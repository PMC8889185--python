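"""Package-specific exception types."""


class ConfigurationError(ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class DensityNotReachedError(RuntimeError):
    """The interaction log cannot support a binary network of the requested size.

    Carries the edge count actually achieved so callers can decide whether to
    retry with a fresh simulation or lower the target.
    """

    def __init__(self, target: int, achieved: int, counting: str = "dyads"):
        self.target = target
        self.achieved = achieved
        self.counting = counting
        super().__init__(
            f"binary network reached only {achieved} edges "
            f"({counting} counting) over the full log; target was {target}"
        )


class UndefinedMetricError(RuntimeError):
    """A summary statistic is undefined for this input (e.g. no eligible triangles)."""
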