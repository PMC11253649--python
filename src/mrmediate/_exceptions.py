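"""Exception types shared across the package."""


class SummaryStatsFormatError(ValueError):
    """A summary-statistics file is structurally unusable (e.g. missing a mandatory column)."""


class InsufficientInstrumentsError(ValueError):
    """An estimator was given fewer instruments than its minimum.

    Carries ``required`` and ``given`` so pipelines can degrade gracefully
    (e.g. fall back from IVW to the single-SNP Wald ratio).
    """

    def __init__(self, method: str, required: int, given: int):
        self.method = method
        self.required = required
        self.given = given
        super().__init__(
            f"{method} requires at least {required} instruments, got {given}"
            + (" (use wald_ratio for a single SNP)" if method == "ivw" and given == 1 else "")
        )
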