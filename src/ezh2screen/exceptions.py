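"""Package-wide exception types."""


class Ezh2ScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(Ezh2ScreenError):
    """Input failed validation.

    Carries a list of human-readable messages (one per violation) so
    loaders can aggregate every problem in a file before failing.
    """

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class DegenerateDataError(Ezh2ScreenError):
    """A statistic is undefined on this input (e.g. zero-variance rater)."""


class UndefinedVAFError(Ezh2ScreenError):
    """VAF requested for a site with zero total reads."""
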