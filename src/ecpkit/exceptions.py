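"""Exception types shared across the toolkit."""


class FormatError(ValueError):
    """A file is missing required metadata or is otherwise malformed."""


class DegenerateSignalError(ValueError):
    """A signal has no usable variance/mean, so a detection threshold cannot be formed."""


class PeriodicityError(ValueError):
    """No periodic peak grid could be established from the candidate peaks."""
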