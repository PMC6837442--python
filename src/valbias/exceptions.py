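"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """Raised when an operation is called with arguments violating its contract.

    The message always names the violated constraint so callers (and the CLI)
    can surface actionable errors.
    """
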