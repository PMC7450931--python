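class ValidationError(ValueError):
    """Raised when a configuration or input fails validation.

    The message always names the offending field or column so callers
    (and the CLI, which maps this to exit code 2) can report it directly.
    """
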