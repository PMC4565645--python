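"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """A tabular input file does not have the expected layout."""


class IntegrityError(ValueError):
    """Input data violates a structural invariant (e.g. duplicate keys)."""


class DegenerateDataError(ValueError):
    """A fit cannot be performed because the data carry no usable variation."""


class ConfigurationError(ValueError):
    """A configuration value is invalid or internally inconsistent."""


class EmptyGroupError(ValueError):
    """A requested city group contains no members."""
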