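"""Exception hierarchy shared across the package."""


class BacHbpredError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BacHbpredError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(BacHbpredError):
    """A sequence or dataset violates an invariant."""


class ModelError(BacHbpredError):
    """A trained model is inconsistent with the data it is applied to."""
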