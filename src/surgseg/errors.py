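"""Exception types used across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(ValueError):
    """A trial or segmentation container is malformed; the message names the offending field."""


class EmptyClusterError(RuntimeError):
    """A cluster lost all its segments; callers re-seed instead of crashing."""


class ExperimentError(RuntimeError):
    """No run of an experiment sweep completed successfully."""
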