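"""Package-specific exception types."""


class InvalidConfigError(ValueError):
    """A simulation or clustering configuration is internally inconsistent
    or infeasible (e.g. a non-positive-definite correlation block, or a
    disjoint disease assignment that cannot satisfy the per-cluster minimum)."""


class EmptyCohortError(ValueError):
    """A filtering step removed every patient; clustering is undefined on
    an empty cohort."""
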