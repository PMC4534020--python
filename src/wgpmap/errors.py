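"""Exception and warning types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A parameter is outside its documented domain."""


class EmptyInputError(ValueError):
    """An operation that requires data received none."""


class UndefinedEstimateError(ValueError):
    """An estimator has no informative observations to work with."""


class PipelineWarning(UserWarning):
    """Base class for structured warnings emitted by pipeline stages."""


class SplitLoopWarning(PipelineWarning):
    """Q-contig re-assembly hit its iteration cap without converging."""


class ContiguityWarning(PipelineWarning):
    """Loci sharing a deletion-line pattern are not contiguous on the map."""


class DisconnectedContigWarning(PipelineWarning):
    """A contig's consensus-band map has a coverage gap."""
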