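"""Exception hierarchy shared across the pipeline stages."""


class LoopMSMError(Exception):
    """Base class for all pipeline errors."""


class TopologyError(LoopMSMError):
    """Trajectory/topology atom-count or structure mismatch."""


class FormatError(LoopMSMError):
    """Unreadable or unsupported file format."""


class SelectionError(LoopMSMError):
    """A residue-range selection could not be resolved."""


class FeaturizationError(LoopMSMError):
    """A dihedral angle could not be computed (missing atoms)."""


class EstimationError(LoopMSMError):
    """A statistical estimator received inadequate data."""


class ProjectionError(LoopMSMError):
    """Feature dimensionality does not match the model."""


class MappingError(LoopMSMError):
    """Atom/feature correspondence with an external structure failed."""


class NumericalError(LoopMSMError):
    """An iterative solver failed to converge or produced NaNs."""


class DegenerateDataError(LoopMSMError):
    """Input data is degenerate (e.g. zero variance) for the requested op."""
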