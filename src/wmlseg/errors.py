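"""Exception types shared across the pipeline."""


class WmlsegError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleSpecError(WmlsegError):
    """A requested lesion load cannot fit in the phantom geometry."""


class InvalidVolumeError(WmlsegError):
    """A lesion volume is negative or otherwise nonsensical."""


class NoBrainContentError(WmlsegError):
    """Slice selection found no slice containing brain tissue."""


class AlignmentError(WmlsegError):
    """Arrays that must share one grid have mismatched shapes."""


class GeometryError(WmlsegError):
    """Voxel geometry is invalid (non-positive spacing, indivisible side)."""


class ModalityMissingError(WmlsegError):
    """A variant needs a modality (DWI) that the cohort does not provide."""


class NoDataError(WmlsegError):
    """An empty training set was supplied."""


class DivergenceError(WmlsegError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


class DegenerateDesignError(WmlsegError):
    """Regression design matrix is rank-deficient (all-identical WMLV)."""


class ConfigurationError(WmlsegError):
    """Inconsistent model/variant configuration."""
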