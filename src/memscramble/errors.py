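"""Exception hierarchy shared across the package."""


class MemscrambleError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(MemscrambleError):
    """A bead role or residue record could not be resolved."""


class FormatError(MemscrambleError):
    """An on-disk file is malformed or inconsistent with its topology."""


class SelectionError(MemscrambleError):
    """A residue/chain/bead selection is empty or undefined."""


class AlignmentError(MemscrambleError):
    """Structural alignment is degenerate (e.g. isotropic selection)."""


class EmptyTrajectoryError(MemscrambleError):
    """An operation would leave no frames to analyse."""


class ScheduleError(MemscrambleError):
    """A synthetic flip/tracer schedule is self-inconsistent."""


class BilayerSpecError(MemscrambleError):
    """A synthetic bilayer specification cannot be realised."""


class SurfaceError(MemscrambleError):
    """No valid grid nodes remain after occupancy/cluster filtering."""


class DensityPathError(MemscrambleError):
    """A maximum-density pathway could not be constructed."""


class ConsistencyError(MemscrambleError):
    """Inputs from different pipeline stages do not refer to the same data."""
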