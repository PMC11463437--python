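"""Analysis configuration.

All fixed constants of the pipeline live in :class:`AnalysisConfig` so that
every stage (scrambling detection, surface averaging, contacts, permeation)
draws its thresholds from a single validated object.  Defaults correspond to
the standard protocol for 10 us Martini trajectories of TMEM16 scramblases
sampled at 1 frame/ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

from .errors import MemscrambleError

#: Per-homolog TM4/TM6 residue ranges (inclusive) used for groove dilation.
TM_RANGES: dict[str, dict[str, tuple[int, int]]] = {
    "nhTMEM16": {"TM4": (327, 339), "TM6": (430, 452)},
    "afTMEM16": {"TM4": (319, 331), "TM6": (426, 438)},
    "TMEM16K": {"TM4": (365, 377), "TM6": (434, 446)},
    "TMEM16F": {"TM4": (512, 524), "TM6": (613, 625)},
    "TMEM16A": {"TM4": (541, 553), "TM6": (635, 647)},
}


@dataclass
class AnalysisConfig:
    """Tunable parameters for the full analysis pipeline.

    Units are Angstrom, nanosecond, degree and Kelvin throughout.
    """

    equilibration_ns: float = 1000.0
    #: far-side thresholds completing a leaflet transition
    angle_lower_deg: float = 35.0
    angle_upper_deg: float = 145.0
    #: reference (resting) angles of the two leaflets
    leaflet_lower_ref_deg: float = 30.0
    leaflet_upper_ref_deg: float = 150.0
    running_average_ns: float = 100.0
    block_ns: float = 1000.0
    contact_cutoff_A: float = 7.0
    dwell_gap_ns: float = 6.0
    groove_open_threshold_A: float = 6.0
    thickness_threshold_A: float = 14.0
    in_groove_cutoff_A: float = 4.7
    surface_spacing_A: float = 1.0
    surface_occupancy_min: float = 0.02
    density_extent_A: tuple[float, float, float] = (100.0, 100.0, 150.0)
    density_spacing_A: float = 0.5
    ewma_factor: float = 0.1
    temperature_K: float = 310.0
    tube_radius_A: float = 8.0
    tm_ranges: Mapping[str, Mapping[str, tuple[int, int]]] = field(
        default_factory=lambda: {h: dict(r) for h, r in TM_RANGES.items()}
    )

    def __post_init__(self) -> None:
        lengths = (
            self.contact_cutoff_A,
            self.groove_open_threshold_A,
            self.thickness_threshold_A,
            self.in_groove_cutoff_A,
            self.surface_spacing_A,
            self.density_spacing_A,
            self.tube_radius_A,
            self.running_average_ns,
            self.block_ns,
            self.dwell_gap_ns,
        )
        if any(v <= 0 for v in lengths):
            raise MemscrambleError("all lengths/windows must be positive")
        if any(v <= 0 for v in self.density_extent_A):
            raise MemscrambleError("density grid extent must be positive")
        if not self.angle_lower_deg < self.angle_upper_deg:
            raise MemscrambleError("lower angle threshold must be < upper")
        if self.equilibration_ns < 0:
            raise MemscrambleError("equilibration cutoff must be >= 0")
        if not 0 <= self.surface_occupancy_min <= 1:
            raise MemscrambleError("occupancy threshold must be in [0, 1]")
        if not 0 < self.ewma_factor <= 1:
            raise MemscrambleError("EWMA factor must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "density_extent_A" in known:
            known["density_extent_A"] = tuple(known["density_extent_A"])
        return cls(**known)
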