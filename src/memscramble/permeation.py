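"""Water and ion permeation counting along a membrane-spanning pathway.

A particle completes a permeation event when it moves from below the lower
slab boundary to above the upper one (or the reverse) while every frame it
spends inside the slab lies within a lateral tube radius of the pathway
polyline.  Particles that leave the tube mid-slab, or return to their
origin side, are not counted; re-entering the slab restarts the state
machine.  Cation-to-anion selectivity is the ratio of total Na to Cl event
counts, flagged when either count is below 10 (prone to statistical error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MemscrambleError
from .trajio import Trajectory


@dataclass
class PermeationEvent:
    particle_id: int
    species: str  # water | Na | Cl
    direction: str  # up | down
    entry_time: float
    exit_time: float


@dataclass
class SelectivitySummary:
    counts: dict[str, int] = field(default_factory=dict)
    ratio_na_cl: float | None = None
    low_count: bool = False

    @property
    def ratio_defined(self) -> bool:
        return self.ratio_na_cl is not None


def count_permeation(
    traj: Trajectory,
    particle_indices: np.ndarray,
    polyline: np.ndarray,
    z_lower: float,
    z_upper: float,
    tube_radius: float = 8.0,
    species: str = "water",
) -> list[PermeationEvent]:
    """Count completed through-slab transits of the given particles."""
    if z_lower >= z_upper:
        raise MemscrambleError("slab bounds inverted (z_lower >= z_upper)")
    poly = np.asarray(polyline, dtype=float)
    events: list[PermeationEvent] = []
    times = traj.times
    for pid in np.asarray(particle_indices, dtype=int):
        z = traj.coords[:, pid, 2]
        side = np.where(z < z_lower, -1, np.where(z > z_upper, 1, 0))
        inside = side == 0
        tube_ok_frame = np.ones(traj.n_frames, dtype=bool)
        if inside.any():
            pos = traj.coords[inside, pid, :]
            d = np.linalg.norm(
                pos[:, None, :] - poly[None, :, :], axis=2
            ).min(axis=1)
            tube_ok_frame[inside] = d <= tube_radius
        origin = 0
        entry_t = times[0]
        transit_ok = True
        for f in range(traj.n_frames):
            s = side[f]
            if s == 0:
                if origin != 0 and not tube_ok_frame[f]:
                    transit_ok = False
                continue
            if origin == 0:
                origin, entry_t, transit_ok = s, times[f], True
                continue
            if s == origin:
                entry_t, transit_ok = times[f], True  # returned: restart
                continue
            # crossed to the far side
            if transit_ok:
                events.append(
                    PermeationEvent(
                        particle_id=int(pid),
                        species=species,
                        direction="up" if origin == -1 else "down",
                        entry_time=float(entry_t),
                        exit_time=float(times[f]),
                    )
                )
            origin, entry_t, transit_ok = s, times[f], True
    events.sort(key=lambda e: e.exit_time)
    return events


def selectivity(events: list[PermeationEvent]) -> SelectivitySummary:
    """Per-species counts and the P_Na/P_Cl count ratio."""
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.species] = counts.get(ev.species, 0) + 1
    na = counts.get("Na", 0)
    cl = counts.get("Cl", 0)
    ratio = None if cl == 0 else na / cl
    return SelectivitySummary(
        counts=counts,
        ratio_na_cl=ratio,
        low_count=(na < 10 or cl < 10),
    )
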