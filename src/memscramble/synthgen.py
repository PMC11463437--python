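"""Synthetic coarse-grained bilayer trajectories with known ground truth.

The generator emulates a DOPC-like Martini bilayer (glycerol-to-glycerol
separation 30 A by default) in which every analysis observable is scripted:
leaflet-exchange (flip) events with prescribed timing and 3D paths, partial
excursions that must *not* count as events, a static protein scaffold whose
walls define TM4/TM6 groove and TM3/TM10 dimer-cleft sites, a smooth local
thinning field, and tracer particles with scripted membrane crossings.

Each lipid is a rigid six-bead template (NC3, PO4, GL1, GL2, C4A, C4B)
placed on a jittered lattice; the NC3->tail vector of an upper-leaflet lipid
points toward -z (orientation angle 180 deg), mirrored for the lower
leaflet.  Identical spec + seed gives a bit-identical trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import BilayerSpecError, ScheduleError, SelectionError
from .trajio import LipidRecord, ResidueRecord, Topology, Trajectory

# Rigid lipid template, local frame with the lipid "up" axis = +z and the
# origin on the glycerol plane.  Lateral offsets of C4A/C4B cancel so the
# mean tail position sits exactly below NC3 (orientation angle exactly
# 180 deg at zero noise).
_HEAD_OFFSET = 8.0   # NC3 above the glycerol plane (A)
_PO4_OFFSET = 5.0
_TAIL_LENGTH = 13.0  # terminal tail beads below the glycerol plane (A)

_LOCAL_OFFSETS = {
    "NC3": (0.0, 0.0, _HEAD_OFFSET),
    "PO4": (0.0, 0.0, _PO4_OFFSET),
    "GL1": (0.6, 0.0, 0.0),
    "GL2": (-0.6, 0.0, 0.0),
    "C4A": (1.0, 0.0, -_TAIL_LENGTH),
    "C4B": (-1.0, 0.0, -_TAIL_LENGTH),
}
_ROLE_ORDER = ("NC3", "PO4", "GL1", "GL2", "C4A", "C4B")


@dataclass
class BilayerSpec:
    """Parameters of the synthetic bilayer."""

    lipids_per_leaflet: int = 64
    box_xy: float = 80.0
    box_z: float = 100.0
    glycerol_separation: float = 30.0
    headgroup_offset: float = _HEAD_OFFSET
    tail_length: float = _TAIL_LENGTH
    noise_sigma: float = 0.0
    #: per-frame rigid lateral displacement of each whole lipid (diffusion
    #: within the sampling interval); does not perturb orientation angles.
    lateral_sigma: float = 1.2
    #: optional local thinning h(x, y) >= 0 (vectorised over arrays);
    #: glycerol planes sit at +/- (d - h)/2, so the local separation is
    #: d - h(x, y), and lipids track the field at their jittered position.
    thickness_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.glycerol_separation <= 0:
            raise BilayerSpecError("glycerol separation must be > 0")
        if self.lipids_per_leaflet <= 0:
            raise BilayerSpecError("need at least one lipid per leaflet")
        if self.noise_sigma < 0 or self.lateral_sigma < 0:
            raise BilayerSpecError("noise sigmas must be >= 0")
        if self.box_xy <= 0 or self.box_z <= 0:
            raise BilayerSpecError("box lengths must be > 0")


@dataclass
class Flip:
    """One scripted complete leaflet transition."""

    lipid_id: int
    start_ns: float
    duration_ns: float = 20.0
    direction: str = "down"  # down: upper->lower, up: lower->upper
    #: optional 3D waypoints for the lipid centre during the flip
    path: Sequence[tuple[float, float, float]] | None = None


@dataclass
class Excursion:
    """A partial tilt that returns to the origin leaflet (never an event)."""

    lipid_id: int
    start_ns: float
    duration_ns: float = 60.0
    max_angle_deg: float = 60.0  # most extreme orientation angle reached


@dataclass
class FlipSchedule:
    flips: list[Flip] = field(default_factory=list)
    excursions: list[Excursion] = field(default_factory=list)

    def validate(self) -> None:
        per_lipid: dict[int, list[tuple[float, float]]] = {}
        for item in list(self.flips) + list(self.excursions):
            if item.duration_ns <= 0:
                raise ScheduleError("durations must be > 0")
            per_lipid.setdefault(item.lipid_id, []).append(
                (item.start_ns, item.start_ns + item.duration_ns)
            )
        for lid, spans in per_lipid.items():
            spans.sort()
            for (a0, a1), (b0, _) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ScheduleError(
                        f"overlapping scripted motions for lipid {lid}"
                    )


@dataclass
class TracerSpec:
    """Scripted membrane crossings for water or ion tracers."""

    species: str = "water"  # water | Na | Cl
    crossings: list[tuple[float, float]] = field(default_factory=list)
    # each crossing: (start_ns, duration_ns); alternate directions start down
    start_above: bool = True
    wanderers: int = 0
    lateral_jitter: float = 0.3
    seed: int = 0


# ---------------------------------------------------------------------------
# bilayer construction
# ---------------------------------------------------------------------------

def _lattice_sites(spec: BilayerSpec) -> np.ndarray:
    """Jitter-free lattice with one site exactly at the box centre."""
    n = spec.lipids_per_leaflet
    m = math.ceil(math.sqrt(n))
    if m % 2 == 0:
        m += 1
    spacing = spec.box_xy / m
    if spacing < 3.0:
        raise BilayerSpecError(
            f"{n} lipids per leaflet do not fit a {spec.box_xy} A box"
        )
    axis = (np.arange(m) - (m - 1) / 2) * spacing + spec.box_xy / 2
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    sites = np.column_stack([xx.ravel(), yy.ravel()])
    centre = np.array([spec.box_xy / 2, spec.box_xy / 2])
    order = np.argsort(np.linalg.norm(sites - centre, axis=1), kind="stable")
    return sites[order[:n]]


def _rotation_about_y(alpha: float) -> np.ndarray:
    c, s = math.cos(alpha), math.sin(alpha)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _lipid_beads(centre: np.ndarray, alpha: float, spec: BilayerSpec) -> np.ndarray:
    """Bead positions for one lipid; ``alpha`` = tilt of the up-axis from +z."""
    offs = np.array([_local_offsets(spec)[r] for r in _ROLE_ORDER])
    return centre + offs @ _rotation_about_y(alpha).T


def _local_offsets(spec: BilayerSpec) -> dict[str, tuple[float, float, float]]:
    offs = dict(_LOCAL_OFFSETS)
    offs["NC3"] = (0.0, 0.0, spec.headgroup_offset)
    offs["C4A"] = (1.0, 0.0, -spec.tail_length)
    offs["C4B"] = (-1.0, 0.0, -spec.tail_length)
    return offs


def _half_separation(spec: BilayerSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = spec.glycerol_separation
    if spec.thickness_field is None:
        return np.full(np.shape(x), d / 2.0)
    return (d - np.asarray(spec.thickness_field(x, y), dtype=float)) / 2.0


def make_bilayer(
    spec: BilayerSpec, n_frames: int, frame_spacing_ns: float = 1.0
) -> Trajectory:
    """Build a bilayer trajectory: jittered lattice, scripted geometry.

    Lipids are rigid templates on a lattice; per frame each lipid takes a
    rigid lateral displacement (``lateral_sigma``) and its glycerol plane
    height follows the thickness field at the displaced position, so
    orientation angles and local plane heights stay exact at zero per-bead
    noise.
    """
    spec.validate()
    sites = _lattice_sites(spec)
    n_per = spec.lipids_per_leaflet
    n_lip = 2 * n_per
    n_beads = 6 * n_lip
    lipids: list[LipidRecord] = []
    names: list[str] = []
    centres = np.empty((n_lip, 3))
    axis_sign = np.empty(n_lip)
    offs = {}  # per-leaflet rotated local offsets, (6, 3)
    base_offsets = np.array([_local_offsets(spec)[r] for r in _ROLE_ORDER])
    offs[1.0] = base_offsets @ _rotation_about_y(0.0).T
    offs[-1.0] = base_offsets @ _rotation_about_y(math.pi).T
    for k in range(n_lip):
        upper = k < n_per
        x, y = sites[k % n_per]
        sign = 1.0 if upper else -1.0
        z = sign * float(_half_separation(spec, np.asarray(x), np.asarray(y)))
        centres[k] = (x, y, z)
        axis_sign[k] = sign
        beads = {r: 6 * k + j for j, r in enumerate(_ROLE_ORDER)}
        lipids.append(LipidRecord(k, beads, "upper" if upper else "lower"))
        names.extend(_ROLE_ORDER)

    top = Topology(n_beads=n_beads, bead_names=names, lipids=lipids)
    rng = np.random.default_rng(spec.seed)
    xy = np.broadcast_to(
        np.concatenate([sites, sites], axis=0), (n_frames, n_lip, 2)
    ).copy()
    if spec.lateral_sigma > 0:
        xy += rng.normal(0.0, spec.lateral_sigma, xy.shape)
    half = _half_separation(spec, xy[..., 0], xy[..., 1])  # (F, n_lip)
    cen = np.empty((n_frames, n_lip, 3))
    cen[..., :2] = xy
    cen[..., 2] = half * axis_sign
    offsets_per_lipid = np.stack(
        [offs[s] for s in axis_sign], axis=0
    )  # (n_lip, 6, 3)
    coords = (
        cen[:, :, None, :] + offsets_per_lipid[None, :, :, :]
    ).reshape(n_frames, n_beads, 3)
    if spec.noise_sigma > 0:
        coords += rng.normal(0.0, spec.noise_sigma, coords.shape)
    times = np.arange(n_frames, dtype=float) * frame_spacing_ns
    box = np.array([spec.box_xy, spec.box_xy, spec.box_z])
    traj = Trajectory(coords, times, box, top)
    traj.meta = {
        "generator": "make_bilayer",
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "lateral_sigma": spec.lateral_sigma,
        "glycerol_separation": spec.glycerol_separation,
        "headgroup_offset": spec.headgroup_offset,
        "tail_length": spec.tail_length,
        "lipid_centres": centres,
        "lipid_axis_sign": axis_sign,
    }
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# scripted flips
# ---------------------------------------------------------------------------

def _path_points(
    start: np.ndarray, end: np.ndarray,
    path: Sequence[tuple[float, float, float]] | None,
) -> np.ndarray:
    pts = [np.asarray(start, dtype=float)]
    if path:
        pts.extend(np.asarray(p, dtype=float) for p in path)
    else:
        pts.append(np.asarray(end, dtype=float))
    return np.asarray(pts)


def _interp_along(points: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Arc-length interpolation along a polyline at fractions u in [0, 1]."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        return np.broadcast_to(points[0], (len(u), 3)).copy()
    s = np.concatenate([[0.0], np.cumsum(seg)]) / total
    out = np.empty((len(u), 3))
    for d in range(3):
        out[:, d] = np.interp(u, s, points[:, d])
    return out


def apply_flips(traj: Trajectory, schedule: FlipSchedule) -> Trajectory:
    """Overwrite scripted lipids' coordinates to realise the schedule.

    Flipping lipids move their centre along the (default: vertical) waypoint
    path while the lipid axis rotates continuously, so the orientation-angle
    trace sweeps from one leaflet's resting angle through 90 deg to beyond
    the far threshold.  Excursions tilt toward ``max_angle_deg`` and return.
    """
    schedule.validate()
    meta = traj.meta
    if "lipid_centres" not in meta:
        raise ScheduleError("trajectory lacks generator metadata")
    spec = BilayerSpec(
        glycerol_separation=float(meta["glycerol_separation"]),
        headgroup_offset=float(meta["headgroup_offset"]),
        tail_length=float(meta["tail_length"]),
        noise_sigma=float(meta["noise_sigma"]),
        lateral_sigma=float(meta.get("lateral_sigma", 0.0)),
        seed=int(meta["seed"]),
    )
    out = traj.copy()
    times = out.times
    by_lipid: dict[int, list] = {}
    for f in schedule.flips:
        by_lipid.setdefault(f.lipid_id, []).append(f)
    for e in schedule.excursions:
        by_lipid.setdefault(e.lipid_id, []).append(e)

    truth: list[dict] = []
    for lid, items in sorted(by_lipid.items()):
        rec = out.topology.lipid(lid)
        items.sort(key=lambda it: it.start_ns)
        centre = np.asarray(meta["lipid_centres"])[lid].copy()
        sign = float(np.asarray(meta["lipid_axis_sign"])[lid])
        # alpha: tilt of the lipid up-axis from +z (0 = upper resting)
        alpha0 = 0.0 if sign > 0 else math.pi
        centres_t = np.broadcast_to(centre, (len(times), 3)).copy()
        alphas_t = np.full(len(times), alpha0)
        for it in items:
            t0, t1 = it.start_ns, it.start_ns + it.duration_ns
            during = (times >= t0) & (times <= t1)
            after = times > t1
            u = np.clip((times[during] - t0) / it.duration_ns, 0.0, 1.0)
            if isinstance(it, Flip):
                going_down = it.direction == "down"
                if going_down != (alpha0 == 0.0):
                    raise ScheduleError(
                        f"flip direction {it.direction!r} inconsistent with "
                        f"lipid {lid} leaflet at t={t0} ns"
                    )
                end = centre.copy()
                end[2] = -centre[2]
                pts = _path_points(centre, end, it.path)
                centres_t[during] = _interp_along(pts, u)
                centres_t[after] = pts[-1]
                a_end = math.pi - alpha0
                alphas_t[during] = alpha0 + (a_end - alpha0) * u
                alphas_t[after] = a_end
                truth.append(
                    {"lipid_id": lid, "t_complete": t1,
                     "direction": "upper_to_lower" if going_down else "lower_to_upper"}
                )
                centre, alpha0 = pts[-1].copy(), a_end
            else:  # Excursion
                rest_theta = 180.0 if alpha0 == 0.0 else 0.0
                tilt = math.radians(abs(rest_theta - it.max_angle_deg))
                tri = 1.0 - np.abs(2.0 * u - 1.0)
                alphas_t[during] = alpha0 + (tilt if alpha0 == 0.0 else -tilt) * tri
        # rebuild bead coordinates for this lipid over all frames
        offs = np.array([_local_offsets(spec)[r] for r in _ROLE_ORDER])
        idx = np.array([rec.beads[r] for r in _ROLE_ORDER])
        cos_a, sin_a = np.cos(alphas_t), np.sin(alphas_t)
        rot = np.zeros((len(times), 3, 3))
        rot[:, 0, 0] = cos_a
        rot[:, 0, 2] = sin_a
        rot[:, 1, 1] = 1.0
        rot[:, 2, 0] = -sin_a
        rot[:, 2, 2] = cos_a
        beads = centres_t[:, None, :] + np.einsum("fij,bj->fbi", rot, offs)
        rng = np.random.default_rng([int(meta["seed"]), 1000003, lid])
        if spec.lateral_sigma > 0:
            beads[..., :2] += rng.normal(
                0.0, spec.lateral_sigma, (len(times), 1, 2)
            )
        if spec.noise_sigma > 0:
            beads = beads + rng.normal(0.0, spec.noise_sigma, beads.shape)
        out.coords[:, idx, :] = beads
    out.meta = dict(meta)
    out.meta["scripted_events"] = truth
    return out


# ---------------------------------------------------------------------------
# protein scaffold
# ---------------------------------------------------------------------------

def add_protein_scaffold(
    traj: Trajectory,
    groove_center: tuple[float, float],
    groove_width: float | np.ndarray = 6.0,
    cleft_center: tuple[float, float] | None = None,
    cleft_width: float = 10.0,
    z_extent: tuple[float, float] = (-18.0, 18.0),
    residues_per_wall: int = 13,
) -> Trajectory:
    """Append a static scaffold: TM4/TM6 groove walls and a TM3/TM10 cleft.

    Walls are vertical bead columns along z separated by ``groove_width``
    (scalar, or a per-frame array for piecewise-varying dilation) along x.
    Residue numbering follows the nhTMEM16 groove registry (TM4 327-,
    TM6 430-) so downstream range selections work unmodified.
    """
    gx, gy = groove_center
    box = traj.box[0]
    for cx, cy in [(gx, gy)] + ([cleft_center] if cleft_center else []):
        if not (0 <= cx <= box[0] and 0 <= cy <= box[1]):
            raise SelectionError("scaffold centre outside the box")
    width = np.asarray(groove_width, dtype=float)
    if width.ndim == 0:
        width = np.full(traj.n_frames, float(width))
    elif width.shape != (traj.n_frames,):
        raise ScheduleError("per-frame groove width must match frame count")

    zs = np.linspace(z_extent[0], z_extent[1], residues_per_wall)
    walls = [
        ("TM4", "A", 327, -1.0, gy),
        ("TM6", "A", 430, +1.0, gy),
    ]
    if cleft_center is not None:
        cx, cy = cleft_center
        walls += [
            ("TM3", "A", 341, -1.0, cy),
            ("TM10", "B", 701, +1.0, cy),
        ]

    n_old = traj.n_beads
    new_names: list[str] = []
    new_res: list[ResidueRecord] = []
    cols: list[np.ndarray] = []  # per-bead (n_frames, 3)
    bead = n_old
    for tm, chain, resid0, side, wy in walls:
        if tm in ("TM3", "TM10"):
            wx = cleft_center[0] + side * cleft_width / 2.0
            x_t = np.full(traj.n_frames, wx)
        else:
            x_t = gx + side * width / 2.0
        for j, z in enumerate(zs):
            # backbone bead on the wall line
            pos = np.column_stack(
                [x_t, np.full(traj.n_frames, wy), np.full(traj.n_frames, z)]
            )
            cols.append(pos)
            new_names.append("BB")
            bb = bead
            bead += 1
            if j % 4 == 3:  # every fourth residue is glycine-like (no side chain)
                side_beads: list[int] = []
            else:
                off = np.array([0.0, 0.8, 0.0])
                cols.append(pos + off)
                new_names.append("SC1")
                side_beads = [bead]
                bead += 1
            new_res.append(ResidueRecord(resid0 + j, chain, bb, side_beads, tm))

    extra = np.stack(cols, axis=1)  # (n_frames, n_new, 3)
    out_coords = np.concatenate([traj.coords, extra], axis=1)
    top = traj.topology
    new_top = Topology(
        n_beads=bead,
        bead_names=top.bead_names + new_names,
        lipids=top.lipids,
        residues=top.residues + new_res,
        waters=top.waters,
        ions=top.ions,
    )
    out = Trajectory(out_coords, traj.times.copy(), traj.box.copy(), new_top,
                     dict(traj.meta))
    out.meta["groove_center"] = np.array([gx, gy])
    if cleft_center is not None:
        out.meta["cleft_center"] = np.array(list(cleft_center))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# tracers
# ---------------------------------------------------------------------------

def add_tracers(
    traj: Trajectory,
    spec: TracerSpec,
    path_xy: tuple[float, float] | None = None,
    z_top: float = 25.0,
    z_bottom: float = -25.0,
) -> Trajectory:
    """Append tracer beads with scripted through-membrane crossings.

    Each scripted tracer sits in one bath, traverses from ``z_top`` to
    ``z_bottom`` (alternating direction per crossing) along the registered
    groove path over its crossing window, then stays in the far bath.
    Wanderers random-walk in the upper bath and never cross.
    """
    for t0, dur in spec.crossings:
        if t0 < traj.times[0] or t0 + dur > traj.times[-1]:
            raise ScheduleError("crossing outside the trajectory time span")
    if path_xy is None:
        gc = traj.meta.get("groove_center")
        if gc is None:
            raise ScheduleError("no path registered; pass path_xy")
        path_xy = (float(gc[0]), float(gc[1]))
    rng = np.random.default_rng([int(spec.seed), 77])
    times = traj.times
    n_frames = traj.n_frames
    cols: list[np.ndarray] = []
    names: list[str] = []
    for k, (t0, dur) in enumerate(spec.crossings):
        down = (k % 2 == 0) == spec.start_above
        z_from = z_top + 6.0 if down else z_bottom - 6.0
        z_to = z_bottom - 6.0 if down else z_top + 6.0
        z = np.full(n_frames, z_from)
        during = (times >= t0) & (times <= t0 + dur)
        u = (times[during] - t0) / dur
        z[during] = z_from + (z_to - z_from) * u
        z[times > t0 + dur] = z_to
        xy = np.asarray(path_xy) + rng.normal(
            0.0, spec.lateral_jitter, (n_frames, 2)
        )
        cols.append(np.column_stack([xy, z]))
        names.append(_tracer_name(spec.species))
    for _ in range(spec.wanderers):
        steps = rng.normal(0.0, 0.8, (n_frames, 3))
        pos = np.cumsum(steps, axis=0)
        pos[:, 0] += rng.uniform(0, traj.box[0, 0])
        pos[:, 1] += rng.uniform(0, traj.box[0, 1])
        pos[:, 2] = z_top + 8.0 + np.abs(pos[:, 2])  # confined above the slab
        cols.append(pos)
        names.append(_tracer_name(spec.species))

    if not cols:
        return traj.copy()
    extra = np.stack(cols, axis=1)
    n_old = traj.n_beads
    idx = list(range(n_old, n_old + len(cols)))
    top = traj.topology
    waters = list(top.waters)
    ions = list(top.ions)
    if spec.species == "water":
        waters.extend(idx)
    else:
        ions.extend((i, spec.species) for i in idx)
    new_top = Topology(
        n_beads=n_old + len(cols),
        bead_names=top.bead_names + names,
        lipids=top.lipids,
        residues=top.residues,
        waters=waters,
        ions=ions,
    )
    out = Trajectory(
        np.concatenate([traj.coords, extra], axis=1),
        traj.times.copy(), traj.box.copy(), new_top, dict(traj.meta),
    )
    out.validate()
    return out


def _tracer_name(species: str) -> str:
    return {"water": "W", "Na": "NA", "Cl": "CL", "Ca": "CA"}[species]
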