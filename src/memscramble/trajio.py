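"""Trajectory/topology data model, alignment, and readers/writers.

The in-memory model is deliberately small: a :class:`Trajectory` holds a
``(frames, beads, 3)`` coordinate array in Angstrom, times in nanoseconds on a
uniform grid, per-frame orthorhombic box lengths, and a :class:`Topology`
describing which beads belong to lipids (with their Martini roles NC3, PO4,
GL1, GL2, C4A, C4B), protein residues, waters and ions.

Standard MD formats (GRO/PDB snapshots, XTC/DCD frames) are read through
MDAnalysis; the package additionally defines a plain-text fixture format
(JSON header + extended-XYZ-like frames) that the synthetic generator writes
and that round-trips coordinates exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    EmptyTrajectoryError,
    FormatError,
    SelectionError,
    TopologyError,
)

#: Bead roles every lipid record must resolve.
LIPID_ROLES = ("NC3", "PO4", "GL1", "GL2", "C4A", "C4B")

_TIME_TOL_NS = 1e-6


@dataclass
class LipidRecord:
    """One lipid: its id, bead index per role, and the leaflet it started in."""

    lipid_id: int
    beads: dict[str, int]
    leaflet: str = "unassigned"  # upper | lower | unassigned

    def validate(self) -> None:
        missing = [r for r in LIPID_ROLES if r not in self.beads]
        if missing:
            raise TopologyError(
                f"lipid {self.lipid_id} missing bead roles: {missing}"
            )
        if len(set(self.beads[r] for r in LIPID_ROLES)) != len(LIPID_ROLES):
            raise TopologyError(f"lipid {self.lipid_id} role beads not distinct")


@dataclass
class ResidueRecord:
    """One protein residue: backbone bead, side-chain beads, chain, TM label.

    Glycine-like residues may have an empty side-chain list.
    """

    resid: int
    chain: str
    backbone: int
    sidechain: list[int] = field(default_factory=list)
    tm: str | None = None


@dataclass
class Topology:
    n_beads: int
    bead_names: list[str]
    lipids: list[LipidRecord] = field(default_factory=list)
    residues: list[ResidueRecord] = field(default_factory=list)
    waters: list[int] = field(default_factory=list)
    ions: list[tuple[int, str]] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.bead_names) != self.n_beads:
            raise TopologyError("bead name list does not match bead count")
        seen: list[int] = []
        for lip in self.lipids:
            lip.validate()
            seen.extend(lip.beads[r] for r in LIPID_ROLES)
        for res in self.residues:
            seen.append(res.backbone)
            seen.extend(res.sidechain)
        seen.extend(self.waters)
        seen.extend(i for i, _ in self.ions)
        arr = np.asarray(seen, dtype=int)
        if arr.size and (arr.min() < 0 or arr.max() >= self.n_beads):
            raise TopologyError("bead index out of range")
        if arr.size != np.unique(arr).size:
            raise TopologyError("bead indices are not globally unique")

    # -- selections -----------------------------------------------------
    def role_indices(self, role: str) -> np.ndarray:
        """Bead index of ``role`` for every lipid, in lipid order."""
        return np.asarray([l.beads[role] for l in self.lipids], dtype=int)

    @property
    def lipid_ids(self) -> np.ndarray:
        return np.asarray([l.lipid_id for l in self.lipids], dtype=int)

    def lipid(self, lipid_id: int) -> LipidRecord:
        for l in self.lipids:
            if l.lipid_id == lipid_id:
                return l
        raise SelectionError(f"no lipid with id {lipid_id}")

    @property
    def chains(self) -> list[str]:
        return sorted({r.chain for r in self.residues})

    def select_residues(
        self,
        chain: str | None = None,
        tm: str | None = None,
        resid_range: tuple[int, int] | None = None,
    ) -> list[ResidueRecord]:
        out = []
        for r in self.residues:
            if chain is not None and r.chain != chain:
                continue
            if tm is not None and r.tm != tm:
                continue
            if resid_range is not None and not (
                resid_range[0] <= r.resid <= resid_range[1]
            ):
                continue
            out.append(r)
        return out

    def residue_beads(self, residues: Iterable[ResidueRecord]) -> np.ndarray:
        """All beads (backbone + side chain) of the given residues."""
        idx: list[int] = []
        for r in residues:
            idx.append(r.backbone)
            idx.extend(r.sidechain)
        return np.asarray(idx, dtype=int)

    def ion_indices(self, species: str) -> np.ndarray:
        return np.asarray([i for i, s in self.ions if s == species], dtype=int)

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_beads": self.n_beads,
            "bead_names": self.bead_names,
            "lipids": [
                {"lipid_id": l.lipid_id, "beads": l.beads, "leaflet": l.leaflet}
                for l in self.lipids
            ],
            "residues": [
                {
                    "resid": r.resid,
                    "chain": r.chain,
                    "backbone": r.backbone,
                    "sidechain": r.sidechain,
                    "tm": r.tm,
                }
                for r in self.residues
            ],
            "waters": list(self.waters),
            "ions": [[i, s] for i, s in self.ions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            n_beads=int(d["n_beads"]),
            bead_names=list(d["bead_names"]),
            lipids=[
                LipidRecord(int(x["lipid_id"]), dict(x["beads"]), x["leaflet"])
                for x in d.get("lipids", [])
            ],
            residues=[
                ResidueRecord(
                    int(x["resid"]),
                    x["chain"],
                    int(x["backbone"]),
                    [int(i) for i in x["sidechain"]],
                    x.get("tm"),
                )
                for x in d.get("residues", [])
            ],
            waters=[int(i) for i in d.get("waters", [])],
            ions=[(int(i), s) for i, s in d.get("ions", [])],
        )


@dataclass
class Trajectory:
    """Time-ordered coarse-grained coordinates plus topology.

    ``coords`` has shape (n_frames, n_beads, 3) in Angstrom; ``times`` are ns
    on a strictly increasing uniform grid; ``box`` holds per-frame
    orthorhombic box lengths.  ``meta`` carries generator-side bookkeeping
    (e.g. ground-truth lattice positions for synthetic data) and is preserved
    by the fixture format.
    """

    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray
    topology: Topology
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.broadcast_to(self.box, (len(self.times), 3)).copy()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (frames, beads, 3)")
        f, n, _ = self.coords.shape
        if n != self.topology.n_beads:
            raise FormatError(
                f"frame bead count {n} != topology size {self.topology.n_beads}"
            )
        if self.times.shape != (f,) or self.box.shape != (f, 3):
            raise FormatError("times/box shape mismatch with frames")
        if f > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise FormatError("times must be strictly increasing")
            if np.ptp(dts) > _TIME_TOL_NS:
                raise FormatError("frame spacing must be uniform")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("coordinates must be finite")
        self.topology.validate()

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ns (1.0 for single-frame trajectories)."""
        if self.n_frames < 2:
            return 1.0
        return float(self.times[1] - self.times[0])

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.coords.copy(),
            self.times.copy(),
            self.box.copy(),
            self.topology,
            dict(self.meta),
        )

    def window_to_frames(self, window_ns: float) -> int:
        """Convert a time window to a frame count (nearest integer, >= 1)."""
        return max(1, int(round(window_ns / self.dt)))


# ---------------------------------------------------------------------------
# alignment and frame selection
# ---------------------------------------------------------------------------

def align_subunit(
    traj: Trajectory, chain: str, reference_frame: int = 0
) -> Trajectory:
    """Translate every frame so one subunit's backbone centroid is fixed.

    The shift is rigid and identical for all beads in a frame (x, y and z),
    so membrane geometry relative to the subunit is preserved; no rotational
    superposition is applied.
    """
    residues = traj.topology.select_residues(chain=chain)
    if not residues:
        raise SelectionError(f"chain {chain!r} has no residues")
    bb = np.asarray([r.backbone for r in residues], dtype=int)
    if not 0 <= reference_frame < traj.n_frames:
        raise SelectionError("reference frame out of range")
    centroids = traj.coords[:, bb, :].mean(axis=1)  # (F, 3)
    shift = centroids[reference_frame] - centroids  # (F, 3)
    out = traj.copy()
    out.coords += shift[:, None, :]
    return out


def align_membrane_frame(
    traj: Trajectory,
    residues: Sequence[ResidueRecord] | None = None,
    tm_labels: tuple[str, ...] = ("TM7", "TM8"),
    reference_frame: int = 0,
) -> Trajectory:
    """Rotate the system about z so a TM-segment principal axis lies along y.

    The rotation is computed once, from the reference frame's backbone-bead
    covariance in the xy plane, and applied to every frame (about the
    selection's xy centroid, so the protein stays in place).
    """
    if residues is None:
        residues = [
            r for r in traj.topology.residues if r.tm in tm_labels
        ]
    if not residues:
        raise SelectionError("empty residue selection for membrane alignment")
    bb = np.asarray([r.backbone for r in residues], dtype=int)
    xy = traj.coords[reference_frame][bb, :2]
    center = xy.mean(axis=0)
    cov = np.cov((xy - center).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 0 or evals[0] / evals[1] > 1.0 - 1e-9:
        raise AlignmentError("selection is isotropic in xy; axis undefined")
    v = evecs[:, 1]  # largest-variance axis
    theta = np.arctan2(v[0], v[1])  # angle from +y, positive toward +x
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])  # CCW by theta maps v onto +y
    out = traj.copy()
    xy_all = out.coords[..., :2] - center
    out.coords[..., :2] = xy_all @ rot.T + center
    return out


def discard_equilibration(traj: Trajectory, cutoff_ns: float) -> Trajectory:
    """Drop frames sampled before ``cutoff_ns``; times are not re-zeroed.

    A frame stamped at t represents the interval [t, t + dt); it is kept
    when that interval reaches past the cutoff, i.e. t + dt > cutoff.
    """
    keep = traj.times + traj.dt > cutoff_ns + 1e-9
    if not np.any(keep):
        raise EmptyTrajectoryError(
            f"equilibration cutoff {cutoff_ns} ns leaves no frames"
        )
    return Trajectory(
        traj.coords[keep], traj.times[keep], traj.box[keep], traj.topology,
        dict(traj.meta),
    )


# ---------------------------------------------------------------------------
# fixture format (plain text, exact round-trip)
# ---------------------------------------------------------------------------

_MAGIC = "#MEMSCRAMBLE-TRAJ 1"


def _bead_role_labels(top: Topology) -> list[str]:
    roles = ["-"] * top.n_beads
    for lip in top.lipids:
        for role, idx in lip.beads.items():
            roles[idx] = role
    for res in top.residues:
        roles[res.backbone] = "BB"
        for i in res.sidechain:
            roles[i] = "SC"
    for i in top.waters:
        roles[i] = "W"
    for i, s in top.ions:
        roles[i] = s
    return roles


def write_fixture(traj: Trajectory, path: str | Path) -> None:
    """Write the plain-text fixture: JSON header + per-frame XYZ blocks."""
    path = Path(path)
    header = {
        "times": [repr(float(t)) for t in traj.times],
        "box": [[repr(float(v)) for v in b] for b in traj.box],
        "topology": traj.topology.to_dict(),
        "meta": _jsonable_meta(traj.meta),
    }
    roles = _bead_role_labels(traj.topology)
    names = traj.topology.bead_names
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(json.dumps(header) + "\n")
        for f in range(traj.n_frames):
            fh.write(f"FRAME {f} {float(traj.times[f])!r}\n")
            frame = traj.coords[f]
            for b in range(traj.n_beads):
                x, y, z = frame[b]
                fh.write(
                    f"{names[b]} {roles[b]} "
                    f"{float(x)!r} {float(y)!r} {float(z)!r}\n"
                )


def _jsonable_meta(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, np.ndarray):
            out[k] = {"__ndarray__": v.tolist()}
        elif isinstance(v, (str, int, float, bool, type(None), list, dict)):
            out[k] = v
        elif isinstance(v, tuple):
            out[k] = list(v)
        # callables and other live objects are dropped on write
    return out


def _meta_from_json(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, dict) and "__ndarray__" in v:
            out[k] = np.asarray(v["__ndarray__"], dtype=float)
        else:
            out[k] = v
    return out


def read_fixture(path: str | Path) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _MAGIC:
            raise FormatError(f"{path}: not a memscramble fixture")
        header = json.loads(fh.readline())
        top = Topology.from_dict(header["topology"])
        times = np.asarray([float(t) for t in header["times"]])
        box = np.asarray([[float(v) for v in b] for b in header["box"]])
        n_frames, n_beads = len(times), top.n_beads
        coords = np.empty((n_frames, n_beads, 3))
        for f in range(n_frames):
            line = fh.readline()
            if not line.startswith("FRAME"):
                raise FormatError(f"{path}: expected FRAME header at frame {f}")
            for b in range(n_beads):
                parts = fh.readline().split()
                if len(parts) != 5:
                    raise FormatError(
                        f"{path}: bad bead line in frame {f} (bead {b})"
                    )
                coords[f, b] = [float(parts[2]), float(parts[3]), float(parts[4])]
            pos = fh.tell()
            nxt = fh.readline()
            if nxt and not nxt.startswith("FRAME"):
                raise FormatError(f"{path}: frame {f} has extra bead lines")
            fh.seek(pos)
    traj = Trajectory(coords, times, box, top, _meta_from_json(header.get("meta", {})))
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# role maps and standard MD formats (via MDAnalysis)
# ---------------------------------------------------------------------------

@dataclass
class RoleMap:
    """Mapping from file-level names to the package's bead roles.

    Parsed from a key-value text file with lines such as::

        lipid DOPC
        role NC3 NC3
        water W
        ion NA Na
        ion CL Cl
        tm TM4 327-339
    """

    lipid_resnames: set[str] = field(default_factory=lambda: {"DOPC"})
    role_names: dict[str, str] = field(
        default_factory=lambda: {r: r for r in LIPID_ROLES}
    )
    water_resnames: set[str] = field(default_factory=lambda: {"W", "WN"})
    ion_names: dict[str, str] = field(
        default_factory=lambda: {"NA": "Na", "NA+": "Na", "CL": "Cl",
                                 "CL-": "Cl", "CA": "Ca", "CA2+": "Ca"}
    )
    tm_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)


def parse_role_map(source: str | Path) -> RoleMap:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    rm = RoleMap()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0].lower()
        if key == "lipid":
            rm.lipid_resnames.add(parts[1])
        elif key == "role" and len(parts) == 3:
            rm.role_names[parts[2]] = parts[1]  # file name -> role
        elif key == "water":
            rm.water_resnames.add(parts[1])
        elif key == "ion" and len(parts) == 3:
            rm.ion_names[parts[1]] = parts[2]
        elif key == "tm" and len(parts) == 3:
            lo, hi = parts[2].split("-")
            rm.tm_ranges[parts[1]] = (int(lo), int(hi))
        else:
            raise FormatError(f"unrecognised role-map line: {raw!r}")
    return rm


_FIXTURE_SUFFIXES = {".mstrj", ".msfix"}


def read_trajectory(
    topology_path: str | Path,
    frames_path: str | Path | None = None,
    role_map: RoleMap | str | Path | None = None,
) -> Trajectory:
    """Read a trajectory from disk.

    Fixture files (``.mstrj``) are self-contained.  Otherwise
    ``topology_path`` is a GRO/PDB snapshot and ``frames_path`` an optional
    XTC/DCD (or multi-model PDB) frame source, read through MDAnalysis;
    coordinates are returned in Angstrom and times in ns.
    """
    topology_path = Path(topology_path)
    if topology_path.suffix in _FIXTURE_SUFFIXES:
        return read_fixture(topology_path)
    if role_map is None:
        rm = RoleMap()
    elif isinstance(role_map, RoleMap):
        rm = role_map
    else:
        rm = parse_role_map(role_map)
    return _read_mdanalysis(topology_path, frames_path, rm)


def _read_mdanalysis(
    topology_path: Path, frames_path: str | Path | None, rm: RoleMap
) -> Trajectory:
    import MDAnalysis as mda

    if frames_path is None:
        u = mda.Universe(str(topology_path))
    else:
        u = mda.Universe(str(topology_path), str(frames_path))

    role_of = rm.role_names  # file bead name -> role
    lipids: list[LipidRecord] = []
    residues: list[ResidueRecord] = []
    waters: list[int] = []
    ions: list[tuple[int, str]] = []
    lipid_id = 0
    for res in u.residues:
        rname = res.resname.strip()
        if rname in rm.lipid_resnames:
            beads: dict[str, int] = {}
            for atom in res.atoms:
                role = role_of.get(atom.name.strip())
                if role in LIPID_ROLES:
                    beads[role] = int(atom.index)
            rec = LipidRecord(lipid_id, beads)
            try:
                rec.validate()
            except TopologyError as err:
                raise TopologyError(
                    f"{topology_path}: residue {res.resid} ({rname}): {err}"
                ) from err
            lipids.append(rec)
            lipid_id += 1
        elif rname in rm.water_resnames:
            waters.extend(int(a.index) for a in res.atoms)
        elif rname in rm.ion_names:
            ions.extend((int(a.index), rm.ion_names[rname]) for a in res.atoms)
        else:
            atoms = list(res.atoms)
            bb = next(
                (a for a in atoms if a.name.strip() in ("BB", "CA")), atoms[0]
            )
            side = [int(a.index) for a in atoms if a.index != bb.index]
            chain = ""
            try:
                chain = str(atoms[0].chainID).strip()
            except Exception:
                pass
            if not chain:
                chain = str(getattr(res, "segid", "")).strip() or "A"
            if chain == "SYSTEM":
                chain = "A"
            tm = None
            for label, (lo, hi) in rm.tm_ranges.items():
                if lo <= res.resid <= hi:
                    tm = label
                    break
            residues.append(
                ResidueRecord(int(res.resid), str(chain).strip() or "A",
                              int(bb.index), side, tm)
            )

    top = Topology(
        n_beads=len(u.atoms),
        bead_names=[a.name.strip() for a in u.atoms],
        lipids=lipids,
        residues=residues,
        waters=waters,
        ions=ions,
    )
    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, top.n_beads, 3))
    times = np.empty(n_frames)
    box = np.empty((n_frames, 3))
    for i, ts in enumerate(u.trajectory):
        coords[i] = ts.positions  # MDAnalysis is already in Angstrom
        times[i] = (ts.time or 0.0) / 1000.0  # ps -> ns
        box[i] = ts.dimensions[:3] if ts.dimensions is not None else np.nan
    if n_frames > 1 and np.ptp(np.diff(times)) > _TIME_TOL_NS:
        times = np.arange(n_frames, dtype=float)  # fall back to 1 ns/frame
    elif n_frames > 1 and times[1] == times[0]:
        times = np.arange(n_frames, dtype=float)
    traj = Trajectory(coords, times, box, top)
    traj.validate()
    return traj
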