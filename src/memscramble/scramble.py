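"""Scrambling-event detection and rate statistics.

A lipid's orientation angle theta is the angle between the +z axis and the
mean of its NC3->C4A and NC3->C4B vectors: upper-leaflet lipids rest near
180 deg (tails pointing down), lower-leaflet lipids near 0 deg.  The raw
per-frame trace is denoised with a 100 ns centred running average; a
scrambling event completes when the smoothed trace of an upper-leaflet lipid
reaches <= 35 deg (or a lower-leaflet lipid >= 145 deg).  The far-side
thresholds act as hysteresis: the leaflet state only changes on a completed
transition, so partial excursions are never counted.

Rates use 1 us block averaging; event streams are checked for Poisson
statistics with a dispersion-index chi-square test; completed events are
classified as in-the-groove when the lipid's PO4 bead passes within 4.7 A
of the maximum-density pathway during the transition window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import ConsistencyError, DensityPathError, MemscrambleError
from .trajio import Trajectory

logger = logging.getLogger(__name__)


@dataclass
class AngleTrace:
    """Per-frame orientation angle of one lipid, raw and smoothed (deg)."""

    lipid_id: int
    times: np.ndarray
    theta: np.ndarray
    theta_smooth: np.ndarray

    @property
    def upper(self) -> np.ndarray:
        """Per-frame leaflet assignment: upper iff smoothed angle >= 90."""
        return self.theta_smooth >= 90.0


@dataclass
class ScramblingEvent:
    lipid_id: int
    direction: str  # upper_to_lower | lower_to_upper
    t_entry: float
    t_complete: float
    i_entry: int
    i_complete: int
    pathway: str | None = None  # in_groove | out_of_groove
    sublabel: str | None = None  # dimer_cleft | other
    min_path_dist: float | None = None


@dataclass
class RateEstimate:
    mean_rate: float  # events per us
    sd: float
    block_ns: float
    counts: np.ndarray


@dataclass
class PoissonTestResult:
    dispersion: float
    pvalue: float
    n_blocks: int
    n_events: int
    sufficient: bool


def _running_mean(x: np.ndarray, window_frames: int) -> np.ndarray:
    """Centred moving average along axis 0, truncated at the edges."""
    half = max(0, window_frames // 2)
    n = x.shape[0]
    c = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo).reshape((-1,) + (1,) * (x.ndim - 1))


def compute_angle_traces(
    traj: Trajectory, window_ns: float = 100.0
) -> list[AngleTrace]:
    """Orientation-angle traces for every lipid.

    theta = arccos(v . z / |v|) in degrees with v the mean of (C4A - NC3)
    and (C4B - NC3); the smoothed trace is a centred moving average over
    ~``window_ns`` (edge frames use the truncated window).
    """
    top = traj.topology
    nc3 = top.role_indices("NC3")
    c4a = top.role_indices("C4A")
    c4b = top.role_indices("C4B")
    v = 0.5 * (
        (traj.coords[:, c4a, :] - traj.coords[:, nc3, :])
        + (traj.coords[:, c4b, :] - traj.coords[:, nc3, :])
    )
    norm = np.linalg.norm(v, axis=2)
    if np.any(norm < 1e-9):
        bad = top.lipid_ids[np.any(norm < 1e-9, axis=0)]
        raise MemscrambleError(
            f"degenerate lipid orientation vector for lipid(s) {bad.tolist()}"
        )
    theta = np.degrees(np.arccos(np.clip(v[..., 2] / norm, -1.0, 1.0)))
    w = traj.window_to_frames(window_ns)
    smooth = _running_mean(theta, w)
    return [
        AngleTrace(int(top.lipid_ids[j]), traj.times, theta[:, j], smooth[:, j])
        for j in range(len(top.lipids))
    ]


def detect_events(
    traces: list[AngleTrace],
    lower_deg: float = 35.0,
    upper_deg: float = 145.0,
    upper_ref_deg: float = 150.0,
    lower_ref_deg: float = 30.0,
) -> list[ScramblingEvent]:
    """State-machine event detection on the smoothed angle traces.

    A lipid's leaflet state is set by the last far-threshold crossing
    (initially by the side of 90 deg of its first smoothed angle) and flips
    when the smoothed trace reaches the opposite far threshold; repeated
    back-and-forth transits each count as separate events.  The transition
    window opens at the last frame before completion at which the trace was
    still beyond the origin leaflet's resting angle.
    """
    events: list[ScramblingEvent] = []
    for tr in traces:
        th = tr.theta_smooth
        state_upper = bool(th[0] >= 90.0)
        window_floor = 0
        for i in range(len(th)):
            fired = (state_upper and th[i] <= lower_deg) or (
                not state_upper and th[i] >= upper_deg
            )
            if not fired:
                continue
            ref = upper_ref_deg if state_upper else lower_ref_deg
            beyond = (
                th[window_floor:i] >= ref
                if state_upper
                else th[window_floor:i] <= ref
            )
            idx = np.nonzero(beyond)[0]
            i_entry = window_floor + int(idx[-1]) if idx.size else window_floor
            events.append(
                ScramblingEvent(
                    lipid_id=tr.lipid_id,
                    direction="upper_to_lower" if state_upper else "lower_to_upper",
                    t_entry=float(tr.times[i_entry]),
                    t_complete=float(tr.times[i]),
                    i_entry=i_entry,
                    i_complete=i,
                )
            )
            state_upper = not state_upper
            window_floor = i
    events.sort(key=lambda e: e.t_complete)
    return events


def estimate_rate(
    event_times: np.ndarray | list[float],
    t_start: float,
    t_end: float,
    block_ns: float = 1000.0,
) -> RateEstimate:
    """Block-averaged scrambling rate in events/us.

    The analysed window is partitioned into consecutive ``block_ns`` blocks
    (a trailing partial block is dropped); the mean and population standard
    deviation of the per-block counts are reported on the events/us scale.
    """
    duration = t_end - t_start
    n_blocks = int(np.floor(duration / block_ns + 1e-9))
    if n_blocks < 1:
        raise MemscrambleError("analysed duration shorter than one block")
    t = np.asarray(event_times, dtype=float)
    edges = t_start + block_ns * np.arange(n_blocks + 1)
    counts, _ = np.histogram(t, bins=edges)
    per_us = 1000.0 / block_ns
    return RateEstimate(
        mean_rate=float(counts.mean() * per_us),
        sd=float(counts.std(ddof=0) * per_us),
        block_ns=block_ns,
        counts=counts,
    )


def poisson_interval_test(
    event_times: np.ndarray | list[float],
    t_start: float,
    t_end: float,
    block_ns: float = 1000.0,
    min_events: int = 10,
) -> PoissonTestResult:
    """Dispersion-index test of Poisson event statistics.

    Per-block counts c_i are formed at ``block_ns`` blocks; the index
    D = var(c)/mean(c) (sample variance) gives the statistic (n-1) D which
    is chi-square with n-1 dof under a homogeneous Poisson stream.  The
    p-value is two-sided, so both regular (underdispersed) and clustered
    (overdispersed) streams are rejected.
    """
    t = np.asarray(event_times, dtype=float)
    n_blocks = int(np.floor((t_end - t_start) / block_ns + 1e-9))
    edges = t_start + block_ns * np.arange(n_blocks + 1)
    counts, _ = np.histogram(t, bins=edges)
    if t.size < min_events:
        return PoissonTestResult(np.nan, np.nan, n_blocks, int(t.size), False)
    mean = counts.mean()
    if mean == 0:
        return PoissonTestResult(np.nan, np.nan, n_blocks, int(t.size), False)
    dispersion = counts.var(ddof=1) / mean
    stat = (n_blocks - 1) * dispersion
    cdf = stats.chi2.cdf(stat, df=n_blocks - 1)
    pvalue = float(2.0 * min(cdf, 1.0 - cdf))
    return PoissonTestResult(float(dispersion), pvalue, n_blocks, int(t.size), True)


# ---------------------------------------------------------------------------
# maximum-density pathway and in/out-of-groove classification
# ---------------------------------------------------------------------------

def build_density_path(
    grid,
    z_range: tuple[float, float],
    xy_center: tuple[float, float] | None = None,
    xy_radius: float | None = None,
    smooth_slabs: int = 3,
) -> np.ndarray:
    """Maximum-density pathway: per z-slab argmax voxel centres, smoothed.

    For every voxel layer inside ``z_range`` the highest-density voxel
    centre is taken (ties broken toward the lowest voxel index, with a
    warning); empty layers are linearly interpolated from their neighbours;
    the xy chain is smoothed with a ``smooth_slabs`` moving average.
    Returns an ordered (n, 3) polyline from high z to low z.
    """
    counts = grid.counts
    origin = np.asarray(grid.origin, dtype=float)
    sp = float(grid.spacing)
    nz = counts.shape[2]
    zc = origin[2] + (np.arange(nz) + 0.5) * sp
    sel = (zc >= min(z_range)) & (zc <= max(z_range))
    layers = np.nonzero(sel)[0]
    if layers.size == 0:
        raise DensityPathError("z range contains no voxel layers")
    xc = origin[0] + (np.arange(counts.shape[0]) + 0.5) * sp
    yc = origin[1] + (np.arange(counts.shape[1]) + 0.5) * sp
    if xy_center is not None and xy_radius is not None:
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        region = (xx - xy_center[0]) ** 2 + (yy - xy_center[1]) ** 2 <= xy_radius**2
    else:
        region = np.ones(counts.shape[:2], dtype=bool)

    pts = np.full((layers.size, 2), np.nan)
    for k, iz in enumerate(layers):
        layer = np.where(region, counts[:, :, iz], 0.0)
        peak = layer.max()
        if peak <= 0:
            continue  # empty slab: interpolated below
        flat = layer.ravel()
        hits = np.nonzero(flat == peak)[0]
        if hits.size > 1:
            warnings.warn(
                f"density path: {hits.size}-way tie in layer z={zc[iz]:.2f} A; "
                "taking lowest voxel index",
                stacklevel=2,
            )
        i, j = np.unravel_index(hits[0], layer.shape)
        pts[k] = (xc[i], yc[j])
    filled = np.isfinite(pts[:, 0])
    if not np.any(filled):
        raise DensityPathError("all slabs empty inside the requested z range")
    for d in range(2):
        pts[:, d] = np.interp(
            np.arange(layers.size), np.nonzero(filled)[0], pts[filled, d]
        )
    if smooth_slabs > 1:
        pts = _running_mean(pts, smooth_slabs)
    path = np.column_stack([pts, zc[layers]])
    return path[np.argsort(-path[:, 2])]  # top-to-bottom


def classify_events(
    events: list[ScramblingEvent],
    traj: Trajectory,
    polyline: np.ndarray,
    cutoff: float = 4.7,
    groove_point: np.ndarray | None = None,
    cleft_point: np.ndarray | None = None,
) -> list[ScramblingEvent]:
    """Label each event in-the-groove or out-of-the-groove.

    An event is in-the-groove iff the minimum, over its transition window,
    of the PO4-bead distance to the pathway polyline is <= ``cutoff``
    (inclusive).  Out-of-the-groove events are sub-labelled ``dimer_cleft``
    when, at their membrane-midplane crossing, the headgroup is nearer the
    registered TM3/TM10 cleft site than the groove site, else ``other``.
    """
    if groove_point is None:
        groove_point = _site_point(traj, ("TM4", "TM6"))
    if cleft_point is None:
        cleft_point = _site_point(traj, ("TM3", "TM10"))
    out: list[ScramblingEvent] = []
    top = traj.topology
    midplane_z = float(np.mean(polyline[:, 2]))
    for ev in events:
        if ev.i_complete >= traj.n_frames or ev.i_entry > ev.i_complete:
            raise ConsistencyError(
                f"event window [{ev.i_entry}, {ev.i_complete}] outside trajectory"
            )
        po4 = top.lipid(ev.lipid_id).beads["PO4"]
        window = traj.coords[ev.i_entry : ev.i_complete + 1, po4, :]
        d = np.linalg.norm(window[:, None, :] - polyline[None, :, :], axis=2)
        dmin = float(d.min())
        labelled = replace(ev, min_path_dist=dmin)
        if dmin <= cutoff:
            labelled.pathway = "in_groove"
        else:
            labelled.pathway = "out_of_groove"
            labelled.sublabel = "other"
            if cleft_point is not None and groove_point is not None:
                imid = int(np.argmin(np.abs(window[:, 2] - midplane_z)))
                p = window[imid, :2]
                if np.linalg.norm(p - cleft_point[:2]) < np.linalg.norm(
                    p - groove_point[:2]
                ):
                    labelled.sublabel = "dimer_cleft"
        out.append(labelled)
    return out


def _site_point(traj: Trajectory, tm_labels: tuple[str, str]) -> np.ndarray | None:
    recs = [r for r in traj.topology.residues if r.tm in tm_labels]
    if not recs:
        return None
    idx = traj.topology.residue_beads(recs)
    return traj.coords[0, idx, :].mean(axis=0)
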