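"""Groove-dilation geometry and scrambling-competence classification.

The TM4-TM6 groove width is the per-frame minimum distance over all beads
(side-chain and backbone) between the two registered residue ranges of one
subunit.  Time series are smoothed for display with a recursive
exponentially weighted moving average (factor 0.1).  Structures are placed
in a competence quadrant from two empirical thresholds: robust scrambling
requires the membrane thinned below 14 A at the groove and a median groove
width above 6 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import TM_RANGES
from .errors import SelectionError
from .membrane import LeafletSurfacePair, min_thickness
from .trajio import Trajectory

__all__ = [
    "TM_RANGES",
    "GrooveSeries",
    "CompetenceSummary",
    "groove_distance_series",
    "ewma",
    "competence_summary",
    "dimer_cleft_width",
]


@dataclass
class GrooveSeries:
    times: np.ndarray
    raw: np.ndarray       # per-frame minimum TM4-TM6 distance, A
    smoothed: np.ndarray  # EWMA (factor 0.1)
    chain: str
    tm4_range: tuple[int, int]
    tm6_range: tuple[int, int]


@dataclass
class CompetenceSummary:
    median: float
    q1: float
    q3: float
    open_fraction: float   # share of frames with groove width > threshold
    min_thickness: float
    quadrant: str


def _range_beads(traj: Trajectory, rng: tuple[int, int], chain: str) -> np.ndarray:
    recs = traj.topology.select_residues(chain=chain, resid_range=rng)
    if not recs:
        raise SelectionError(
            f"no residues {rng[0]}-{rng[1]} on chain {chain!r}"
        )
    return traj.topology.residue_beads(recs)


def _min_distance_series(
    traj: Trajectory, idx_a: np.ndarray, idx_b: np.ndarray,
    z_below: float | None = None,
) -> np.ndarray:
    a = traj.coords[:, idx_a, :]
    b = traj.coords[:, idx_b, :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=3)
    if z_below is not None:
        mask_a = a[..., 2] < z_below
        mask_b = b[..., 2] < z_below
        pair_ok = mask_a[:, :, None] & mask_b[:, None, :]
        d = np.where(pair_ok, d, np.inf)
    out = d.reshape(traj.n_frames, -1).min(axis=1)
    return np.where(np.isfinite(out), out, np.nan)


def groove_distance_series(
    traj: Trajectory,
    tm4_range: tuple[int, int],
    tm6_range: tuple[int, int],
    chain: str = "A",
    ewma_factor: float = 0.1,
) -> GrooveSeries:
    """Per-frame minimum TM4-TM6 distance (all-bead minimum) plus EWMA."""
    idx4 = _range_beads(traj, tm4_range, chain)
    idx6 = _range_beads(traj, tm6_range, chain)
    raw = _min_distance_series(traj, idx4, idx6)
    return GrooveSeries(
        times=traj.times, raw=raw, smoothed=ewma(raw, ewma_factor),
        chain=chain, tm4_range=tuple(tm4_range), tm6_range=tuple(tm6_range),
    )


def ewma(series: np.ndarray, factor: float = 0.1) -> np.ndarray:
    """Recursive exponential smoothing: s_0 = x_0, s_t = f x_t + (1-f) s_{t-1}."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise SelectionError("empty series")
    zi = signal.lfilter_zi([factor], [1.0, -(1.0 - factor)]) * x[0]
    y, _ = signal.lfilter([factor], [1.0, -(1.0 - factor)], x, zi=zi)
    return y


def competence_summary(
    groove: GrooveSeries,
    surfaces: LeafletSurfacePair | float,
    open_threshold: float = 6.0,
    thickness_threshold: float = 14.0,
) -> CompetenceSummary:
    """Quartile statistics of the raw groove series plus the quadrant label.

    Quartiles and the open fraction are computed on the raw (unsmoothed)
    series; smoothing is for display only.  ``surfaces`` may be a
    LeafletSurfacePair (minimal thickness is computed) or a thickness in A.
    """
    raw = groove.raw[np.isfinite(groove.raw)]
    q1, med, q3 = np.percentile(raw, [25, 50, 75])
    open_frac = float(np.mean(raw > open_threshold))
    if isinstance(surfaces, LeafletSurfacePair):
        thick = min_thickness(surfaces)[0]
    else:
        thick = float(surfaces)
    thin = thick < thickness_threshold
    open_ = med > open_threshold
    quadrant = {
        (True, True): "robust_scrambling",
        (True, False): "thinned_closed",
        (False, True): "thick_open",
        (False, False): "non_scrambling",
    }[(thin, open_)]
    return CompetenceSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        open_fraction=open_frac, min_thickness=thick, quadrant=quadrant,
    )


def dimer_cleft_width(
    traj: Trajectory,
    tm3_range: tuple[int, int],
    chain_a: str,
    tm10_range: tuple[int, int],
    chain_b: str,
    midplane_z: float = 0.0,
) -> np.ndarray:
    """Per-frame minimum TM3(chain A)-TM10(chain B) distance below midplane.

    Frames where either selection has no bead below the midplane yield NaN.
    """
    idx3 = _range_beads(traj, tm3_range, chain_a)
    idx10 = _range_beads(traj, tm10_range, chain_b)
    return _min_distance_series(traj, idx3, idx10, z_below=midplane_z)
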