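"""Shared fixtures: synthetic bilayers with scripted ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from memscramble.synthgen import (
    BilayerSpec,
    Excursion,
    Flip,
    FlipSchedule,
    add_protein_scaffold,
    apply_flips,
    make_bilayer,
)


@pytest.fixture(scope="session")
def small_bilayer():
    """Static 32-lipid bilayer, no noise, exact geometry."""
    spec = BilayerSpec(
        lipids_per_leaflet=16, box_xy=48.0, noise_sigma=0.0,
        lateral_sigma=0.0, seed=0,
    )
    return make_bilayer(spec, 50)


@pytest.fixture(scope="session")
def scaffold_bilayer():
    """Bilayer with groove walls 6 A apart and a cleft site 20 A away."""
    spec = BilayerSpec(
        lipids_per_leaflet=16, box_xy=48.0, noise_sigma=0.0,
        lateral_sigma=0.0, seed=0,
    )
    traj = make_bilayer(spec, 50)
    return add_protein_scaffold(
        traj, groove_center=(24.0, 24.0), groove_width=6.0,
        cleft_center=(44.0, 24.0), cleft_width=10.0,
    )


def build_flip_trajectory(
    n_flips: int,
    seed: int,
    n_partials: int = 5,
    noise_sigma: float = 1.0,
    lipids_per_leaflet: int = 64,
    min_gap_ns: float = 170.0,
):
    """Bilayer with ``n_flips`` scripted flips spread over a window sized to
    hold them, plus partial excursions; returns (trajectory, schedule).

    Flip directions follow each lipid's evolving leaflet so repeated flips
    of one lipid alternate; scripted motions of one lipid never overlap.
    """
    n_frames = max(1500, int(n_flips * 45) + 1200)
    spec = BilayerSpec(
        lipids_per_leaflet=lipids_per_leaflet, box_xy=80.0,
        noise_sigma=noise_sigma, seed=seed,
    )
    traj = make_bilayer(spec, n_frames)
    rng = np.random.default_rng(seed + 1)
    n_lip = 2 * lipids_per_leaflet
    flips: list[Flip] = []
    state = {
        l: ("upper" if l < lipids_per_leaflet else "lower")
        for l in range(n_lip)
    }
    next_free = np.zeros(n_lip)
    starts = np.sort(
        rng.uniform(200.0, n_frames - 250.0, n_flips)
    ) if n_flips else np.empty(0)
    for st in starts:
        ok = [l for l in range(n_lip) if next_free[l] <= st]
        lid = int(rng.choice(ok))
        direction = "down" if state[lid] == "upper" else "up"
        flips.append(Flip(lid, float(st), direction=direction))
        state[lid] = "lower" if direction == "down" else "upper"
        next_free[lid] = st + min_gap_ns
    excursions = []
    t = 150.0
    placed = 0
    lid = 0
    while placed < n_partials:
        if next_free[lid] <= t and not any(
            f.lipid_id == lid and f.start_ns < t + 260.0 for f in flips
        ):
            angle = 60.0 if lid < lipids_per_leaflet else 120.0
            excursions.append(Excursion(lid, t, max_angle_deg=angle))
            next_free[lid] = t + 260.0
            placed += 1
        lid = (lid + 1) % n_lip
        if lid == 0:
            t += 300.0
        if t > n_frames - 300.0:
            break
    schedule = FlipSchedule(flips=flips, excursions=excursions)
    return apply_flips(traj, schedule), schedule
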