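"""Protein-lipid contact frequencies and gap-tolerant dwell times.

A contact exists at a frame when the residue's outermost side-chain bead
(the bead farthest from its backbone at that frame; the backbone bead for
glycine) is strictly within 7 A of the lipid's choline (NC3) or phosphate
(PO4) bead.  Dwell events are maximal contact runs merged across breaks of
up to 6 ns; dwell duration counts both endpoints and any merged gap frames.
Per-residue summaries pick the headgroup bead (NC3 vs PO4) with the higher
mean dwell, average contact frequency over monomers, report the mean of the
top-50% longest dwell events, and attribute contact frames to lipids that
scramble versus bulk lipids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SelectionError
from .trajio import ResidueRecord, Trajectory


@dataclass
class ContactTimeline:
    """Merged contact intervals for one (residue, lipid) pair."""

    residue_id: int
    lipid_id: int
    bead: str  # NC3 | PO4
    chain: str
    intervals: list[tuple[int, int]]  # inclusive frame indices, post-merge
    n_contact_frames: int             # raw (unmerged) contact frames
    dt: float = 1.0

    @property
    def dwell_times(self) -> list[float]:
        return [(e - s + 1) * self.dt for s, e in self.intervals]


@dataclass
class ResidueContactSummary:
    residue_id: int
    bead: str
    frequency: float           # contact-frame fraction, averaged over monomers
    mean_dwell_top50: float    # ns
    scrambler_share: float     # contact frames made by scrambling lipids
    n_dwell_events: int
    empty: bool = False


def outermost_bead_positions(
    traj: Trajectory, residues: Sequence[ResidueRecord]
) -> np.ndarray:
    """(n_frames, n_res, 3) positions of each residue's outermost bead.

    Resolved per frame: the side-chain bead farthest from the backbone bead
    at that frame; residues without side chains use the backbone bead.
    """
    out = np.empty((traj.n_frames, len(residues), 3))
    for j, res in enumerate(residues):
        if not res.sidechain:
            out[:, j, :] = traj.coords[:, res.backbone, :]
            continue
        side = traj.coords[:, res.sidechain, :]
        bb = traj.coords[:, res.backbone, :]
        d = np.linalg.norm(side - bb[:, None, :], axis=2)
        pick = np.argmax(d, axis=1)
        out[:, j, :] = side[np.arange(traj.n_frames), pick]
    return out


def contact_frames(
    traj: Trajectory,
    residue: ResidueRecord,
    lipid_id: int,
    bead: str = "NC3",
    cutoff: float = 7.0,
) -> np.ndarray:
    """Boolean contact series for one residue/lipid pair (strict < cutoff)."""
    prot = outermost_bead_positions(traj, [residue])[:, 0, :]
    lip = traj.coords[:, traj.topology.lipid(lipid_id).beads[bead], :]
    return np.linalg.norm(prot - lip, axis=1) < cutoff


def contact_matrix(
    traj: Trajectory,
    residues: Sequence[ResidueRecord],
    lipid_ids: Sequence[int],
    bead: str = "NC3",
    cutoff: float = 7.0,
) -> np.ndarray:
    """Boolean contacts, shape (n_frames, n_residues, n_lipids)."""
    prot = outermost_bead_positions(traj, residues)
    idx = [traj.topology.lipid(l).beads[bead] for l in lipid_ids]
    lip = traj.coords[:, idx, :]
    d = np.linalg.norm(prot[:, :, None, :] - lip[:, None, :, :], axis=3)
    return d < cutoff


def dwell_intervals(
    series: np.ndarray,
    gap_frames: int = 6,
    dt: float = 1.0,
    residue_id: int = -1,
    lipid_id: int = -1,
    bead: str = "NC3",
    chain: str = "A",
) -> ContactTimeline:
    """Merge contact runs across breaks of at most ``gap_frames`` frames."""
    on = np.nonzero(np.asarray(series, dtype=bool))[0]
    intervals: list[tuple[int, int]] = []
    if on.size:
        start = prev = int(on[0])
        for i in on[1:]:
            if i - prev - 1 <= gap_frames:
                prev = int(i)
            else:
                intervals.append((start, prev))
                start = prev = int(i)
        intervals.append((start, prev))
    return ContactTimeline(
        residue_id=residue_id, lipid_id=lipid_id, bead=bead, chain=chain,
        intervals=intervals, n_contact_frames=int(on.size), dt=dt,
    )


def top50_mean(dwells: Sequence[float]) -> float:
    """Mean of the longest half of dwell events (ceiling count)."""
    if not dwells:
        return 0.0
    k = math.ceil(len(dwells) / 2)
    return float(np.mean(sorted(dwells, reverse=True)[:k]))


def summarize_residue(
    residue_id: int,
    contacts_by_bead: Mapping[str, Mapping[str, np.ndarray]],
    lipid_ids: Sequence[int],
    scrambler_ids: Iterable[int] = (),
    gap_frames: int = 6,
    dt: float = 1.0,
) -> ResidueContactSummary:
    """Summarise one residue from per-bead, per-chain contact matrices.

    ``contacts_by_bead[bead][chain]`` is a boolean (n_frames, n_lipids)
    matrix for this residue.  The bead with the higher mean dwell time is
    selected; frequency is the fraction of frames with any lipid contact,
    averaged over chains.
    """
    scramblers = set(scrambler_ids)
    lipid_ids = list(lipid_ids)

    def _dwells(bead: str) -> list[float]:
        out: list[float] = []
        for chain, mat in contacts_by_bead[bead].items():
            for j in range(mat.shape[1]):
                tl = dwell_intervals(mat[:, j], gap_frames, dt,
                                     residue_id, lipid_ids[j], bead, chain)
                out.extend(tl.dwell_times)
        return out

    per_bead = {bead: _dwells(bead) for bead in contacts_by_bead}
    means = {
        b: (float(np.mean(d)) if d else 0.0) for b, d in per_bead.items()
    }
    bead = max(sorted(means), key=lambda b: means[b])
    dwells = per_bead[bead]

    freqs = []
    contact_total = 0
    contact_scramblers = 0
    for chain, mat in contacts_by_bead[bead].items():
        freqs.append(float(mat.any(axis=1).mean()))
        per_lipid = mat.sum(axis=0)
        contact_total += int(per_lipid.sum())
        for j, lid in enumerate(lipid_ids):
            if lid in scramblers:
                contact_scramblers += int(per_lipid[j])
    share = contact_scramblers / contact_total if contact_total else 0.0
    return ResidueContactSummary(
        residue_id=residue_id,
        bead=bead,
        frequency=float(np.mean(freqs)) if freqs else 0.0,
        mean_dwell_top50=top50_mean(dwells),
        scrambler_share=share,
        n_dwell_events=len(dwells),
        empty=not dwells,
    )


def residue_summaries(
    traj: Trajectory,
    residues_by_chain: Mapping[str, Sequence[ResidueRecord]],
    scrambler_ids: Iterable[int] = (),
    cutoff: float = 7.0,
    gap_frames: int = 6,
) -> list[ResidueContactSummary]:
    """Full per-residue contact summary across monomers.

    ``residues_by_chain`` maps chain ids to equal-length residue lists in
    corresponding order (monomer copies of the same residue).
    """
    chains = list(residues_by_chain)
    if not chains:
        raise SelectionError("no chains given")
    n_res = len(residues_by_chain[chains[0]])
    lipid_ids = list(traj.topology.lipid_ids)
    mats = {
        bead: {
            ch: contact_matrix(traj, residues_by_chain[ch], lipid_ids, bead,
                               cutoff)
            for ch in chains
        }
        for bead in ("NC3", "PO4")
    }
    out = []
    dt = traj.dt
    for r in range(n_res):
        contacts_by_bead = {
            bead: {ch: mats[bead][ch][:, r, :] for ch in chains}
            for bead in ("NC3", "PO4")
        }
        out.append(
            summarize_residue(
                residues_by_chain[chains[0]][r].resid,
                contacts_by_bead, lipid_ids, scrambler_ids, gap_frames, dt,
            )
        )
    return out
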