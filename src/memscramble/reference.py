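"""Reference scrambling-event counts from the published CG-MD survey.

Per-structure event counts for the five TMEM16 homologs simulated for 10 us
each in a DOPC Martini bilayer (1 us discarded for equilibration, leaving a
9 us analysed window).  Events are split into in-the-groove (headgroup
within 4.7 A of the DOPC maximum-density pathway) and out-of-the-groove;
``reported_rate`` is the published block-averaged mean rate in events/us.

These counts serve as arithmetic inputs for reconstructing the published
rate statistics with :func:`memscramble.scramble.estimate_rate`.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Production length minus equilibration, ns.
ANALYSED_WINDOW_NS = 9000.0


@dataclass(frozen=True)
class StructureCounts:
    homolog: str
    pdb: str
    in_groove: int
    out_of_groove: int
    reported_rate: float  # events/us, block-averaged mean

    @property
    def total(self) -> int:
        return self.in_groove + self.out_of_groove


SCRAMBLING_COUNTS: tuple[StructureCounts, ...] = (
    StructureCounts("nhTMEM16", "4WIS", 219, 1, 24.4),
    StructureCounts("nhTMEM16", "6QM6", 141, 0, 15.7),
    StructureCounts("afTMEM16", "7RXG", 96, 0, 10.7),
    StructureCounts("TMEM16K", "5OC9", 66, 8, 8.2),
    StructureCounts("TMEM16K", "6R7X", 0, 4, 0.4),
    StructureCounts("TMEM16F F518H", "8B8J", 98, 4, 11.3),
    StructureCounts("TMEM16F", "6QP6*", 24, 3, 3.0),
    StructureCounts("TMEM16F T137Y", "8TAG", 0, 9, 1.0),
    StructureCounts("TMEM16F", "6P47", 1, 3, 0.4),
    StructureCounts("TMEM16F", "6P48", 0, 4, 0.4),
    StructureCounts("TMEM16F F518H/Q623A", "8BC0", 0, 4, 0.4),
    StructureCounts("TMEM16F F518H", "8B8Q", 0, 4, 0.4),
    StructureCounts("TMEM16F F518H", "8B8G", 2, 0, 0.2),
    StructureCounts("TMEM16F", "6QPB", 0, 3, 0.3),
    StructureCounts("TMEM16A", "7ZK3*6", 0, 11, 1.2),
    StructureCounts("TMEM16A", "5OYB*", 2, 0, 0.2),
    StructureCounts("TMEM16A", "7ZK3*10", 0, 1, 0.1),
    StructureCounts("TMEM16A", "7ZK3*8", 0, 1, 0.1),
)


def by_pdb(pdb: str) -> StructureCounts:
    for rec in SCRAMBLING_COUNTS:
        if rec.pdb == pdb:
            return rec
    raise KeyError(pdb)


def aggregate() -> dict[str, float]:
    """Survey-wide bookkeeping: totals and the in-groove share."""
    total = sum(r.total for r in SCRAMBLING_COUNTS)
    out = sum(r.out_of_groove for r in SCRAMBLING_COUNTS)
    in_groove = sum(r.in_groove for r in SCRAMBLING_COUNTS)
    return {
        "total_events": total,
        "in_groove_events": in_groove,
        "out_of_groove_events": out,
        "in_groove_share_pct": 100.0 * in_groove / total,
    }
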