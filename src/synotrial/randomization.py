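"""Stratified permuted-block 1:1 treatment allocation.

Patients are randomized 1:1 to rituximab or tocilizumab within strata
defined by the histological pathotype (B-cell poor, B-cell rich,
germinal-centre positive, unknown) crossed with a site group (lead
centre vs all others by default). Allocation proceeds in permuted
blocks of size six or four, the size of each new block drawn uniformly
at random per stratum; within every completed block the arms are
exactly balanced, so the running per-stratum imbalance never exceeds
half the largest block size.

An append-only audit log records order, stratum and assigned arm; a
redacted view omits the pathotype stratum because site staff remain
masked to histological subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["AllocationState", "randomize", "ARMS"]

ARMS = ("rituximab", "tocilizumab")


@dataclass
class AllocationState:
    """Mutable allocation state for one trial's randomization.

    ``strata`` maps (pathotype, site_group) to the unconsumed remainder
    of the current permuted block; the audit log grows by one record
    per assignment.
    """

    seed: int = 0
    block_sizes: Tuple[int, ...] = (6, 4)
    strata: Dict[Tuple[str, str], List[str]] = field(default_factory=dict)
    counts: Dict[Tuple[str, str], Dict[str, int]] = field(default_factory=dict)
    audit_log: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(b % 2 for b in self.block_sizes):
            raise ValueError("block sizes must be even for exact 1:1 balance")
        self._rng = np.random.default_rng(self.seed)

    def _new_block(self) -> List[str]:
        size = int(self._rng.choice(self.block_sizes))
        block = [ARMS[0]] * (size // 2) + [ARMS[1]] * (size // 2)
        self._rng.shuffle(block)
        return block

    def assign(self, stratum: Tuple[str, str]) -> str:
        queue = self.strata.setdefault(stratum, [])
        if not queue:
            queue.extend(self._new_block())
        arm = queue.pop(0)
        tally = self.counts.setdefault(stratum, {a: 0 for a in ARMS})
        tally[arm] += 1
        self.audit_log.append(
            {
                "order": len(self.audit_log) + 1,
                "pathotype": stratum[0],
                "site_group": stratum[1],
                "arm": arm,
            }
        )
        return arm

    def imbalance(self, stratum: Tuple[str, str]) -> int:
        tally = self.counts.get(stratum, {a: 0 for a in ARMS})
        return abs(tally[ARMS[0]] - tally[ARMS[1]])

    def audit_frame(self, redacted: bool = False) -> pd.DataFrame:
        """Audit log as a table; the redacted site view hides pathotype."""
        df = pd.DataFrame(self.audit_log)
        if redacted and not df.empty:
            df = df.drop(columns=["pathotype"])
        return df


def randomize(
    pathotype: str,
    site_group: str,
    state: AllocationState,
) -> str:
    """Assign the next patient in (pathotype, site_group) to an arm."""
    return state.assign((str(pathotype), str(site_group)))
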