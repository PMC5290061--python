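"""Node Injury Scale (NIS) damage scoring and yield-loss conversion.

The NIS scores corn root damage on 0.00–3.00: the integer part counts full
node-equivalents of root destroyed, the decimals the percentage of one
further node.  The simulation knows, per node 1–7, how much root mass the
pest-free twin grew and how much the pest run lost to feeding and pruning,
so the score is the capped sum of per-node loss percentages divided by 100.
A one-unit NIS difference converts to 16.5 ± 1.9 % yield loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .roots import N_NODES

NIS_MAX = 3.0
YIELD_LOSS_PER_NIS = 16.5       # % yield loss per NIS unit
YIELD_LOSS_PER_NIS_SD = 1.9


@dataclass
class NodeLossLedger:
    """Per-node grown (pest-free twin) and lost (eaten + pruned) root mass, g."""

    grown_g: np.ndarray          # length 7, index 0 == node 1
    lost_g: np.ndarray
    assessment_day: int | None = None

    def __post_init__(self):
        self.grown_g = np.asarray(self.grown_g, dtype=float)
        self.lost_g = np.asarray(self.lost_g, dtype=float)
        if self.grown_g.shape != (N_NODES,) or self.lost_g.shape != (N_NODES,):
            raise ValueError(f"ledgers must have {N_NODES} node entries")
        if np.any(self.grown_g < 0) or np.any(self.lost_g < 0):
            raise ValueError("ledger masses must be >= 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "NodeLossLedger":
        df = pd.read_csv(path)
        required = {"node", "grown_g", "lost_g"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"ledger CSV must have columns {sorted(required)}")
        grown = np.zeros(N_NODES)
        lost = np.zeros(N_NODES)
        for _, row in df.iterrows():
            n = int(row["node"])
            if not 1 <= n <= N_NODES:
                raise ValueError(f"node {n} outside 1..{N_NODES}")
            grown[n - 1] = row["grown_g"]
            lost[n - 1] = row["lost_g"]
        return cls(grown_g=grown, lost_g=lost)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"node": np.arange(1, N_NODES + 1),
                      "grown_g": self.grown_g,
                      "lost_g": self.lost_g}).to_csv(path, index=False)


@dataclass
class DamageResult:
    nis: float                        # 0.00–3.00, two decimals
    total_node_equivalents_lost: float  # % (uncapped sum of per-node losses)
    yield_loss_pct: float
    yield_loss_sd_pct: float

    def to_dict(self) -> dict:
        return {"nis": self.nis,
                "total_node_equivalents_lost_pct": self.total_node_equivalents_lost,
                "yield_loss_pct": self.yield_loss_pct,
                "yield_loss_sd_pct": self.yield_loss_sd_pct}


def compute_nis(ledger: NodeLossLedger) -> DamageResult:
    """Score the ledger on the Node Injury Scale.

    Per node, loss % = 100 · lost/grown; the percentages are summed over
    nodes into node-equivalents.  Totals above 300 % score 3.00; below, the
    score is the total divided by 100, reported to two decimals.  Nodes the
    twin never grew contribute nothing, but a ledger with no grown mass at
    all is undefined.
    """
    if not np.any(ledger.grown_g > 0):
        raise ValueError("damage undefined: pest-free twin grew no root mass")
    over = ledger.lost_g > ledger.grown_g
    if np.any(over):
        raise ValueError(
            f"node {int(np.flatnonzero(over)[0]) + 1} lost more than it grew")
    grown = ledger.grown_g
    with np.errstate(invalid="ignore", divide="ignore"):
        loss_pct = np.where(grown > 0, 100.0 * ledger.lost_g / grown, 0.0)
    total = float(loss_pct.sum())
    nis = round(min(NIS_MAX, total / 100.0), 2)
    yl, sd = nis_to_yield_loss(nis)
    return DamageResult(nis=nis, total_node_equivalents_lost=total,
                        yield_loss_pct=yl, yield_loss_sd_pct=sd)


def nis_to_yield_loss(delta_nis: float) -> tuple[float, float]:
    """Linear NIS → yield-loss conversion: 16.5 ± 1.9 % per NIS unit."""
    if not 0.0 <= delta_nis <= NIS_MAX:
        raise ValueError(f"ΔNIS must lie in [0, {NIS_MAX}]; got {delta_nis}")
    return (YIELD_LOSS_PER_NIS * delta_nis, YIELD_LOSS_PER_NIS_SD * delta_nis)
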