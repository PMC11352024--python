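"""The Hawaiian-fly (*Drosophila cyrtoloma*) wing-vein network analysis.

The forewing venation is a ladder: seven edge-vein segments (V_E_1..7) along
the wing margin and seven base-vein segments (V_B_1..7) along the base form
the rails, joined by six connecting veins (rungs).  The fourth, fifth and
sixth rungs are split into edge- and base-side segments by the junctions of
two crossveins: the posterior crossvein (PCV), common to fruit flies, and
the extra crossvein (ECV) unique to the Hawaiian planitibia group.  The ECV
meets the fifth connecting vein at the PCV's anterior junction, forming a
cruciform node.

Hemolymph enters at the shared anterior base terminal and leaves at the
shared posterior one.  This module builds that network from the measured
geometry table, ablates the ECV virtually, and classifies the per-vein flow
changes its presence causes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core import (
    HEMOLYMPH,
    Q_IN_DEFAULT,
    FlowSolution,
    FluidProperties,
    HydraulicNetwork,
    MalformedTableError,
)
from .io import network_from_tables, packaged_topology, packaged_vein_table

__all__ = [
    "EXPECTED_VEIN_IDS",
    "FlowChangeMap",
    "build_cyrtoloma_network",
    "ablate",
    "compare_flows",
    "reduction_percent",
    "load_table1",
]

EXPECTED_VEIN_IDS = frozenset(
    [f"V_E_{i}" for i in range(1, 8)]
    + [f"V_B_{i}" for i in range(1, 8)]
    + ["V_C_1", "V_C_2", "V_C_3"]
    + ["V_C_4_E", "V_C_4_B", "V_C_5_E", "V_C_5_B", "V_C_6_E", "V_C_6_B"]
    + ["ECV", "PCV"]
)

#: default no-flow threshold: |q| below this fraction of Q_in counts as no flow
ZERO_FLOW_THRESHOLD = 0.001


def load_table1() -> pd.DataFrame:
    """The packaged measured geometry table (25 veins, mm units)."""
    return packaged_vein_table()


def build_cyrtoloma_network(
    table: pd.DataFrame | None = None,
    props: FluidProperties = HEMOLYMPH,
    inflow: float = Q_IN_DEFAULT,
) -> HydraulicNetwork:
    """Build the 17-node, 25-channel wing-vein network.

    ``table`` defaults to the packaged measured geometry.  Raises
    :class:`MalformedTableError` when vein ids are missing or unexpected.
    """
    if table is None:
        table = packaged_vein_table()
    ids = set(table["vein_id"])
    if ids != EXPECTED_VEIN_IDS:
        missing = sorted(EXPECTED_VEIN_IDS - ids)
        extra = sorted(ids - EXPECTED_VEIN_IDS)
        raise MalformedTableError(
            f"vein table mismatch: missing {missing}, unexpected {extra}"
        )
    return network_from_tables(table, packaged_topology(), props, inflow)


def ablate(network: HydraulicNetwork, channel_id: str = "ECV") -> HydraulicNetwork:
    """Virtually remove one vein; raises ``KeyError`` if absent."""
    return network.without_channel(channel_id)


def reduction_percent(loss_without: float, loss_with: float) -> float:
    """Percent drop in total pressure loss due to a channel's presence."""
    if loss_without <= 0:
        raise ValueError("baseline loss must be positive")
    return 100.0 * (loss_without - loss_with) / loss_without


@dataclass(frozen=True)
class FlowChangeMap:
    """Per-channel flow change between two solutions of congruent networks.

    ``rate`` is the relative magnitude change (|q| − |q_ref|)/|q_ref| (NaN
    when the reference flow is exactly zero); ``category`` is one
    of ``increase`` / ``decrease`` / ``no-flow`` (no-flow meaning |q| fell
    below the threshold fraction of Q_in); ``reversed`` flags channels whose
    flow direction flipped while both magnitudes stay above threshold.
    """

    rate: Mapping[str, float]
    category: Mapping[str, str]
    reversed: Mapping[str, bool]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": sorted(self.rate),
                "change_rate": [self.rate[c] for c in sorted(self.rate)],
                "category": [self.category[c] for c in sorted(self.rate)],
                "direction_reversed": [self.reversed[c] for c in sorted(self.rate)],
            }
        )


def compare_flows(
    with_ecv: FlowSolution,
    without_ecv: FlowSolution,
    inflow: float,
    threshold: float = ZERO_FLOW_THRESHOLD,
) -> FlowChangeMap:
    """Classify per-vein flow changes caused by a crossvein's presence.

    Channels present only in the with-ECV solution (the crossvein itself)
    are excluded from the rates.  Raises ``ValueError`` when the shared
    channel sets disagree beyond that.
    """
    shared = set(without_ecv.channel_flow)
    if not shared <= set(with_ecv.channel_flow):
        raise ValueError("channel sets are not congruent")
    cut = threshold * inflow
    rate: dict[str, float] = {}
    category: dict[str, str] = {}
    flipped: dict[str, bool] = {}
    for cid in shared:
        q, q0 = with_ecv.channel_flow[cid], without_ecv.channel_flow[cid]
        rate[cid] = (abs(q) - abs(q0)) / abs(q0) if q0 != 0.0 else math.nan
        if abs(q) < cut:
            category[cid] = "no-flow"
        elif abs(q) > abs(q0):
            category[cid] = "increase"
        elif abs(q) < abs(q0):
            category[cid] = "decrease"
        else:
            category[cid] = "no-change"
        flipped[cid] = abs(q) >= cut and abs(q0) >= cut and (q * q0 < 0)
    return FlowChangeMap(rate=rate, category=category, reversed=flipped, threshold=threshold)
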