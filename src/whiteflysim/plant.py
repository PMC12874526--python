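"""Cotton host-plant growth: leaf area and mainstem nodes.

The plant provides the denominator for whitefly density outputs and
the emigration trigger (adults leave en masse once the plant exceeds
a mainstem-node threshold, matching field observations of whitefly
departure from maturing cotton).  Leaf area follows logistic growth
and nodes accrue linearly, both with rates multiplied by the plant
Arrhenius factor, which peaks at 28.5 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .temperature import TemperatureResponse, arrhenius_factor

__all__ = ["PlantParams", "PlantState", "step_plant", "density_outputs"]

#: leaf disc sampling area used for immature counts, cm^2
DISC_AREA_CM2 = 3.88

#: default leaf area for adult counts, as a multiple of the disc
ADULT_LEAF_MULTIPLIER = 20.0


@dataclass(frozen=True)
class PlantParams:
    """Growth parameters at the plant reference temperature.

    Calibrated defaults: a young cotton plant (~3 weeks, two true
    leaves) growing logistically toward a full canopy, and mainstem
    nodes appearing at a constant temperature-corrected rate from a
    seedling initial value.
    """

    r_leaf: float = 0.018      # logistic leaf-area growth rate, 1/d
    leaf_area_max: float = 12000.0  # cm^2 per plant
    r_node: float = 0.034      # node appearance rate, 1/d
    leaf_area_0: float = 60.0  # cm^2 seedling leaf area
    nodes_0: float = 2.0       # seedling mainstem nodes


@dataclass(frozen=True)
class PlantState:
    """Leaf area (cm^2) and mainstem node count (continuous)."""

    leaf_area: float
    nodes: float

    @property
    def node_count(self) -> int:
        """Nodes reported as an integer."""
        return int(self.nodes)


def step_plant(state: PlantState, T: float, dt: float = 1.0,
               plant_resp: TemperatureResponse | None = None,
               params: PlantParams = PlantParams()) -> PlantState:
    """Advance the plant by ``dt`` days at mean temperature ``T``.

    Logistic leaf-area growth (exact within-step solution) and linear
    node accrual; deterministic.
    """
    c_T = 1.0 if plant_resp is None else arrhenius_factor(T, plant_resp)
    A = state.leaf_area
    K = params.leaf_area_max
    rt = params.r_leaf * c_T * dt
    # exact logistic update: invariant to splitting a day in halves
    A_new = K / (1.0 + (K / A - 1.0) * np.exp(-rt))
    nodes_new = state.nodes + params.r_node * c_T * dt
    return replace(state, leaf_area=float(A_new), nodes=float(nodes_new))


def density_outputs(stage_counts: dict, state: PlantState,
                    disc_area: float = DISC_AREA_CM2,
                    adult_leaf_multiplier: float = ADULT_LEAF_MULTIPLIER) -> dict:
    """Per-disc densities from whole-plant counts.

    Immature densities refer to a sampled leaf disc; adult densities
    to a default leaf area ``adult_leaf_multiplier`` times the disc
    (per-leaf counts in the field reference did not record actual
    leaf sizes).
    """
    from .deb import Stage

    if state.leaf_area <= 0:
        raise ValueError("leaf area must be > 0")
    out = {}
    for stage, count in stage_counts.items():
        area = disc_area
        if stage == Stage.ADULT:
            area = disc_area * adult_leaf_multiplier
        out[stage] = count * area / state.leaf_area
    return out
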