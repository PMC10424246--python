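"""Pass-number dosing plan for droplet-printed Transwell inserts.

Cells are deposited layer by layer ("passes") over the insert surface, so the
per-insert cell dose scales linearly with the pass count: 2200 cells per pass
gives 0.22–1.1 × 10⁵ cells for 10–50 passes, one-tenth to one-half of the
2.2 × 10⁵ cells used for conventional manual seeding.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PrintPlan", "cells_per_insert", "plan_summary", "MANUAL_SEEDING_CELLS"]

#: Per-insert cell count of the conventional manual-seeding reference.
MANUAL_SEEDING_CELLS = 2.2e5


@dataclass(frozen=True)
class PrintPlan:
    """A droplet-printing dosing plan for one Transwell insert.

    Parameters
    ----------
    passes : int
        Number of printed layers (>= 0).
    cells_per_pass : float
        Cells deposited per insert per pass. Default 2200.
    insert_diameter : float
        Transwell insert diameter in mm. Default 6.5.
    printed_spot_diameter : float
        Diameter of the printed circular spot in mm; must cover the insert.
        Default 7.0.
    est_time_per_pass : float
        Planning estimate of minutes per pass. Default 0.2 (10 passes ≈ 2 min).
    """

    passes: int
    cells_per_pass: float = 2200.0
    insert_diameter: float = 6.5
    printed_spot_diameter: float = 7.0
    est_time_per_pass: float = 0.2

    def __post_init__(self) -> None:
        if self.passes < 0:
            raise ValueError("passes must be >= 0")
        if self.cells_per_pass < 0 or self.est_time_per_pass < 0:
            raise ValueError("cells_per_pass and est_time_per_pass must be >= 0")
        if self.insert_diameter <= 0 or self.printed_spot_diameter <= 0:
            raise ValueError("diameters must be positive")
        if self.printed_spot_diameter < self.insert_diameter:
            raise ValueError(
                "printed spot must cover the insert "
                f"(spot {self.printed_spot_diameter} mm < "
                f"insert {self.insert_diameter} mm)"
            )


def cells_per_insert(plan: PrintPlan) -> float:
    """Total cells deposited per insert: passes × cells_per_pass."""
    return plan.passes * plan.cells_per_pass


def plan_summary(
    plan: PrintPlan, manual_reference: float = MANUAL_SEEDING_CELLS
) -> dict[str, float]:
    """Planning quantities for a print run.

    Returns ``cells`` (per insert), ``est_print_time_min`` and
    ``fraction_of_manual`` (dose relative to the manual-seeding reference).
    """
    if manual_reference <= 0:
        raise ValueError("manual_reference must be positive")
    cells = cells_per_insert(plan)
    return {
        "cells": cells,
        "est_print_time_min": plan.passes * plan.est_time_per_pass,
        "fraction_of_manual": cells / manual_reference,
    }
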