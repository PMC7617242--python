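"""Deterministic trial-design utilities.

Caliper-to-volume conversion, human-to-mouse dose conversion, stratified
"spiral" randomization by baseline tumor volume, and the dosing schedules
used by the two in vivo trial designs:

* design 1 — treatment starts at a fixed time after implantation; fixed
  mg doses converted from the human doses by relative body mass
  (60 kg human vs 20 g mouse, ratio 1/3000).
* design 2 — treatment starts at a fixed tumor volume (~100 mm^3) with
  stratified randomization; escalated per-weight (mg/kg) doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Total treatment duration in days (11 weeks).
TREATMENT_DURATION_DAYS = 77

#: Default reference masses for fixed-dose conversion.
HUMAN_MASS_KG = 60.0
MOUSE_MASS_G = 20.0


def tumor_volume(width_mm, height_mm):
    """Tumor volume in mm^3 from caliper width W and height H: TV = W^2 * H / 2.

    Accepts scalars or arrays; negative inputs are rejected.
    """
    w = np.asarray(width_mm, dtype=float)
    h = np.asarray(height_mm, dtype=float)
    if np.any(w < 0) or np.any(h < 0):
        raise ValueError("caliper measurements must be non-negative")
    out = w * w * h / 2.0
    return float(out) if out.ndim == 0 else out


def convert_human_fixed_dose(
    human_dose_mg: float,
    human_mass_kg: float = HUMAN_MASS_KG,
    mouse_mass_g: float = MOUSE_MASS_G,
) -> float:
    """Convert a fixed human dose (mg) to a mouse dose (mg) by body-mass ratio.

    At the default masses (60 kg human, 20 g mouse) the ratio is 1/3000,
    e.g. 150 mg -> 0.05 mg.
    """
    if human_dose_mg < 0:
        raise ValueError("dose must be non-negative")
    if human_mass_kg <= 0 or mouse_mass_g <= 0:
        raise ValueError("masses must be positive")
    return human_dose_mg * (mouse_mass_g / 1000.0) / human_mass_kg


def per_weight_dose(dose_mg_per_kg: float, mouse_mass_g: float = MOUSE_MASS_G) -> float:
    """Absolute mouse dose (mg) for a per-weight dose (mg/kg), e.g. 40 mg/kg at 20 g -> 0.8 mg."""
    if dose_mg_per_kg <= 0 or mouse_mass_g <= 0:
        raise ValueError("dose and mass must be positive")
    return dose_mg_per_kg * mouse_mass_g / 1000.0


def spiral_pattern(n: int, n_cohorts: int) -> np.ndarray:
    """Cohort labels (1-based) for ranks 0..n-1 in boustrophedon order.

    Sweeps alternate 1..k, k..1, 1..k, ...; when ``n_cohorts`` does not
    divide ``n`` the final sweep is simply truncated.
    """
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    idx = np.arange(n)
    sweep, pos = idx // n_cohorts, idx % n_cohorts
    return np.where(sweep % 2 == 0, pos + 1, n_cohorts - pos)


@dataclass
class CohortAssignment:
    """Result of spiral randomization: one cohort label per mouse."""

    mouse_ids: list
    volumes_mm3: np.ndarray
    cohorts: np.ndarray  # 1-based labels aligned with mouse_ids
    n_cohorts: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mouse": self.mouse_ids, "volume_mm3": self.volumes_mm3, "cohort": self.cohorts}
        )


def spiral_randomize(volumes, n_cohorts: int, mouse_ids=None) -> CohortAssignment:
    """Assign mice to cohorts balancing baseline tumor volume.

    Volumes are ranked low to high and cohorts assigned in a spiral
    (1-3, 3-1, 1-3, ... for three cohorts), which balances enrollment
    volumes across cohorts.  Ties are broken by the stable sort on
    (volume, mouse id), so the assignment is deterministic.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size == 0:
        raise ValueError("no volumes provided")
    if not 1 <= n_cohorts <= volumes.size:
        raise ValueError("need 1 <= n_cohorts <= number of mice")
    if mouse_ids is None:
        mouse_ids = list(range(len(volumes)))
    if len(mouse_ids) != len(volumes):
        raise ValueError("mouse_ids and volumes length mismatch")

    order = sorted(range(len(volumes)), key=lambda i: (volumes[i], str(mouse_ids[i])))
    labels_by_rank = spiral_pattern(len(volumes), n_cohorts)
    cohorts = np.empty(len(volumes), dtype=int)
    for rank, i in enumerate(order):
        cohorts[i] = labels_by_rank[rank]
    return CohortAssignment(list(mouse_ids), volumes, cohorts, n_cohorts)


@dataclass
class DosingSchedule:
    """Dosing schedule for one drug in one trial design.

    ``dose_mg`` is set for fixed-dose (design 1) schedules, ``dose_mg_per_kg``
    for per-weight (design 2 / monotherapy) schedules; exactly one is set.
    """

    drug: str
    route: str  # "iv" or "oral"
    cycle_length: int  # days
    dose_days_in_cycle: list = field(default_factory=list)  # 1-based days within cycle
    n_cycles: int = 4
    dose_mg: float | None = None
    dose_mg_per_kg: float | None = None
    design: int = 1

    def __post_init__(self) -> None:
        if (self.dose_mg is None) == (self.dose_mg_per_kg is None):
            raise ValueError("exactly one of dose_mg / dose_mg_per_kg must be set")
        dose = self.dose_mg if self.dose_mg is not None else self.dose_mg_per_kg
        if dose <= 0:
            raise ValueError("dose must be positive")
        if any(d < 1 or d > self.cycle_length for d in self.dose_days_in_cycle):
            raise ValueError("dose days must lie within the cycle")

    def dose_days(self) -> list[int]:
        """Absolute 1-based study days on which doses are given, over all cycles.

        The full cycle structure is kept (4 x 21-day cycles run to day 84)
        even though the analysis window constant is 77 days; the printed
        per-cycle dose days win over the window for scheduling.
        """
        return [
            (c * self.cycle_length) + d
            for c in range(self.n_cycles)
            for d in self.dose_days_in_cycle
        ]

    def dose_for_mouse(self, mouse_mass_g: float = MOUSE_MASS_G) -> float:
        """Per-administration dose in mg for a mouse of the given mass."""
        if self.dose_mg is not None:
            return self.dose_mg
        return per_weight_dose(self.dose_mg_per_kg, mouse_mass_g)

    def to_frame(self, mouse_mass_g: float = MOUSE_MASS_G) -> pd.DataFrame:
        dose = self.dose_for_mouse(mouse_mass_g)
        days = self.dose_days()
        return pd.DataFrame({"drug": self.drug, "day": days, "dose_mg": dose})


# Printed regimens.  Carboplatin design-1 dose (0.16 mg, from the human AUC5
# dose) is a constant: the pharmacokinetic inputs behind it are not available.
# Paclitaxel design-1 uses the tolerability-adjusted 0.07 mg actually
# administered (the naive mg/m^2 conversion would give 0.04 mg).
_COMBINATION = {
    "carboplatin": dict(route="iv", days=[1], d1_mg=0.16, d2_mgkg=40.0),
    "paclitaxel": dict(route="iv", days=[1, 8, 15], d1_mg=0.07, d2_mgkg=7.0),
    "olaparib": dict(route="oral", days=list(range(3, 15)), d1_mg=0.05, d2_mgkg=50.0),
}
_MONO = {
    "olaparib": dict(route="oral", mgkg=50.0),
    "AZD1775": dict(route="oral", mgkg=120.0),
}


def build_schedule(drug: str, design: int, regimen: str = "combination") -> DosingSchedule:
    """Dosing schedule for one drug under trial design 1 or 2.

    Combination (CT/CTO) schedules run 4 cycles of 21 days: carboplatin on
    day 1 of each cycle, paclitaxel on days 1/8/15, olaparib on days 3-14.
    Monotherapy schedules (olaparib 50 mg/kg, AZD1775 120 mg/kg) run 5 days
    on / 2 days off for the full 11 weeks.
    """
    if design not in (1, 2):
        raise ValueError(f"unknown trial design: {design!r}")
    if regimen == "combination":
        if drug not in _COMBINATION:
            raise ValueError(f"unknown combination-arm drug: {drug!r}")
        info = _COMBINATION[drug]
        kwargs = (
            dict(dose_mg=info["d1_mg"]) if design == 1 else dict(dose_mg_per_kg=info["d2_mgkg"])
        )
        return DosingSchedule(
            drug=drug,
            route=info["route"],
            cycle_length=21,
            dose_days_in_cycle=list(info["days"]),
            n_cycles=4,
            design=design,
            **kwargs,
        )
    if regimen == "monotherapy":
        if drug not in _MONO:
            raise ValueError(f"unknown monotherapy drug: {drug!r}")
        info = _MONO[drug]
        return DosingSchedule(
            drug=drug,
            route=info["route"],
            cycle_length=7,
            dose_days_in_cycle=[1, 2, 3, 4, 5],
            n_cycles=11,
            dose_mg_per_kg=info["mgkg"],
            design=design,
        )
    raise ValueError(f"unknown regimen: {regimen!r}")
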