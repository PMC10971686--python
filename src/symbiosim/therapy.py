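"""GLUT1 / MCT1 inhibitor pharmacology.

Drugs are diffusible substances held at a (possibly time-varying) boundary
concentration; they reach cells by pure diffusion.  At each phenotype step a
drug activates its inhibitor-input node in the cell's regulatory network
with the saturable probability

    P(inhibit) = e_max * C / (IC50 + C),        e_max = 0.85 by default,

drawn fresh per cell and step (memoryless, consistent with reversible
binding).  Three administration strategies are modelled: continuous dosing,
alternating windows (lactate-intake blocker first, then the glucose-uptake
blocker, and so on), and simultaneous periodic dosing (both drugs on, then a
therapy-free interval of the same length); the control arm runs both drugs
continuously at half dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DrugSpec",
    "Schedule",
    "inhibition_probability",
    "apply_inhibition",
    "boundary_dose_at",
]

SCHEDULE_MODES = ("continuous", "alternating", "simultaneous_periodic", "control", "none")


@dataclass(frozen=True)
class DrugSpec:
    """One inhibitor: which network node it activates and its potency."""

    name: str
    target_inhibitor_node: str
    ic50: float = 1.0
    e_max: float = 0.85
    boundary_multiple: float = 1.0  # dose as a multiple of ic50

    def __post_init__(self):
        if not 0 < self.e_max <= 1:
            raise ValueError("e_max must lie in (0, 1]")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.boundary_multiple < 0:
            raise ValueError("boundary_multiple must be >= 0")

    @property
    def dose(self) -> float:
        return self.boundary_multiple * self.ic50


@dataclass(frozen=True)
class Schedule:
    """Administration strategy; period and duration in days."""

    mode: str = "none"
    period: float = 5.0
    duration: float = float("inf")

    def __post_init__(self):
        if self.mode not in SCHEDULE_MODES:
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.mode in ("alternating", "simultaneous_periodic") and self.period <= 0:
            raise ValueError("period must be positive for periodic modes")


def inhibition_probability(concentration: float, drug: DrugSpec) -> float:
    """Saturable per-step inhibition probability e_max*C/(IC50+C)."""
    if np.any(np.asarray(concentration) < 0):
        raise ValueError("concentration must be >= 0")
    return drug.e_max * concentration / (drug.ic50 + concentration)


def apply_inhibition(
    drugs: Iterable[DrugSpec],
    local: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Bernoulli draw per drug at the cell's local drug concentration.

    Returns inhibitor-node values (1 = inhibited this step).  A drug whose
    field is absent from ``local`` contributes 0.
    """
    out: dict[str, int] = {}
    for drug in drugs:
        conc = local[drug.name] if drug.name in local else 0.0
        p = inhibition_probability(conc, drug)
        out[drug.target_inhibitor_node] = 1 if (p > 0 and rng.random() < p) else 0
    return out


def boundary_dose_at(t_days: float, drug: DrugSpec, schedule: Schedule, drug_index: int = 0) -> float:
    """Boundary concentration of ``drug`` at time ``t_days``.

    ``drug_index`` orders the two drugs for the alternating mode: index 0
    (the lactate-intake blocker, administered first) is on during even
    windows, index 1 during odd windows.
    """
    if t_days < 0:
        raise ValueError("t must be >= 0")
    if schedule.mode == "none" or t_days >= schedule.duration:
        return 0.0
    if schedule.mode == "continuous":
        return drug.dose
    if schedule.mode == "control":
        return 0.5 * drug.dose
    window = int(t_days // schedule.period)
    if schedule.mode == "alternating":
        return drug.dose if window % 2 == (drug_index % 2) else 0.0
    # simultaneous_periodic: both drugs on during even windows
    return drug.dose if window % 2 == 0 else 0.0
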