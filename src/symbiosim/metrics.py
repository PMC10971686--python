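"""Population accounting and the metabolic symbiosis index (MSI).

The tumour's occupied sites are partitioned into oxygenated and hypoxic
regions by an oxygen cutoff (by default the same activation threshold that
drives the cells' own Oxygen_supply input, keeping the metric consistent
with the dynamics).  Over the *active* cells of each region, phi_L is the
fraction of lactate-metabolic cells (mitochondrial ATP fuelled through the
MCT1-dependent lactate-intake branch) and phi_G the fraction of glycolytic
cells.  Then

    MSI = (phi_L(A_oxy) - phi_G(A_oxy)) / (phi_L(A_oxy) + phi_G(A_oxy))

when phi_L(A_oxy) > phi_G(A_oxy) and phi_L(A_hypo) < phi_G(A_hypo), and
MSI = 0 otherwise (including when either region has no active cell).  The
index runs from 0 (no symbiosis) to 1 (full division of labour).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "RegionPartition",
    "MSIRecord",
    "PopulationCounts",
    "partition_regions",
    "is_lactate_metabolic",
    "is_glycolytic",
    "compute_msi",
    "count_populations",
    "symbiosis_effect_map",
]

#: network node marking the MCT1-dependent lactate-intake branch
LACTATE_BRANCH_NODE = "Lactate_oxidation"


@dataclass(frozen=True)
class RegionPartition:
    """Disjoint, covering split of occupied tumour sites by oxygenation."""

    oxygenated_sites: frozenset
    hypoxic_sites: frozenset
    oxygen_cutoff: float

    def __post_init__(self):
        if self.oxygenated_sites & self.hypoxic_sites:
            raise ValueError("region partition is not disjoint")


@dataclass(frozen=True)
class MSIRecord:
    time: float
    phi_L_oxy: float
    phi_G_oxy: float
    phi_L_hypo: float
    phi_G_hypo: float
    msi: float


@dataclass(frozen=True)
class PopulationCounts:
    total: int = 0          # all cells including dead
    active: int = 0         # metabolically active (either pathway bit set)
    glycoATP: int = 0
    mitoATP: int = 0
    both: int = 0           # overlap (cells running both pathways)
    necrotic: int = 0
    hypoxic: int = 0        # live cells below the oxygen cutoff
    oxygenated: int = 0
    per_tag_total: Mapping[str, int] = field(default_factory=dict)
    per_tag_active: Mapping[str, int] = field(default_factory=dict)


def _cell_active(cell) -> bool:
    return not cell.necrotic and (cell.glyco_bit or cell.mito_bit)


def is_glycolytic(cell) -> bool:
    """Cell relies on glycolysis for ATP (glycoATP bit set)."""
    return bool(cell.glyco_bit) and not cell.necrotic


def is_lactate_metabolic(cell) -> bool:
    """Mitochondrial ATP fuelled by exogenous lactate: mitoATP set with the
    MCT1-dependent intake branch active.  Falls back to MCT1 AND
    Lactate_supply when the network has no explicit branch node."""
    if cell.necrotic or not cell.mito_bit:
        return False
    values = cell.net_state.values
    if LACTATE_BRANCH_NODE in values:
        return bool(values[LACTATE_BRANCH_NODE])
    return bool(values.get("MCT1", 0) and values.get("Lactate_supply", 0))


def partition_regions(cells: Iterable, oxygen_field, cutoff: float) -> RegionPartition:
    oxy, hypo = set(), set()
    for c in cells:
        site = tuple(c.site)
        if oxygen_field.values[site] >= cutoff:
            oxy.add(site)
        else:
            hypo.add(site)
    return RegionPartition(frozenset(oxy), frozenset(hypo), cutoff)


def compute_msi(cells: Iterable, fields: Mapping, cutoff: float, time: float = 0.0) -> MSIRecord:
    """Evaluate the symbiosis index over the active cells of each region."""
    oxygen = fields["oxygen"]
    n_oxy = n_hypo = 0
    l_oxy = g_oxy = l_hypo = g_hypo = 0
    for c in cells:
        if not _cell_active(c):
            continue
        lac = is_lactate_metabolic(c)
        gly = is_glycolytic(c)
        if oxygen.values[tuple(c.site)] >= cutoff:
            n_oxy += 1
            l_oxy += lac
            g_oxy += gly
        else:
            n_hypo += 1
            l_hypo += lac
            g_hypo += gly
    if n_oxy == 0 or n_hypo == 0:
        phi = (
            l_oxy / n_oxy if n_oxy else 0.0,
            g_oxy / n_oxy if n_oxy else 0.0,
            l_hypo / n_hypo if n_hypo else 0.0,
            g_hypo / n_hypo if n_hypo else 0.0,
        )
        return MSIRecord(time, *phi, 0.0)
    phi_l_oxy, phi_g_oxy = l_oxy / n_oxy, g_oxy / n_oxy
    phi_l_hypo, phi_g_hypo = l_hypo / n_hypo, g_hypo / n_hypo
    msi = 0.0
    if phi_l_oxy > phi_g_oxy and phi_l_hypo < phi_g_hypo:
        msi = (phi_l_oxy - phi_g_oxy) / (phi_l_oxy + phi_g_oxy)
    return MSIRecord(time, phi_l_oxy, phi_g_oxy, phi_l_hypo, phi_g_hypo, msi)


def count_populations(cells: Iterable, fields: Mapping, cutoff: float) -> PopulationCounts:
    total = active = glyco = mito = both = necrotic = hypoxic = oxygenated = 0
    per_tag_total: dict[str, int] = {}
    per_tag_active: dict[str, int] = {}
    oxygen = fields["oxygen"]
    for c in cells:
        total += 1
        tag = c.population_tag
        per_tag_total[tag] = per_tag_total.get(tag, 0) + 1
        if c.necrotic:
            necrotic += 1
            continue
        g, m = bool(c.glyco_bit), bool(c.mito_bit)
        if g or m:
            active += 1
            per_tag_active[tag] = per_tag_active.get(tag, 0) + 1
        glyco += g
        mito += m
        both += g and m
        if oxygen.values[tuple(c.site)] >= cutoff:
            oxygenated += 1
        else:
            hypoxic += 1
    per_tag_active = {t: per_tag_active.get(t, 0) for t in per_tag_total}
    return PopulationCounts(
        total, active, glyco, mito, both, necrotic, hypoxic, oxygenated,
        per_tag_total, per_tag_active,
    )


def symbiosis_effect_map(run_wt, run_ko, substance: str) -> np.ndarray:
    """Percentage change 100*(C_wt - C_ko)/C_ko along the centre
    cross-section over time, NaN-masked where C_ko = 0.

    ``run_wt`` and ``run_ko`` are paired :class:`SimulationResult` objects
    sharing seed and config apart from the perturbation under study.
    """
    prof_wt = run_wt.profiles[substance]
    prof_ko = run_ko.profiles[substance]
    if prof_wt.shape != prof_ko.shape:
        raise ValueError(
            f"paired runs disagree in profile shape: {prof_wt.shape} vs {prof_ko.shape}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (prof_wt - prof_ko) / prof_ko
    change[prof_ko == 0] = np.nan
    return change
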