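"""Stoichiometric consumption/production rates.

Rates follow Monod (saturating) kinetics in the local substrate
concentrations and are switched by the cell's two pathway bits, glycoATP and
mitoATP, which the regulatory network provides each phenotype step:

* OXPHOS consumes 6 O2 per glucose and yields ``A0`` (28-36) ATP per glucose.
* Glycolysis yields 2 ATP, 2 lactate and 2 protons per glucose; a glycolytic
  cell still draws a fraction ``K_glyco`` (default 0.5) of the maximal oxygen
  rate for other biosynthetic processes.
* Reverse Warburg: exogenous lactate is oxidised at 3 O2 per lactate.

All rates are molar-equivalent (mM/h); the microenvironment layer converts
the oxygen rate to %O2/h via the solubility constant in the scenario config.
Functions accept scalars or numpy arrays for the concentrations and bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "MetabolicParams",
    "MetabolicState",
    "LocalConcentrations",
    "monod",
    "oxygen_rate",
    "glucose_rate",
    "atp_rate",
    "lactate_production_rate",
    "lactate_consumption_rate",
    "proton_rate",
    "ph_of",
    "max_atp_rate",
    "proliferation_energy_ok",
]


@dataclass(frozen=True)
class MetabolicParams:
    """Stoichiometric constants.

    mu_o2
        Maximum oxygen consumption rate (mM/h, molar-equivalent).
    K_o2, K_G, K_L
        Half-saturation coefficients for oxygen (%O2), glucose (mM) and
        lactate (mM).
    A0
        ATP yield per glucose under OXPHOS (dimensionless, 28-36).
    K_glyco
        Fraction of the maximal oxygen rate consumed during glycolysis.
    beta
        Proton buffering coefficient of the microenvironment.
    atp_gate_fraction
        Proliferation requires an ATP rate of at least this fraction of the
        saturating-substrate maximum (default 0.8).
    """

    mu_o2: float = 4.3
    K_o2: float = 0.45
    K_G: float = 0.04
    K_L: float = 0.3
    A0: float = 30.0
    K_glyco: float = 0.5
    beta: float = 0.001
    atp_gate_fraction: float = 0.8

    def __post_init__(self):
        for name in ("mu_o2", "K_o2", "K_G", "K_L", "A0", "K_glyco", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.K_glyco > 1:
            raise ValueError("K_glyco must be <= 1")
        if self.beta > 1:
            raise ValueError("beta must be <= 1")
        if not 28 <= self.A0 <= 36:
            raise ValueError("A0 must lie in [28, 36]")
        if not 0 < self.atp_gate_fraction < 1:
            raise ValueError("atp_gate_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class MetabolicState:
    """The cell's pathway bits, provided by its regulatory network."""

    glycoATP: int = 0
    mitoATP: int = 0

    def __post_init__(self):
        if self.glycoATP not in (0, 1) or self.mitoATP not in (0, 1):
            raise ValueError("pathway bits must be 0 or 1")


@dataclass(frozen=True)
class LocalConcentrations:
    """Concentrations at a cell's site: oxygen in %O2, glucose/lactate in mM,
    protons in molar; growth factors and drugs by name in ``extra``."""

    oxygen: float = 0.0
    glucose: float = 0.0
    lactate: float = 0.0
    protons: float = 0.0
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("oxygen", "glucose", "lactate", "protons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be non-negative")

    def __getitem__(self, name: str) -> float:
        if name in ("oxygen", "glucose", "lactate", "protons"):
            return getattr(self, name)
        return self.extra[name]

    def __contains__(self, name: str) -> bool:
        return name in ("oxygen", "glucose", "lactate", "protons") or name in self.extra


def monod(C, K):
    """Saturating Monod factor C/(K+C)."""
    C = np.asarray(C, dtype=float)
    return C / (K + C)


def oxygen_rate(local, ms: MetabolicState, p: MetabolicParams):
    """R_o2 = mu_o2 * MonodO2 * (mitoATP + K_glyco * glycoATP)."""
    return p.mu_o2 * monod(local.oxygen, p.K_o2) * (ms.mitoATP + p.K_glyco * ms.glycoATP)


def glucose_rate(local, ms: MetabolicState, p: MetabolicParams):
    """OXPHOS draws glucose at mu_o2/6 (1 glucose : 6 O2); glycolysis draws
    (A0/2)-fold more so that both pathways support similar ATP rates."""
    mito = (p.mu_o2 / 6.0) * monod(local.oxygen, p.K_o2) * monod(local.glucose, p.K_G)
    glyco = (p.mu_o2 / 6.0) * (p.A0 / 2.0) * monod(local.glucose, p.K_G)
    return mito * ms.mitoATP + glyco * ms.glycoATP


def atp_rate(local, ms: MetabolicState, p: MetabolicParams):
    """ATP production rate; by construction both pathways reach the same
    saturating maximum A0*mu_o2/6."""
    mito = p.A0 * (p.mu_o2 / 6.0) * monod(local.oxygen, p.K_o2) * monod(local.glucose, p.K_G)
    glyco = p.A0 * (p.mu_o2 / 6.0) * monod(local.glucose, p.K_G)
    return mito * ms.mitoATP + glyco * ms.glycoATP


def lactate_production_rate(local, ms: MetabolicState, p: MetabolicParams):
    """Two lactate per glucose under glycolysis."""
    return 2.0 * (p.mu_o2 / 6.0) * (p.A0 / 2.0) * monod(local.glucose, p.K_G) * ms.glycoATP


def lactate_consumption_rate(local, ms: MetabolicState, p: MetabolicParams):
    """Reverse Warburg lactate intake: 1 lactate per 3 O2."""
    return (
        2.0
        * (p.mu_o2 / 6.0)
        * monod(local.oxygen, p.K_o2)
        * monod(local.lactate, p.K_L)
        * ms.mitoATP
    )


def proton_rate(local, ms: MetabolicState, p: MetabolicParams):
    """Two protons per glucose under glycolysis, damped by the buffering
    coefficient beta."""
    return p.beta * p.A0 * (p.mu_o2 / 6.0) * monod(local.glucose, p.K_G) * ms.glycoATP


def ph_of(protons) -> float:
    """pH = -log10([H+]) with [H+] in molar."""
    protons = np.asarray(protons, dtype=float)
    if np.any(protons <= 0):
        raise ValueError("pH is undefined for a non-positive proton concentration")
    return -np.log10(protons)


def max_atp_rate(p: MetabolicParams) -> float:
    """Saturating-substrate maximum of the ATP rate (either pathway)."""
    return p.A0 * p.mu_o2 / 6.0


def proliferation_energy_ok(local, ms: MetabolicState, p: MetabolicParams):
    """True iff the ATP rate reaches atp_gate_fraction of the maximum."""
    return atp_rate(local, ms, p) >= p.atp_gate_fraction * max_atp_rate(p)
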