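"""2D diffusion-reaction microenvironment.

Each soluble substance (oxygen, glucose, lactate, protons, growth factors,
inhibitors) lives on a per-site concentration grid.  Because substances
diffuse on a time scale of seconds while phenotypes change over hours, every
field is relaxed to the steady state D * lap(C) = sink between phenotype
updates, with the concentration pinned at its boundary value on the domain
edge (Dirichlet).  Sinks are assembled from the resident cells' metabolic
rates (consumption positive, production negative) and, since those rates are
Monod functions of the field itself, an outer fixed-point loop re-evaluates
the sinks a few times per phenotype step.

The solver is a 5-point finite-difference red-black SOR relaxation with
concentrations clamped at >= 0; a direct sparse solve of the same
discretisation serves as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .metabolism import (
    MetabolicParams,
    monod,
)

__all__ = [
    "Lattice",
    "SubstanceSpec",
    "Field",
    "SolverError",
    "assemble_sinks",
    "solve_steady_state",
    "equilibrate",
    "CANONICAL_SUBSTANCES",
]

#: substances whose sinks come from the stoichiometric rate equations
CANONICAL_SUBSTANCES = ("oxygen", "glucose", "lactate", "protons")


class SolverError(RuntimeError):
    """Relaxation failed to reach the requested residual."""


@dataclass(frozen=True)
class Lattice:
    """Square 2D lattice; one cell slot per site; spacing in micrometres."""

    nx: int = 100
    ny: int = 100
    spacing: float = 20.0

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise ValueError("lattice must be at least 3x3")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def centre(self) -> tuple[int, int]:
        return (self.nx // 2, self.ny // 2)


@dataclass(frozen=True)
class SubstanceSpec:
    """Diffusion/boundary contract for one substance.

    D is in lattice-site^2 per hour; ``mM_to_field`` converts the molar
    (mM/h) rates of the metabolism module into field units per hour (e.g.
    1/solubility for oxygen tracked in %O2, 1e-3 for protons in molar).
    """

    name: str
    D: float
    boundary_value: float
    role: str = "nutrient"  # nutrient | metabolite | growth_factor | inhibitor
    gamma_consume: float = 0.0
    gamma_produce: float = 0.0
    mM_to_field: float = 1.0

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.boundary_value < 0 or self.gamma_consume < 0 or self.gamma_produce < 0:
            raise ValueError("boundary value and gamma coefficients must be >= 0")
        if self.role not in ("nutrient", "metabolite", "growth_factor", "inhibitor"):
            raise ValueError(f"unknown substance role {self.role!r}")


@dataclass
class Field:
    """Concentration grid for one substance."""

    spec: SubstanceSpec
    values: np.ndarray

    @classmethod
    def uniform(cls, spec: SubstanceSpec, lattice: Lattice) -> "Field":
        return cls(spec, np.full(lattice.shape, float(spec.boundary_value)))

    def at(self, site: tuple[int, int]) -> float:
        return float(self.values[site])

    def apply_boundary(self) -> None:
        v = self.values
        v[0, :] = v[-1, :] = self.spec.boundary_value
        v[:, 0] = v[:, -1] = self.spec.boundary_value


# ---------------------------------------------------------------------------
# Sink assembly


def _cell_arrays(cells) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Site indices plus pathway bits for non-necrotic cells."""
    xs, ys, glyco, mito = [], [], [], []
    for c in cells:
        if getattr(c, "necrotic", False):
            continue
        i, j = c.site
        xs.append(i)
        ys.append(j)
        glyco.append(c.glyco_bit)
        mito.append(c.mito_bit)
    return (
        np.asarray(xs, dtype=int),
        np.asarray(ys, dtype=int),
        np.asarray(glyco, dtype=float),
        np.asarray(mito, dtype=float),
    )


def assemble_sinks(
    cells: Iterable,
    substance: str,
    fields: Mapping[str, Field],
    params: MetabolicParams,
    lattice: Lattice,
) -> np.ndarray:
    """Per-site net rate map for one substance (consumption positive,
    production negative, in field units per hour).

    Oxygen/glucose/lactate/proton sinks follow the stoichiometric rate
    equations evaluated at the resident cell's pathway bits; lactate couples
    consumption minus production; protons are pure production.  Growth
    factors and inhibitors use the first-order gamma forms at every live cell
    site.  Necrotic cells (and metabolically inactive cells, whose bits are
    both zero) contribute nothing to the stoichiometric sinks.
    """
    if substance not in fields:
        raise KeyError(f"unknown substance {substance!r}")
    spec = fields[substance].spec
    sinks = np.zeros(lattice.shape)
    xs, ys, glyco, mito = _cell_arrays(cells)
    if xs.size == 0:
        return sinks
    scale = spec.mM_to_field
    p = params
    if substance in CANONICAL_SUBSTANCES:
        o2 = fields["oxygen"].values[xs, ys]
        mon_o2 = monod(o2, p.K_o2)
        if substance == "oxygen":
            rate = p.mu_o2 * mon_o2 * (mito + p.K_glyco * glyco)
        elif substance == "glucose":
            mon_g = monod(fields["glucose"].values[xs, ys], p.K_G)
            rate = (p.mu_o2 / 6.0) * mon_o2 * mon_g * mito + (p.mu_o2 / 6.0) * (
                p.A0 / 2.0
            ) * mon_g * glyco
        elif substance == "lactate":
            mon_g = monod(fields["glucose"].values[xs, ys], p.K_G)
            mon_l = monod(fields["lactate"].values[xs, ys], p.K_L)
            consume = 2.0 * (p.mu_o2 / 6.0) * mon_o2 * mon_l * mito
            produce = 2.0 * (p.mu_o2 / 6.0) * (p.A0 / 2.0) * mon_g * glyco
            rate = consume - produce
        else:  # protons: production only
            mon_g = monod(fields["glucose"].values[xs, ys], p.K_G)
            rate = -p.beta * p.A0 * (p.mu_o2 / 6.0) * mon_g * glyco
        np.add.at(sinks, (xs, ys), rate * scale)
    elif spec.role == "growth_factor":
        conc = fields[substance].values[xs, ys]
        np.add.at(sinks, (xs, ys), spec.gamma_consume * conc - spec.gamma_produce)
    elif spec.role == "inhibitor":
        conc = fields[substance].values[xs, ys]
        np.add.at(sinks, (xs, ys), spec.gamma_consume * conc)
    else:
        raise KeyError(
            f"substance {substance!r} has no stoichiometric rule and role "
            f"{spec.role!r} defines no gamma form"
        )
    return sinks


# ---------------------------------------------------------------------------
# Steady-state solver


def solve_steady_state(
    fld: Field,
    sinks: np.ndarray,
    tol: float = 1e-6,
    spacing: float = 1.0,
    omega: float | None = None,
    max_iter: int = 50_000,
) -> Field:
    """Relax D*lap(C) = sink to steady state with Dirichlet edges.

    Red-black SOR on the 5-point Laplacian; concentrations are clamped at
    >= 0 (a sink cannot drive a negative concentration).  ``tol`` bounds the
    maximum residual of the discrete equation relative to the field scale;
    sites pinned at the clamp are excluded from the residual.  Raises
    :class:`SolverError` if the residual is not reached within ``max_iter``
    sweeps.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    C = fld.values
    nx, ny = C.shape
    if sinks.shape != C.shape:
        raise ValueError("sink map shape does not match the field")
    fld.apply_boundary()
    # right-hand side of the interior update: C_ij = mean(neighbours) - g_ij
    g = sinks * (spacing**2) / (4.0 * fld.spec.D)
    if omega is None:
        n = max(nx, ny)
        omega = 2.0 / (1.0 + np.sin(np.pi / n))

    red = np.zeros((nx, ny), dtype=bool)
    ii, jj = np.indices((nx, ny))
    red[1:-1, 1:-1] = ((ii + jj) % 2 == 0)[1:-1, 1:-1]
    black = np.zeros((nx, ny), dtype=bool)
    black[1:-1, 1:-1] = ~red[1:-1, 1:-1]

    def sweep(mask):
        nb = np.zeros_like(C)
        nb[1:-1, 1:-1] = (
            C[:-2, 1:-1] + C[2:, 1:-1] + C[1:-1, :-2] + C[1:-1, 2:]
        )
        target = nb / 4.0 - g
        C[mask] += omega * (target[mask] - C[mask])
        np.maximum(C, 0.0, out=C)

    def residual():
        nb = (
            C[:-2, 1:-1] + C[2:, 1:-1] + C[1:-1, :-2] + C[1:-1, 2:]
        )
        r = nb / 4.0 - g[1:-1, 1:-1] - C[1:-1, 1:-1]
        # ignore clamped sites whose unconstrained solution would be negative
        clamped = (C[1:-1, 1:-1] == 0.0) & (r < 0)
        r = np.where(clamped, 0.0, r)
        scale = max(float(np.max(np.abs(C))), float(fld.spec.boundary_value), 1e-300)
        return float(np.max(np.abs(r))) / scale

    for it in range(max_iter):
        sweep(red)
        sweep(black)
        if it % 8 == 7 and residual() < tol:
            break
    else:
        raise SolverError(
            f"steady-state relaxation for {fld.spec.name!r} did not reach "
            f"tol={tol:g} within {max_iter} sweeps (residual {residual():.3e})"
        )
    fld.apply_boundary()
    return fld


def equilibrate(
    fields: Mapping[str, Field],
    cells: Iterable,
    params: MetabolicParams,
    lattice: Lattice,
    n_outer: int = 3,
    tol: float = 1e-6,
) -> None:
    """Outer fixed-point loop: re-evaluate the Monod sinks against the
    updated fields ``n_outer`` times, relaxing every substance each pass."""
    cells = list(cells)
    for _ in range(max(1, n_outer)):
        for name, fld in fields.items():
            sinks = assemble_sinks(cells, name, fields, params, lattice)
            solve_steady_state(fld, sinks, tol=tol, spacing=1.0)


def field_to_text(fld: Field, path) -> None:
    """Write a field as a plain-matrix text grid."""
    np.savetxt(path, fld.values, fmt="%.8g")
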