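"""Preset scenario configurations.

``paper`` scale mirrors the full study conditions (100x100 lattice, 25
simulated days); ``desk`` scale is a smaller, faster configuration (50x50
lattice, 15 days) whose maximum oxygen consumption rate is raised so that
the oxygen penetration depth scales with the smaller domain — the tumour
traverses the same normoxic → hypoxic → symbiotic progression at a size a
workstation can sweep.  See docs/methods.md for the scaling argument.
"""

from __future__ import annotations


from .config import (
    NecrosisThresholds,
    PopulationSpec,
    ScenarioConfig,
    TimeScales,
    default_substances,
)
from .environment import Lattice, SubstanceSpec
from .metabolism import MetabolicParams
from .network import Perturbation
from .therapy import DrugSpec, Schedule

__all__ = ["baseline", "competition", "drug_scenario", "add_drug_fields"]

_SCALES = {
    # (nx, ny, mu_o2, duration_days)
    "paper": (100, 100, 4.3, 25.0),
    "desk": (50, 50, 16.0, 16.0),
}


def _pert(p53: str, mct1: str) -> tuple[Perturbation, ...]:
    out = []
    if p53 in ("ko", "-", "knockout"):
        out.append(Perturbation("p53", "knockout"))
    elif p53 not in ("wt", "+", "wild-type"):
        raise ValueError(f"unknown p53 status {p53!r}")
    if mct1 in ("ko", "-", "knockout"):
        out.append(Perturbation("MCT1", "knockout"))
    elif mct1 not in ("wt", "+", "wild-type"):
        raise ValueError(f"unknown MCT1 status {mct1!r}")
    return tuple(out)


def baseline(
    scale: str = "desk",
    p53: str = "wt",
    mct1: str = "wt",
    oxygen: float = 6.0,
    glucose: float = 5.0,
    lactate: float = 1.0,
    duration_days: float | None = None,
    initial_cells: int = 100,
    replicates: int = 10,
    base_seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """Single-population tumour growth under constant boundary nutrients."""
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(_SCALES)}")
    nx, ny, mu_o2, days = _SCALES[scale]
    if duration_days is not None:
        days = duration_days
    cfg = ScenarioConfig(
        lattice=Lattice(nx=nx, ny=ny),
        substances=default_substances(oxygen, glucose, lactate),
        metabolic=MetabolicParams(mu_o2=mu_o2),
        populations=(PopulationSpec(tag=f"p53{p53}_MCT1{mct1}", fraction=1.0,
                                    perturbations=_pert(p53, mct1)),),
        initial_cells=initial_cells,
        duration_h=days * 24.0,
        replicates=replicates,
        base_seed=base_seed,
    )
    return cfg.replace(**overrides) if overrides else cfg


def competition(
    scale: str = "desk",
    glucose: float = 1.0,
    lactate: float = 5.0,
    oxygen: float = 6.0,
    p53: str = "ko",
    duration_days: float | None = None,
    **overrides,
) -> ScenarioConfig:
    """Two populations mixed 1:1 — symbiosis-capable (MCT1wt) versus
    MCT1-knockout — competing for the configured boundary nutrients."""
    cfg = baseline(scale=scale, p53=p53, oxygen=oxygen, glucose=glucose,
                   lactate=lactate, duration_days=duration_days)
    pops = (
        PopulationSpec(tag="MCT1wt", fraction=0.5, perturbations=_pert(p53, "wt")),
        PopulationSpec(tag="MCT1-", fraction=0.5, perturbations=_pert(p53, "ko")),
    )
    cfg = cfg.replace(populations=pops)
    return cfg.replace(**overrides) if overrides else cfg


def add_drug_fields(cfg: ScenarioConfig, drugs: tuple[DrugSpec, ...]) -> ScenarioConfig:
    """Give every drug a diffusible substance field (diffusivity mirrors
    glucose; first-order cellular uptake)."""
    subs = dict(cfg.substances)
    for drug in drugs:
        subs[drug.name] = SubstanceSpec(
            drug.name, D=4500.0, boundary_value=0.0, role="inhibitor",
            gamma_consume=0.05,
        )
    return cfg.replace(substances=subs, drugs=drugs)


def drug_scenario(
    mode: str = "continuous",
    dose_multiple: float = 10.0,
    period_days: float = 5.0,
    scale: str = "desk",
    p53: str = "ko",
    duration_days: float | None = None,
    glut1i_multiple: float | None = None,
    **overrides,
) -> ScenarioConfig:
    """MCT1i + GLUT1i administration.  Modes: continuous, alternating,
    simultaneous_periodic, control (both continuous at half dose), none."""
    cfg = baseline(scale=scale, p53=p53, duration_days=duration_days)
    drugs = (
        DrugSpec("mct1i", target_inhibitor_node="MCT1I", ic50=1.0,
                 boundary_multiple=dose_multiple),
        DrugSpec("glut1i", target_inhibitor_node="GLUT1I", ic50=1.0,
                 boundary_multiple=(dose_multiple if glut1i_multiple is None
                                    else glut1i_multiple)),
    )
    cfg = add_drug_fields(cfg, drugs)
    cfg = cfg.replace(schedule=Schedule(mode=mode, period=period_days))
    return cfg.replace(**overrides) if overrides else cfg
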