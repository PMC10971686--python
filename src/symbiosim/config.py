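"""Scenario configuration: the reproducibility surface of the simulator.

A :class:`ScenarioConfig` bundles everything one run needs — lattice and
time scales, substance specs with boundary values, stoichiometric constants,
the regulatory-network file, perturbations and population composition, drug
schedule, duration, replicate count and base seed.  Configs round-trip
through YAML and are schema-validated with field-path error messages.

Units: time in hours, lengths in lattice sites (site spacing in µm), oxygen
in %O2, glucose/lactate in mM, protons in molar.  The oxygen solubility
constant (mM per %O2) converts molar metabolic rates into %O2/h for the
oxygen field.

Baseline numeric values not printed in the source literature's main text
(diffusion coefficients, activation thresholds, time scales, mu_o2, necrosis
criticals) are supplementary-derived defaults, declared here once and
flagged as such; see docs/methods.md for how they were chosen.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .environment import Lattice, SubstanceSpec
from .metabolism import MetabolicParams
from .network import (
    NetworkDefinition,
    Perturbation,
    load_default_network,
    load_network,
)
from .therapy import DrugSpec, Schedule

__all__ = [
    "TimeScales",
    "NecrosisThresholds",
    "PopulationSpec",
    "ScenarioConfig",
    "ConfigError",
    "O2_SOLUBILITY_MM_PER_PERCENT",
    "default_substances",
]

#: Henry-law solubility of oxygen in tissue at 37 C, mM per %O2.
O2_SOLUBILITY_MM_PER_PERCENT = 0.013


class ConfigError(ValueError):
    """Schema violation; the message names the offending field path."""


@dataclass(frozen=True)
class TimeScales:
    """Nested time scales (hours).  The network tick is implicit: each
    phenotype step performs ``n_sweeps`` full asynchronous sweeps."""

    t_phenotype: float = 1.0
    t_diffusion: float = 1.0
    t_division: float = 24.0
    t_q: float = 3.0
    n_sweeps: int = 1

    def __post_init__(self):
        for name in ("t_phenotype", "t_diffusion", "t_division", "t_q"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"times.{name} must be positive")
        if self.t_phenotype > self.t_division:
            raise ConfigError("times.t_phenotype must not exceed times.t_division")
        if self.n_sweeps < 1:
            raise ConfigError("times.n_sweeps must be >= 1")


@dataclass(frozen=True)
class NecrosisThresholds:
    """A cell becomes necrotic when oxygen AND glucose are both below these
    critical values (supplementary-derived defaults)."""

    oxygen_critical: float = 0.1  # %O2
    glucose_critical: float = 0.1  # mM

    def __post_init__(self):
        if self.oxygen_critical <= 0 or self.glucose_critical <= 0:
            raise ConfigError("necrosis thresholds must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """One initial sub-population: a tag, its mixing fraction and the
    perturbations (knockouts/enrichments) its cells carry."""

    tag: str = "wt"
    fraction: float = 1.0
    perturbations: tuple[Perturbation, ...] = ()

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ConfigError(f"population {self.tag!r}: fraction must lie in (0, 1]")


def default_substances(
    oxygen_boundary: float = 6.0,
    glucose_boundary: float = 5.0,
    lactate_boundary: float = 1.0,
) -> dict[str, SubstanceSpec]:
    """The baseline substance block (diffusivities in site^2/h for 20 µm
    sites; all values supplementary-derived)."""
    return {
        "oxygen": SubstanceSpec(
            "oxygen", D=18000.0, boundary_value=oxygen_boundary, role="nutrient",
            mM_to_field=1.0 / O2_SOLUBILITY_MM_PER_PERCENT,
        ),
        "glucose": SubstanceSpec("glucose", D=4500.0, boundary_value=glucose_boundary),
        "lactate": SubstanceSpec("lactate", D=5000.0, boundary_value=lactate_boundary,
                                 role="metabolite"),
        "protons": SubstanceSpec("protons", D=20000.0, boundary_value=10 ** -7.4,
                                 role="metabolite", mM_to_field=1e-3),
        "tgfa": SubstanceSpec("tgfa", D=900.0, boundary_value=0.0, role="growth_factor",
                              gamma_consume=0.1, gamma_produce=1e-3),
    }


@dataclass(frozen=True)
class ScenarioConfig:
    lattice: Lattice = field(default_factory=Lattice)
    times: TimeScales = field(default_factory=TimeScales)
    substances: Mapping[str, SubstanceSpec] = field(default_factory=default_substances)
    metabolic: MetabolicParams = field(default_factory=MetabolicParams)
    necrosis: NecrosisThresholds = field(default_factory=NecrosisThresholds)
    network_path: str | None = None  # None -> packaged default network
    #: activation-threshold overrides for bound input nodes, e.g.
    #: {"Glucose_supply": 0.6}; applied on top of the network file.
    input_thresholds: Mapping[str, float] = field(default_factory=dict)
    populations: tuple[PopulationSpec, ...] = (PopulationSpec(),)
    initial_cells: int = 100
    drugs: tuple[DrugSpec, ...] = ()
    schedule: Schedule = field(default_factory=Schedule)
    duration_h: float = 600.0
    record_interval_h: float = 6.0
    n_outer: int = 3
    solver_tol: float = 1e-6
    replicates: int = 10
    base_seed: int = 0

    def __post_init__(self):
        if self.initial_cells < 0:
            raise ConfigError("initial_cells must be >= 0")
        if self.duration_h < 0:
            raise ConfigError("duration_h must be >= 0")
        if self.record_interval_h <= 0:
            raise ConfigError("record_interval_h must be positive")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        total = sum(p.fraction for p in self.populations)
        if self.populations and abs(total - 1.0) > 1e-9:
            raise ConfigError("populations: fractions must sum to 1")
        tags = [p.tag for p in self.populations]
        if len(set(tags)) != len(tags):
            raise ConfigError("populations: duplicate tag")

    # ------------------------------------------------------------------
    def load_network(self) -> NetworkDefinition:
        if self.network_path is None:
            defn = load_default_network()
        else:
            defn = load_network(self.network_path)
        if self.input_thresholds:
            from .network import InputBinding

            bindings = dict(defn.input_bindings)
            for name, thr in self.input_thresholds.items():
                if name not in bindings:
                    raise ConfigError(
                        f"input_thresholds: {name!r} is not a bound input node"
                    )
                bindings[name] = InputBinding(bindings[name].substance, float(thr))
            defn = NetworkDefinition(defn.nodes, bindings)
        return defn

    def validate(self) -> None:
        """Cross-field checks that need the parsed network."""
        defn = self.load_network()
        defn.require_fate_nodes()
        for name, binding in defn.input_bindings.items():
            if binding.substance not in self.substances:
                raise ConfigError(
                    f"network input {name!r} is bound to substance "
                    f"{binding.substance!r} which the scenario does not model"
                )
        for pop in self.populations:
            for p in pop.perturbations:
                if p.node not in defn:
                    raise ConfigError(
                        f"populations[{pop.tag}].perturbations: unknown node {p.node!r}"
                    )
        for drug in self.drugs:
            if drug.target_inhibitor_node not in defn:
                raise ConfigError(
                    f"drugs[{drug.name}]: unknown inhibitor node "
                    f"{drug.target_inhibitor_node!r}"
                )
            if drug.name not in self.substances:
                raise ConfigError(
                    f"drugs[{drug.name}]: no substance spec for the drug field"
                )

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)

    def with_perturbations(self, *perturbations: Perturbation) -> "ScenarioConfig":
        """Add perturbations to every population (e.g. a global knockout arm)."""
        pops = tuple(
            dataclasses.replace(p, perturbations=p.perturbations + tuple(perturbations))
            for p in self.populations
        )
        return self.replace(populations=pops)

    # ------------------------------------------------------------------
    # serialisation
    def to_dict(self) -> dict[str, Any]:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                d = {}
                for f in dataclasses.fields(obj):
                    d[f.name] = enc(getattr(obj, f.name))
                return d
            if isinstance(obj, Mapping):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        d = enc(self)
        # Perturbation/expr internals do not belong in YAML; re-encode tersely
        d["populations"] = [
            {
                "tag": p.tag,
                "fraction": p.fraction,
                "perturbations": [[q.node, q.mode] for q in p.perturbations],
            }
            for p in self.populations
        ]
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ScenarioConfig":
        try:
            kwargs: dict[str, Any] = {}
            if "lattice" in data:
                kwargs["lattice"] = Lattice(**data["lattice"])
            if "times" in data:
                kwargs["times"] = TimeScales(**data["times"])
            if "substances" in data:
                kwargs["substances"] = {
                    k: SubstanceSpec(**v) for k, v in data["substances"].items()
                }
            if "metabolic" in data:
                kwargs["metabolic"] = MetabolicParams(**data["metabolic"])
            if "necrosis" in data:
                kwargs["necrosis"] = NecrosisThresholds(**data["necrosis"])
            if "populations" in data:
                kwargs["populations"] = tuple(
                    PopulationSpec(
                        tag=p["tag"],
                        fraction=p.get("fraction", 1.0),
                        perturbations=tuple(
                            Perturbation(node, mode)
                            for node, mode in p.get("perturbations", [])
                        ),
                    )
                    for p in data["populations"]
                )
            if "drugs" in data:
                kwargs["drugs"] = tuple(DrugSpec(**d) for d in data["drugs"])
            if "schedule" in data:
                kwargs["schedule"] = Schedule(**data["schedule"])
            for key in (
                "network_path", "input_thresholds", "initial_cells", "duration_h",
                "record_interval_h", "n_outer", "solver_tol", "replicates", "base_seed",
            ):
                if key in data:
                    kwargs[key] = data[key]
            unknown = set(data) - set(f.name for f in dataclasses.fields(cls))
            if unknown:
                raise ConfigError(f"unknown config fields: {sorted(unknown)}")
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the config contents for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
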