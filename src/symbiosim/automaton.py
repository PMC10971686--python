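"""The cellular scale: lattice agents executing the phenotype cycle.

Each phenotype step (default 1 h) a cell first checks necrosis — if both
local oxygen AND glucose are below their critical values it dies in place
and keeps occupying its site.  Otherwise its regulatory network is driven by
the local concentrations (and stochastic drug inhibition), updated
asynchronously, and the fate node read out.  Proliferation additionally
requires the ATP-rate gate (80% of the maximal rate).  A proliferative cell
older than the division time divides into a uniformly chosen empty Moore
neighbour; with no empty neighbour it turns quiescent (contact inhibition)
and waits ``t_q`` before re-evaluating.  Apoptotic cells are removed, and
their site freed, within the same step.  All soluble fields are relaxed to
steady state between phenotype updates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import environment as env
from . import metrics as met
from . import therapy as thx
from .config import NecrosisThresholds, ScenarioConfig, TimeScales
from .metabolism import LocalConcentrations, MetabolicState, proliferation_energy_ok
from .network import (
    NetworkDefinition,
    NetworkState,
    Perturbation,
    Phenotype,
    read_fate,
    set_inputs,
    update_async,
)

__all__ = [
    "Cell",
    "Simulation",
    "SimulationResult",
    "phenotype_step",
    "attempt_division",
    "remove_apoptotic",
    "run_simulation",
    "moore_neighbours",
]

_MOORE = tuple(
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
)


def moore_neighbours(site, shape):
    i, j = site
    nx, ny = shape
    for di, dj in _MOORE:
        ni, nj = i + di, j + dj
        if 0 <= ni < nx and 0 <= nj < ny:
            yield (ni, nj)


@dataclass
class Cell:
    """Lattice agent.  A necrotic cell never changes phenotype again but
    still occupies its site; at most one cell per site."""

    site: tuple[int, int]
    net_state: NetworkState
    age: float = 0.0
    phenotype: Phenotype = Phenotype.GROWTH_ARREST
    perturbations: tuple[Perturbation, ...] = ()
    population_tag: str = "wt"
    quiescent_since: float | None = None
    necrotic: bool = False

    @property
    def glyco_bit(self) -> int:
        return 0 if self.necrotic else self.net_state.values.get("glycoATP", 0)

    @property
    def mito_bit(self) -> int:
        return 0 if self.necrotic else self.net_state.values.get("mitoATP", 0)

    def metabolic_state(self) -> MetabolicState:
        return MetabolicState(self.glyco_bit, self.mito_bit)


def _local_concentrations(fields: Mapping[str, env.Field], site) -> LocalConcentrations:
    extra = {}
    core = {}
    for name, fld in fields.items():
        if name in ("oxygen", "glucose", "lactate", "protons"):
            core[name] = float(fld.values[site])
        else:
            extra[name] = float(fld.values[site])
    return LocalConcentrations(extra=extra, **core)


def phenotype_step(
    cell: Cell,
    local: LocalConcentrations,
    defn: NetworkDefinition,
    thresholds: NecrosisThresholds,
    rng: np.random.Generator,
    times: TimeScales | None = None,
    now: float = 0.0,
    params=None,
    inhibitor_inputs: Mapping[str, int] | None = None,
) -> Cell:
    """One fate evaluation for one cell (necrosis check, network update,
    ATP-gated fate).  Mutates and returns ``cell``."""
    times = times or TimeScales()
    if cell.necrotic:
        return cell
    if local.oxygen < thresholds.oxygen_critical and local.glucose < thresholds.glucose_critical:
        cell.necrotic = True
        cell.phenotype = Phenotype.NECROTIC
        cell.quiescent_since = None
        return cell
    # quiescent cells wait t_q before re-checking their environment
    if cell.quiescent_since is not None and (now - cell.quiescent_since) < times.t_q:
        return cell
    forced = {p.node: p.forced_value for p in cell.perturbations}
    if inhibitor_inputs:
        for node, val in inhibitor_inputs.items():
            forced.setdefault(node, val)
    set_inputs(cell.net_state, defn, local, forced=forced)
    update_async(cell.net_state, defn, n_sweeps=times.n_sweeps, rng=rng, forced=forced)
    fate = read_fate(cell.net_state, defn)
    if fate is Phenotype.PROLIFERATION and params is not None:
        if not proliferation_energy_ok(local, cell.metabolic_state(), params):
            fate = Phenotype.GROWTH_ARREST
    cell.phenotype = fate
    if fate is Phenotype.GROWTH_ARREST:
        if cell.quiescent_since is None:
            cell.quiescent_since = now
    else:
        cell.quiescent_since = None
    return cell


def attempt_division(
    cell: Cell,
    occupied: np.ndarray,
    rng: np.random.Generator,
    defn: NetworkDefinition,
    now: float = 0.0,
    fields: Mapping[str, env.Field] | None = None,
) -> Cell | None:
    """Divide into a uniformly chosen empty Moore neighbour; with no space
    the cell turns quiescent (contact inhibition).  The daughter inherits
    perturbations and population tag, with age 0 and a fresh network state
    (settled against the local environment when ``fields`` is given, so the
    newborn's fate is not read off transient all-zero node values)."""
    empties = [s for s in moore_neighbours(cell.site, occupied.shape) if not occupied[s]]
    if not empties:
        cell.phenotype = Phenotype.GROWTH_ARREST
        cell.quiescent_since = now
        return None
    site = empties[int(rng.integers(len(empties)))]
    state = NetworkState.initial(defn)
    forced = {p.node: p.forced_value for p in cell.perturbations}
    for node, val in forced.items():
        state.values[node] = val
    daughter = Cell(
        site=site,
        net_state=state,
        age=0.0,
        phenotype=Phenotype.GROWTH_ARREST,
        perturbations=cell.perturbations,
        population_tag=cell.population_tag,
    )
    if fields is not None:
        local = _local_concentrations(fields, site)
        set_inputs(state, defn, local, forced=forced)
        update_async(state, defn, n_sweeps=4, rng=rng, forced=forced)
    cell.age = 0.0
    occupied[site] = True
    return daughter


def remove_apoptotic(cells: list[Cell], occupied: np.ndarray | None = None) -> list[Cell]:
    """Delete apoptotic cells, freeing their sites."""
    kept = []
    for c in cells:
        if c.phenotype is Phenotype.APOPTOSIS and not c.necrotic:
            if occupied is not None:
                occupied[c.site] = False
        else:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Time series, cross-section profiles and end state of one run."""

    config: ScenarioConfig
    seed: int
    timeseries: pd.DataFrame
    msi_records: list[met.MSIRecord]
    profiles: dict[str, np.ndarray]  # substance -> (n_records, ny) centre row
    profile_times: np.ndarray
    fields: dict[str, env.Field]
    cells: list[Cell]
    manifest: dict

    def final(self, column: str) -> float:
        if len(self.timeseries) == 0:
            return float("nan")
        return float(self.timeseries[column].iloc[-1])


class Simulation:
    """One stochastic realisation of a scenario."""

    def __init__(self, config: ScenarioConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.seed = int(seed)
        self.rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        self.lattice = config.lattice
        self.base_defn = config.load_network()
        self.time = 0.0
        self.oxygen_cutoff = self._oxygen_cutoff()
        # per-population network definitions with their perturbations burnt in
        self.defs: dict[str, NetworkDefinition] = {}
        for pop in config.populations:
            self.defs[pop.tag] = self.base_defn.with_perturbations(pop.perturbations)
        self.fields = {
            name: env.Field.uniform(spec, self.lattice)
            for name, spec in config.substances.items()
        }
        self.occupied = np.zeros(self.lattice.shape, dtype=bool)
        self.cells: list[Cell] = []
        self._seed_cells()
        self._records: list[dict] = []
        self._msi: list[met.MSIRecord] = []
        self._profiles: dict[str, list[np.ndarray]] = {"oxygen": [], "glucose": [], "lactate": []}
        self._profile_times: list[float] = []

    # ------------------------------------------------------------------
    def _oxygen_cutoff(self) -> float:
        binding = self.base_defn.input_bindings.get("Oxygen_supply")
        return binding.threshold if binding is not None else 1.5

    def _seed_cells(self) -> None:
        """Initial tumour: a filled disc of ``initial_cells`` sites at the
        domain centre; mixed populations are randomly interleaved."""
        n = self.config.initial_cells
        if n == 0:
            return
        cx, cy = self.lattice.centre()
        ii, jj = np.indices(self.lattice.shape)
        r2 = (ii - cx) ** 2 + (jj - cy) ** 2
        order = np.argsort(r2, axis=None, kind="stable")
        sites = [np.unravel_index(k, self.lattice.shape) for k in order[:n]]
        # assign tags at the configured ratio, randomly interleaved
        tags: list[str] = []
        pops = self.config.populations
        counts = [int(round(p.fraction * n)) for p in pops]
        while sum(counts) > n:
            counts[int(np.argmax(counts))] -= 1
        while sum(counts) < n:
            counts[int(np.argmin(counts))] += 1
        for pop, k in zip(pops, counts):
            tags.extend([pop.tag] * k)
        self.rng.shuffle(tags)
        pert = {p.tag: p.perturbations for p in pops}
        t_div = self.config.times.t_division
        for site, tag in zip(sites, tags):
            state = NetworkState.initial(self.defs[tag])
            for p in pert[tag]:
                state.values[p.node] = p.forced_value
            cell = Cell(
                site=tuple(int(v) for v in site),
                net_state=state,
                age=float(self.rng.uniform(0.0, t_div)),
                perturbations=tuple(pert[tag]),
                population_tag=tag,
            )
            self.occupied[cell.site] = True
            self.cells.append(cell)

    # ------------------------------------------------------------------
    def _update_drug_boundaries(self) -> None:
        t_days = self.time / 24.0
        for idx, drug in enumerate(self.config.drugs):
            dose = thx.boundary_dose_at(t_days, drug, self.config.schedule, drug_index=idx)
            fld = self.fields[drug.name]
            fld.spec = dataclasses.replace(fld.spec, boundary_value=dose)

    def _equilibrate(self) -> None:
        env.equilibrate(
            self.fields, self.cells, self.config.metabolic, self.lattice,
            n_outer=self.config.n_outer, tol=self.config.solver_tol,
        )

    def _settle_networks(self, sweeps: int = 4) -> None:
        """Let initial cells' networks relax against the equilibrated fields."""
        for cell in self.cells:
            forced = {p.node: p.forced_value for p in cell.perturbations}
            local = _local_concentrations(self.fields, cell.site)
            set_inputs(cell.net_state, self.defs[cell.population_tag], local, forced=forced)
            update_async(
                cell.net_state, self.defs[cell.population_tag],
                n_sweeps=sweeps, rng=self.rng, forced=forced,
            )

    def _record(self) -> None:
        counts = met.count_populations(self.cells, self.fields, self.oxygen_cutoff)
        msi = met.compute_msi(self.cells, self.fields, self.oxygen_cutoff, time=self.time)
        self._msi.append(msi)
        row = {
            "time_h": self.time,
            "total": counts.total,
            "active": counts.active,
            "glycoATP": counts.glycoATP,
            "mitoATP": counts.mitoATP,
            "both": counts.both,
            "necrotic": counts.necrotic,
            "hypoxic": counts.hypoxic,
            "oxygenated": counts.oxygenated,
            "msi": msi.msi,
        }
        for tag, v in counts.per_tag_total.items():
            row[f"total_{tag}"] = v
        for tag, v in counts.per_tag_active.items():
            row[f"active_{tag}"] = v
        self._records.append(row)
        cx = self.lattice.centre()[0]
        for name in self._profiles:
            self._profiles[name].append(self.fields[name].values[cx, :].copy())
        self._profile_times.append(self.time)

    # ------------------------------------------------------------------
    def step(self) -> None:
        """One phenotype tick: dose update, field equilibration, shuffled
        per-cell fate evaluation, divisions and apoptotic removal."""
        dt = self.config.times.t_phenotype
        self.time += dt
        self._update_drug_boundaries()
        self._equilibrate()
        order = self.rng.permutation(len(self.cells))
        snapshot = [self.cells[i] for i in order]
        removed: set[int] = set()
        newborn: list[Cell] = []
        drugs = self.config.drugs
        for cell in snapshot:
            if cell.necrotic:
                cell.age += dt
                continue
            defn = self.defs[cell.population_tag]
            local = _local_concentrations(self.fields, cell.site)
            inhib = thx.apply_inhibition(drugs, local, self.rng) if drugs else None
            phenotype_step(
                cell, local, defn, self.config.necrosis, self.rng,
                times=self.config.times, now=self.time,
                params=self.config.metabolic, inhibitor_inputs=inhib,
            )
            if cell.phenotype is Phenotype.APOPTOSIS:
                self.occupied[cell.site] = False
                removed.add(id(cell))
                continue
            cell.age += dt
            if (
                cell.phenotype is Phenotype.PROLIFERATION
                and cell.age >= self.config.times.t_division
            ):
                daughter = attempt_division(
                    cell, self.occupied, self.rng, defn, now=self.time, fields=self.fields
                )
                if daughter is not None:
                    newborn.append(daughter)
        if removed:
            self.cells = [c for c in self.cells if id(c) not in removed]
        self.cells.extend(newborn)

    def run(self) -> SimulationResult:
        cfg = self.config
        n_steps = int(round(cfg.duration_h / cfg.times.t_phenotype))
        record_every = max(1, int(round(cfg.record_interval_h / cfg.times.t_phenotype)))
        self._equilibrate()
        self._settle_networks()
        if n_steps > 0:
            self._record()
        for k in range(1, n_steps + 1):
            self.step()
            if k % record_every == 0 or k == n_steps:
                self._record()
        columns = [
            "time_h", "total", "active", "glycoATP", "mitoATP", "both",
            "necrotic", "hypoxic", "oxygenated", "msi",
        ]
        if self._records:
            ts = pd.DataFrame(self._records).fillna(0)
        else:
            ts = pd.DataFrame(columns=columns)
        profiles = {name: np.asarray(rows) for name, rows in self._profiles.items()}
        manifest = {
            "seed": self.seed,
            "config_digest": cfg.digest(),
            "n_steps": n_steps,
            "grid": list(self.lattice.shape),
        }
        return SimulationResult(
            config=cfg, seed=self.seed, timeseries=ts, msi_records=self._msi,
            profiles=profiles, profile_times=np.asarray(self._profile_times),
            fields=self.fields, cells=self.cells, manifest=manifest,
        )


def run_simulation(config: ScenarioConfig, seed: int = 0) -> SimulationResult:
    """Run one replicate of a scenario and return its result."""
    return Simulation(config, seed=seed).run()
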