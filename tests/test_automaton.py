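"""Cellular automaton: necrosis, division, apoptotic removal, and whole-run
invariants (site exclusivity, seed reproducibility, tag conservation,
early exponential growth)."""

import numpy as np
from scipy import stats

from symbiosim import scenarios
from symbiosim.automaton import (
    Cell,
    attempt_division,
    moore_neighbours,
    phenotype_step,
    remove_apoptotic,
    run_simulation,
)
from symbiosim.config import NecrosisThresholds, TimeScales
from symbiosim.metabolism import LocalConcentrations, MetabolicParams
from symbiosim.network import (
    NetworkState,
    Perturbation,
    Phenotype,
    load_default_network,
)

THRESH = NecrosisThresholds(oxygen_critical=0.1, glucose_critical=0.1)


def make_cell(defn, site=(5, 5), **kwargs):
    return Cell(site=site, net_state=NetworkState.initial(defn), **kwargs)


def rich_local(**over):
    base = dict(oxygen=6.0, glucose=5.0, lactate=5.0, extra={"tgfa": 1.0})
    base.update(over)
    return LocalConcentrations(**base)


class TestPhenotypeStep:
    def test_necrosis_requires_both_nutrients_low(self, default_defn, rng):
        cell = make_cell(default_defn)
        phenotype_step(cell, rich_local(oxygen=0.05, glucose=0.05), default_defn,
                       THRESH, rng)
        assert cell.necrotic and cell.phenotype is Phenotype.NECROTIC

    def test_single_low_nutrient_is_not_necrosis(self, default_defn, rng):
        cell = make_cell(default_defn)
        phenotype_step(cell, rich_local(oxygen=0.05), default_defn, THRESH, rng)
        assert not cell.necrotic

    def test_necrotic_cell_never_changes_again(self, default_defn, rng):
        cell = make_cell(default_defn)
        cell.necrotic = True
        cell.phenotype = Phenotype.NECROTIC
        phenotype_step(cell, rich_local(), default_defn, THRESH, rng)
        assert cell.phenotype is Phenotype.NECROTIC

    def test_well_fed_cell_proliferates(self, default_defn, rng):
        cell = make_cell(default_defn)
        for step in range(6):  # let the network settle
            phenotype_step(cell, rich_local(), default_defn, THRESH, rng,
                           now=float(4 * step), params=MetabolicParams())
        assert cell.phenotype is Phenotype.PROLIFERATION

    def test_atp_gate_downgrades_proliferation_to_arrest(self, default_defn, rng):
        """Network fate is Proliferation but the ATP rate is below 80% of the
        maximum, so the cell is growth-arrested."""
        params = MetabolicParams(K_G=1.0)  # MonodG(1.3) = 0.565 < 0.8
        hypoxic = rich_local(oxygen=0.5, glucose=1.3, lactate=0.0)
        cell = make_cell(default_defn)
        for _ in range(6):
            phenotype_step(cell, hypoxic, default_defn, THRESH, rng, params=params)
            cell.quiescent_since = None  # force re-evaluation every step
        assert cell.net_state["glycoATP"] == 1
        assert cell.net_state["Proliferation"] == 1
        assert cell.phenotype is Phenotype.GROWTH_ARREST

    def test_quiescent_cell_waits_t_q(self, default_defn, rng):
        times = TimeScales(t_q=3.0)
        cell = make_cell(default_defn)
        cell.quiescent_since = 10.0
        before = dict(cell.net_state.values)
        phenotype_step(cell, rich_local(), default_defn, THRESH, rng,
                       times=times, now=11.0)
        assert cell.net_state.values == before  # skipped
        phenotype_step(cell, rich_local(), default_defn, THRESH, rng,
                       times=times, now=13.5, params=MetabolicParams())
        assert cell.net_state.values != before  # re-evaluated after t_q


class TestDivision:
    def test_no_space_turns_quiescent(self, default_defn, rng):
        occupied = np.ones((11, 11), dtype=bool)
        cell = make_cell(default_defn)
        cell.phenotype = Phenotype.PROLIFERATION
        daughter = attempt_division(cell, occupied, rng, default_defn, now=7.0)
        assert daughter is None
        assert cell.phenotype is Phenotype.GROWTH_ARREST
        assert cell.quiescent_since == 7.0

    def test_daughter_uniform_over_empty_neighbours(self, default_defn):
        """Chi-square over 8000 seeded trials against the uniform law on the
        8 Moore neighbours."""
        rng = np.random.default_rng(99)
        counts = {}
        for _ in range(8000):
            occupied = np.zeros((11, 11), dtype=bool)
            occupied[5, 5] = True
            cell = make_cell(default_defn)
            cell.phenotype = Phenotype.PROLIFERATION
            daughter = attempt_division(cell, occupied, rng, default_defn)
            counts[daughter.site] = counts.get(daughter.site, 0) + 1
        assert set(counts) == set(moore_neighbours((5, 5), (11, 11)))
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-3

    def test_daughter_inherits_perturbations_and_tag(self, default_defn, rng):
        perts = (Perturbation("MCT1", "knockout"),)
        defn = default_defn.with_perturbations(perts)
        occupied = np.zeros((11, 11), dtype=bool)
        occupied[5, 5] = True
        cell = make_cell(defn, perturbations=perts, population_tag="MCT1-")
        cell.phenotype = Phenotype.PROLIFERATION
        daughter = attempt_division(cell, occupied, rng, defn)
        assert daughter.population_tag == "MCT1-"
        assert daughter.perturbations == perts
        assert daughter.net_state["MCT1"] == 0
        assert daughter.age == 0.0 and cell.age == 0.0

    def test_division_marks_site_occupied(self, default_defn, rng):
        occupied = np.zeros((5, 5), dtype=bool)
        occupied[2, 2] = True
        cell = make_cell(default_defn, site=(2, 2))
        cell.phenotype = Phenotype.PROLIFERATION
        daughter = attempt_division(cell, occupied, rng, default_defn)
        assert occupied[daughter.site]


class TestRemoval:
    def test_one_apoptotic_among_ten(self, default_defn):
        occupied = np.zeros((11, 11), dtype=bool)
        cells = []
        for k in range(10):
            c = make_cell(default_defn, site=(k // 4 + 1, k % 4 + 1))
            occupied[c.site] = True
            cells.append(c)
        cells[3].phenotype = Phenotype.APOPTOSIS
        dead_site = cells[3].site
        kept = remove_apoptotic(cells, occupied)
        assert len(kept) == 9
        assert not occupied[dead_site]

    def test_no_apoptotic_is_identity(self, default_defn):
        cells = [make_cell(default_defn, site=(1, 1))]
        assert remove_apoptotic(list(cells)) == cells

    def test_freed_site_reusable_by_neighbour_division(self, default_defn, rng):
        """Two-step scenario: apoptotic removal frees the only empty site,
        which a neighbour's division then claims."""
        occupied = np.ones((3, 3), dtype=bool)
        victim = make_cell(default_defn, site=(1, 1))
        victim.phenotype = Phenotype.APOPTOSIS
        remove_apoptotic([victim], occupied)
        divider = make_cell(default_defn, site=(0, 0))
        divider.phenotype = Phenotype.PROLIFERATION
        daughter = attempt_division(divider, occupied, rng, default_defn)
        assert daughter.site == (1, 1)


class TestWholeRuns:
    def test_zero_initial_cells(self):
        from symbiosim.environment import Lattice

        cfg = scenarios.baseline(scale="desk", initial_cells=0, duration_days=0.1)
        cfg = cfg.replace(lattice=Lattice(nx=20, ny=20))
        res = run_simulation(cfg, seed=0)
        assert (res.timeseries["total"] == 0).all()
        for name in ("oxygen", "glucose", "lactate"):
            np.testing.assert_allclose(
                res.fields[name].values, res.fields[name].spec.boundary_value
            )

    def test_seed_reproducibility_and_site_exclusivity(self):
        cfg = scenarios.baseline(scale="desk", duration_days=2.0)
        a = run_simulation(cfg, seed=11)
        b = run_simulation(cfg, seed=11)
        assert a.timeseries.equals(b.timeseries)
        sites = [c.site for c in a.cells]
        assert len(sites) == len(set(sites))

    def test_total_count_monotone_under_rich_nutrients(self):
        cfg = scenarios.baseline(scale="desk", oxygen=9.0, lactate=5.0,
                                 duration_days=4.0)
        res = run_simulation(cfg, seed=5)
        total = res.timeseries["total"].to_numpy()
        assert (np.diff(total) >= 0).all()

    def test_tag_conservation_in_competition(self, competition_run):
        ts = competition_run.timeseries
        tags = {c.population_tag for c in competition_run.cells}
        assert tags <= {"MCT1wt", "MCT1-"}
        assert "total_MCT1wt" in ts and "total_MCT1-" in ts

    def test_early_growth_doubles_at_division_time(self):
        """From a single seeded cell under abundant uniform nutrients the
        population doubles once per division time (within 15%) over a
        five-division window."""
        cfg = scenarios.baseline(scale="desk", oxygen=9.0, lactate=5.0,
                                 initial_cells=1, duration_days=5.0)
        res = run_simulation(cfg, seed=7)
        ts = res.timeseries
        n0, n1 = ts["total"].iloc[0], ts["total"].iloc[-1]
        window_h = ts["time_h"].iloc[-1] - ts["time_h"].iloc[0]
        doubling = window_h / np.log2(n1 / n0)
        assert abs(doubling - cfg.times.t_division) <= 0.15 * cfg.times.t_division

    def test_duration_zero_gives_header_only_series(self):
        cfg = scenarios.baseline(scale="desk", duration_days=0.0)
        res = run_simulation(cfg, seed=0)
        assert len(res.timeseries) == 0
        assert "total" in res.timeseries.columns
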