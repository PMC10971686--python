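"""Shared fixtures.

The stochastic whole-model fixtures (baseline wild-type / MCT1-knockout
pair, low-glucose competition, drug-schedule arms) are session-scoped: they
take tens of seconds each and several test modules interrogate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from symbiosim import scenarios
from symbiosim.automaton import run_simulation
from symbiosim.network import load_default_network


@pytest.fixture(scope="session")
def default_defn():
    return load_default_network()


@pytest.fixture(scope="session")
def baseline_wt_run():
    """Desk-scale baseline tumour, MCT1 wild type (symbiosis-capable)."""
    return run_simulation(scenarios.baseline(scale="desk"), seed=1)


@pytest.fixture(scope="session")
def baseline_ko_run():
    """Paired MCT1-knockout arm: same seed and config apart from the
    perturbation."""
    return run_simulation(scenarios.baseline(scale="desk", mct1="ko"), seed=1)


@pytest.fixture(scope="session")
def competition_run():
    """1:1 mixed MCT1wt / MCT1- populations at 1 mM glucose, 5 mM lactate."""
    cfg = scenarios.competition(scale="desk", glucose=1.0, lactate=5.0, duration_days=12)
    return run_simulation(cfg, seed=2)


@pytest.fixture(scope="session")
def schedule_runs():
    """Alternating versus simultaneous-periodic dosing at matched dose
    (10x IC50, 5-day windows, 10 days), two seeds per arm."""
    out = {}
    for mode in ("alternating", "simultaneous_periodic"):
        cfg = scenarios.drug_scenario(
            mode=mode, dose_multiple=10.0, period_days=5.0, duration_days=10
        )
        out[mode] = [run_simulation(cfg, seed=s) for s in (3, 4)]
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
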