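"""Replicate orchestration, gene screens, between-condition statistics and
file output.

Replicate seeds are deterministic functions of (base seed, replicate index),
so any single replicate can be reproduced bit-for-bit at the metrics level.
Between-condition significance uses Welch's two-sample t-test at the 0.05
level on end-time outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import environment as env
from .automaton import SimulationResult, run_simulation
from .config import ConfigError, ScenarioConfig
from .network import Perturbation
from .sensitivity import ParameterRange, lhs_sample, prcc

__all__ = [
    "ComparisonResult",
    "replicate_seed",
    "run_replicates",
    "compare_conditions",
    "run_screen",
    "apply_parameters",
    "run_sensitivity",
    "write_run_dir",
]


def replicate_seed(base_seed: int, index: int) -> int:
    """Deterministic per-replicate seed (kept below 2**31)."""
    return int(np.random.SeedSequence([int(base_seed), int(index)]).generate_state(1)[0] % (2**31))


def run_replicates(config: ScenarioConfig, n: int | None = None) -> list[SimulationResult]:
    n = config.replicates if n is None else n
    return [
        run_simulation(config, seed=replicate_seed(config.base_seed, i)) for i in range(n)
    ]


@dataclass(frozen=True)
class ComparisonResult:
    """Welch test between two replicate arms on one end-time output."""

    mean_a: float
    mean_b: float
    mean_difference: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_conditions(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> ComparisonResult:
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both arms must be non-empty")
    if a.size < 2 or b.size < 2:
        return ComparisonResult(float(a.mean()), float(b.mean()),
                                float(a.mean() - b.mean()), float("nan"), False, alpha)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return ComparisonResult(
        float(a.mean()), float(b.mean()), float(a.mean() - b.mean()),
        p, bool(p < alpha), alpha,
    )


def run_screen(
    base: ScenarioConfig,
    genes: Iterable[str],
    modes: Sequence[str] = ("enrichment", "knockout"),
    n_replicates: int | None = None,
    endpoints: Sequence[str] = ("total", "active"),
) -> pd.DataFrame:
    """Gene-perturbation screen of symbiosis-induced growth.

    For every (gene, mode) — plus an unperturbed wild-type row — the
    scenario is run with MCT1 wild type and MCT1 knocked out, across
    replicates, and the percentage growth change due to symbiosis
    100*(growth_wt - growth_ko)/growth_ko is reported per endpoint together
    with a Welch p-value.
    """
    defn = base.load_network()
    genes = list(genes)
    for g in genes:
        if g not in defn:
            raise ConfigError(f"screen gene {g!r} is not a network node")
    n = base.replicates if n_replicates is None else n_replicates
    rows = []
    conditions = [("WT", "none", ())] + [
        (g, mode, (Perturbation(g, mode),)) for g in genes for mode in modes
    ]
    for gene, mode, perts in conditions:
        cfg_wt = base.with_perturbations(*perts)
        cfg_ko = cfg_wt.with_perturbations(Perturbation("MCT1", "knockout"))
        res_wt = run_replicates(cfg_wt, n)
        res_ko = run_replicates(cfg_ko, n)
        row = {"gene": gene, "mode": mode, "n_replicates": n}
        for endpoint in endpoints:
            wt = np.array([r.final(endpoint) for r in res_wt])
            ko = np.array([r.final(endpoint) for r in res_ko])
            cmp = compare_conditions(wt, ko)
            denom = ko.mean()
            row[f"pct_change_{endpoint}"] = (
                float("nan") if denom == 0 else 100.0 * (wt.mean() - ko.mean()) / denom
            )
            row[f"p_value_{endpoint}"] = cmp.p_value
            row[f"significant_{endpoint}"] = cmp.significant
            row[f"mean_wt_{endpoint}"] = wt.mean()
            row[f"mean_ko_{endpoint}"] = ko.mean()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sensitivity-analysis integration

_METABOLIC_NAMES = {"mu_o2", "K_o2", "K_G", "K_L"}
_THRESHOLD_MAP = {
    "oxygen_activation_threshold": "Oxygen_supply",
    "glucose_activation_threshold": "Glucose_supply",
    "lactate_activation_threshold": "Lactate_supply",
    "tgfa_activation_threshold": "EGFR_stimulus",
}


def apply_parameters(config: ScenarioConfig, values: Mapping[str, float]) -> ScenarioConfig:
    """Return a config with the named sensitivity parameters replaced."""
    subs = dict(config.substances)
    metabolic = config.metabolic
    necrosis = config.necrosis
    thresholds = dict(config.input_thresholds)
    for name, value in values.items():
        if name in _METABOLIC_NAMES:
            metabolic = dataclasses.replace(metabolic, **{name: float(value)})
        elif name in _THRESHOLD_MAP:
            thresholds[_THRESHOLD_MAP[name]] = float(value)
        elif name.startswith("D_"):
            sub = name[2:]
            subs[sub] = dataclasses.replace(subs[sub], D=float(value))
        elif name.endswith("_boundary"):
            sub = name[: -len("_boundary")]
            subs[sub] = dataclasses.replace(subs[sub], boundary_value=float(value))
        elif name == "oxygen_critical":
            necrosis = dataclasses.replace(necrosis, oxygen_critical=float(value))
        elif name == "glucose_critical":
            necrosis = dataclasses.replace(necrosis, glucose_critical=float(value))
        elif name.startswith("gamma_"):
            _, sub, kind = name.split("_", 2)
            key = f"gamma_{kind}"
            subs[sub] = dataclasses.replace(subs[sub], **{key: float(value)})
        else:
            raise ConfigError(f"unknown sensitivity parameter {name!r}")
    return config.replace(
        substances=subs, metabolic=metabolic, necrosis=necrosis,
        input_thresholds=thresholds,
    )


def run_sensitivity(
    config: ScenarioConfig,
    parameters: Sequence[ParameterRange],
    n_samples: int = 40,
    seed: int = 0,
    outputs: Sequence[str] = ("total", "mitoATP", "glycoATP", "necrotic"),
):
    """Full LHS → simulate → PRCC pipeline: one simulation per design row
    (seed = base seed + row offset), end-time outputs correlated against the
    sampled parameters."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    design = lhs_sample(parameters, n_samples=n_samples, rng=rng)
    frame = design.to_frame()
    out_rows = []
    for i in range(design.n_samples):
        cfg = apply_parameters(config, frame.iloc[i].to_dict())
        res = run_simulation(cfg, seed=replicate_seed(seed, i))
        out_rows.append({name: res.final(name) for name in outputs})
    out = pd.DataFrame(out_rows)
    result = prcc(design, out)
    return design, out, result


# ---------------------------------------------------------------------------
# Artefacts


def write_run_dir(result: SimulationResult, outdir) -> Path:
    """Deterministic artefact layout: config copy, manifest (seed + config
    hash), metric time series, MSI records, field matrices and centre
    cross-section profiles."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    result.timeseries.to_csv(outdir / "metrics.csv", index=False)
    pd.DataFrame([dataclasses.asdict(m) for m in result.msi_records]).to_csv(
        outdir / "msi.csv", index=False
    )
    fdir = outdir / "fields"
    fdir.mkdir(exist_ok=True)
    field_manifest = {}
    for name, fld in result.fields.items():
        env.field_to_text(fld, fdir / f"{name}.txt")
        field_manifest[name] = {
            "substance": name,
            "time_h": float(result.profile_times[-1]) if len(result.profile_times) else 0.0,
            "boundary_value": fld.spec.boundary_value,
            "role": fld.spec.role,
        }
    with open(fdir / "manifest.json", "w") as fh:
        json.dump(field_manifest, fh, indent=2, sort_keys=True)
    for name, prof in result.profiles.items():
        df = pd.DataFrame(prof)
        df.insert(0, "time_h", result.profile_times)
        df.to_csv(outdir / f"profile_{name}.csv", index=False)
    return outdir
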