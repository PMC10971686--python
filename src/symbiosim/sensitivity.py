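"""Latin hypercube sampling and partial rank correlation coefficients.

Parameters are varied within ±20% of their baseline values over an
equal-width-bin Latin hypercube (default 40 bins for 20 parameters; LHS
requires more than 4/3 as many bins as parameters).  For each parameter the
design draws exactly one uniform sample per bin and shuffles the column
independently.  Model outputs recorded per design row are then related to
each parameter by the partial rank correlation coefficient: all columns are
rank-transformed, the ranks of the parameter of interest and of the output
are each residualised on the ranks of the remaining parameters by least
squares, and the correlation of the residuals is reported, with a p-value
from the standard t-approximation on n - 2 - (k - 1) degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParameterRange",
    "LHSDesign",
    "PRCCResult",
    "lhs_sample",
    "prcc",
    "default_parameter_ranges",
]


@dataclass(frozen=True)
class ParameterRange:
    """One varied parameter: ±20% around its baseline by default."""

    name: str
    baseline: float
    rel_width: float = 0.2

    def __post_init__(self):
        if self.low >= self.high:
            raise ValueError(f"parameter {self.name!r}: empty range")

    @property
    def low(self) -> float:
        return (1.0 - self.rel_width) * self.baseline

    @property
    def high(self) -> float:
        return (1.0 + self.rel_width) * self.baseline


@dataclass(frozen=True)
class LHSDesign:
    parameters: tuple[ParameterRange, ...]
    matrix: np.ndarray  # (n_samples, n_parameters)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=[p.name for p in self.parameters])

    def bin_index(self) -> np.ndarray:
        """Equal-width bin index of every entry (for the one-per-bin check)."""
        lows = np.array([p.low for p in self.parameters])
        highs = np.array([p.high for p in self.parameters])
        frac = (self.matrix - lows) / (highs - lows)
        idx = np.floor(frac * self.n_samples).astype(int)
        return np.clip(idx, 0, self.n_samples - 1)


@dataclass(frozen=True)
class PRCCResult:
    """Long-form table with one row per (parameter, output[, time])."""

    table: pd.DataFrame  # columns: parameter, output, coefficient, p_value, significant

    def coefficient(self, parameter: str, output: str) -> float:
        sel = self.table[
            (self.table.parameter == parameter) & (self.table.output == output)
        ]
        return float(sel.coefficient.iloc[0])


def lhs_sample(
    parameters,
    n_samples: int = 40,
    rng: np.random.Generator | None = None,
) -> LHSDesign:
    """Stratified one-sample-per-bin design, uniform within bin, with
    independent column shuffles."""
    parameters = tuple(parameters)
    k = len(parameters)
    if k == 0:
        raise ValueError("at least one parameter is required")
    min_samples = math.ceil(4 * k / 3) + 1
    if n_samples < min_samples:
        raise ValueError(
            f"LHS with {k} parameters needs at least {min_samples} bins "
            f"(more than 4*{k}/3); got {n_samples}"
        )
    rng = np.random.default_rng() if rng is None else rng
    matrix = np.empty((n_samples, k))
    for j, p in enumerate(parameters):
        edges = np.linspace(p.low, p.high, n_samples + 1)
        widths = np.diff(edges)
        samples = edges[:-1] + rng.random(n_samples) * widths
        matrix[:, j] = rng.permutation(samples)
    return LHSDesign(parameters, matrix)


def _partial_rank_corr(ranks: np.ndarray, y_rank: np.ndarray, j: int):
    """PRCC of column j against y, controlling for the other columns."""
    n, k = ranks.shape
    others = np.delete(ranks, j, axis=1)
    design = np.column_stack([np.ones(n), others])
    bx, *_ = np.linalg.lstsq(design, ranks[:, j], rcond=None)
    by, *_ = np.linalg.lstsq(design, y_rank, rcond=None)
    rx = ranks[:, j] - design @ bx
    ry = y_rank - design @ by
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - 2 - (k - 1)
    if dof <= 0 or abs(r) == 1.0:
        return r, 0.0 if abs(r) == 1.0 else np.nan
    t = r * math.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, p


def prcc(
    design: LHSDesign,
    outputs: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
) -> PRCCResult:
    """Partial rank correlation of every parameter against every output
    column.  Constant columns yield NaN coefficients (reported missing)."""
    if isinstance(outputs, np.ndarray):
        outputs = pd.DataFrame(
            outputs if outputs.ndim == 2 else outputs[:, None],
            columns=None,
        )
        outputs.columns = [f"output_{i}" for i in range(outputs.shape[1])]
    if len(outputs) != design.n_samples:
        raise ValueError("outputs are not aligned with the design rows")
    if outputs.isna().any().any():
        raise ValueError("outputs contain missing values")
    ranks = np.column_stack(
        [stats.rankdata(design.matrix[:, j]) for j in range(design.matrix.shape[1])]
    )
    rows = []
    for out_name in outputs.columns:
        y = np.asarray(outputs[out_name], dtype=float)
        y_rank = stats.rankdata(y)
        for j, p in enumerate(design.parameters):
            if np.all(design.matrix[:, j] == design.matrix[0, j]) or np.all(y == y[0]):
                r, pv = np.nan, np.nan
            else:
                r, pv = _partial_rank_corr(ranks, y_rank, j)
            rows.append(
                {
                    "parameter": p.name,
                    "output": out_name,
                    "coefficient": r,
                    "p_value": pv,
                    "significant": bool(pv < alpha) if np.isfinite(pv) else False,
                }
            )
    return PRCCResult(pd.DataFrame(rows))


def default_parameter_ranges(config) -> tuple[ParameterRange, ...]:
    """The 20-parameter diffusion/threshold block varied in the sensitivity
    analysis: diffusion coefficients, activation thresholds, half-saturation
    coefficients, the maximum oxygen consumption rate, boundary nutrient
    levels, necrosis criticals and the growth-factor gammas."""
    defn = config.load_network()
    thr = {n: b.threshold for n, b in defn.input_bindings.items()}
    subs = config.substances
    m = config.metabolic
    ranges = [
        ParameterRange("D_oxygen", subs["oxygen"].D),
        ParameterRange("D_glucose", subs["glucose"].D),
        ParameterRange("D_lactate", subs["lactate"].D),
        ParameterRange("D_protons", subs["protons"].D),
        ParameterRange("D_tgfa", subs["tgfa"].D),
        ParameterRange("oxygen_activation_threshold", thr.get("Oxygen_supply", 1.5)),
        ParameterRange("glucose_activation_threshold", thr.get("Glucose_supply", 0.5)),
        ParameterRange("lactate_activation_threshold", thr.get("Lactate_supply", 0.8)),
        ParameterRange("tgfa_activation_threshold", thr.get("EGFR_stimulus", 1e-6)),
        ParameterRange("mu_o2", m.mu_o2),
        ParameterRange("K_o2", m.K_o2),
        ParameterRange("K_G", m.K_G),
        ParameterRange("K_L", m.K_L),
        ParameterRange("oxygen_boundary", subs["oxygen"].boundary_value),
        ParameterRange("glucose_boundary", subs["glucose"].boundary_value),
        ParameterRange("lactate_boundary", subs["lactate"].boundary_value),
        ParameterRange("oxygen_critical", config.necrosis.oxygen_critical),
        ParameterRange("glucose_critical", config.necrosis.glucose_critical),
        ParameterRange("gamma_tgfa_produce", subs["tgfa"].gamma_produce),
        ParameterRange("gamma_tgfa_consume", subs["tgfa"].gamma_consume),
    ]
    return tuple(ranges)
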