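"""Synthetic colony-count data for survival curves and two-way designs.

Counts are drawn from the Poisson law prob(y) = exp(-NS) (NS)^y / y! with
mean N*S: N cells seeded, S the modelled survival probability.  Optional
extra variability — the usual source of overdispersion in real assays —
enters as a lognormal multiplier on each plate's expected count
(Poisson-lognormal mixing), so means stay positive and the log-scale
perturbations are Gaussian; ``replicate_sd = 0`` gives pure Poisson data
(dispersion ~ 1 on refit).  The multiplier is drawn per plate, not per
experiment: an experiment-level shift of the plating efficiency would be
absorbed exactly by the fitted per-experiment intercepts and produce no
overdispersion at all.

Defaults mirror a typical radiation clonogenic study: 8 replicate
experiments at doses 0-6 Gy with alpha = 0.5/Gy, beta = 0.02/Gy^2, and a
cells-seeded schedule growing with dose so every plate expects a countable
number of colonies; two-way data use 4 replicate experiments of a 2x2
design.  Also included are the small-sample estimator utilities for the
efficiency comparison of pooled versus arithmetic mean survival fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_data import AssayTable

__all__ = [
    "CurveSimSpec",
    "TwoWaySimSpec",
    "simulate_curve_data",
    "simulate_twoway_data",
    "relative_efficiency",
    "pooled_and_arithmetic_means",
]


def _default_doses() -> tuple:
    return (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass
class CurveSimSpec:
    """Conditions for a simulated dose-response experiment series.

    ``cells_schedule`` gives cells seeded per plate at each dose; if None,
    it is chosen per dose so the expected colony count is about
    ``target_colonies`` (rounded up to a multiple of 50), as experimenters
    seed more cells at higher doses.
    """

    alpha: float = 0.5  # per Gy
    beta: float = 0.02  # per Gy^2
    pe_mean: float = 0.5
    n_experiments: int = 8
    doses: tuple = field(default_factory=_default_doses)
    cells_schedule: tuple | None = None
    plates_per_dose: int = 1
    replicate_sd: float = 0.0
    target_colonies: int = 50
    group_label: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pe_mean <= 1):
            raise ValueError("pe_mean must be in (0, 1]")
        if self.alpha < 0 or self.beta < 0 or self.replicate_sd < 0:
            raise ValueError("alpha, beta and replicate_sd must be >= 0")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if self.cells_schedule is None:
            self.cells_schedule = tuple(
                int(50 * math.ceil(self.target_colonies / (self.pe_mean * s) / 50))
                for s in self._survival(np.asarray(self.doses))
            )
        if len(self.cells_schedule) != len(self.doses):
            raise ValueError("cells_schedule must match doses in length")

    def _survival(self, d: np.ndarray) -> np.ndarray:
        return np.exp(-self.alpha * d - self.beta * d**2)


def simulate_curve_data(spec: CurveSimSpec, rng: np.random.Generator | None = None) -> AssayTable:
    """Draw a colony-count table under the LQ model.

    Per plate a multiplier g ~ lognormal(0, replicate_sd) perturbs the
    expected count: y ~ Poisson(N * g * pe * S(d)).  Fully reproducible
    from ``spec.seed`` (or an externally supplied rng).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    doses = np.asarray(spec.doses, dtype=float)
    surv = spec._survival(doses)
    rows = []
    for j in range(spec.n_experiments):
        for d, s, n_cells in zip(doses, surv, spec.cells_schedule):
            base = n_cells * spec.pe_mean * s
            if not np.isfinite(base) or base <= 0:
                raise ValueError(f"degenerate expected count {base} at dose {d}")
            for _ in range(spec.plates_per_dose):
                g = rng.lognormal(0.0, spec.replicate_sd) if spec.replicate_sd > 0 else 1.0
                mean = base * g
                rows.append(
                    {
                        "experiment_id": f"exp{j + 1}",
                        "dose": d,
                        "cells_seeded": int(n_cells),
                        "colonies": int(rng.poisson(mean)),
                    }
                )
    df = pd.DataFrame(rows)
    if spec.group_label is not None:
        df.insert(0, "group", spec.group_label)
    return AssayTable(df)


@dataclass
class TwoWaySimSpec:
    """Conditions for a simulated 2x2 factorial colony-count experiment.

    Effects are on the log scale: survival in design cell (x1, x2) is
    pe * exp(A x1 + B0 x2 + (B1 - B0) x1 x2).  Default effects are typical
    knockdown/treatment magnitudes (about 70 %, 38 % and 26 % survival).
    """

    effect_a: float = -0.348
    effect_b0: float = -0.976
    effect_b1: float = -1.343
    pe_mean: float = 0.3
    n_experiments: int = 4
    cells_per_plate: int = 500
    plates_per_cell: int = 1
    replicate_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pe_mean <= 1):
            raise ValueError("pe_mean must be in (0, 1]")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")


def simulate_twoway_data(spec: TwoWaySimSpec, rng: np.random.Generator | None = None) -> AssayTable:
    """Draw a 2x2 factorial colony-count table (four cells per experiment)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    d = spec.effect_b1 - spec.effect_b0
    rows = []
    for j in range(spec.n_experiments):
        for x1 in (0, 1):
            for x2 in (0, 1):
                s = math.exp(spec.effect_a * x1 + spec.effect_b0 * x2 + d * x1 * x2)
                base = spec.cells_per_plate * spec.pe_mean * s
                if not np.isfinite(base) or base <= 0:
                    raise ValueError(f"degenerate expected count in cell ({x1},{x2})")
                for _ in range(spec.plates_per_cell):
                    g = rng.lognormal(0.0, spec.replicate_sd) if spec.replicate_sd > 0 else 1.0
                    mean = base * g
                    rows.append(
                        {
                            "experiment_id": f"exp{j + 1}",
                            "factor_a": x1,
                            "factor_b": x2,
                            "cells_seeded": spec.cells_per_plate,
                            "colonies": int(rng.poisson(mean)),
                        }
                    )
    return AssayTable(pd.DataFrame(rows))


def relative_efficiency(n1: float, n2: float) -> float:
    """Efficiency of the arithmetic-mean relative to the pooled-mean estimator.

    For two plates with n1 and n2 cells seeded, the pooled mean (the ML
    estimator of a common survival fraction) has Poisson variance
    mu/(n1+n2) while the arithmetic mean of the per-plate fractions has
    variance (mu/n1 + mu/n2)/4; their ratio is

        4 / [(1/n1 + 1/n2) * (n1 + n2)],

    which is 1 for equal cell numbers and < 1 otherwise.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cell numbers must be positive")
    return 4.0 / ((1.0 / n1 + 1.0 / n2) * (n1 + n2))


def pooled_and_arithmetic_means(k1: float, k2: float, n1: float, n2: float):
    """Pooled mean (ML) and arithmetic mean (LS) of two survival fractions.

    m1 = (k1 + k2)/(n1 + n2) and m2 = (k1/n1 + k2/n2)/2; the two coincide
    whenever n1 = n2.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("colony counts must be >= 0")
    if n1 < 1 or n2 < 1:
        raise ValueError("cell numbers must be >= 1")
    m1 = (k1 + k2) / (n1 + n2)
    m2 = (k1 / n1 + k2 / n2) / 2.0
    return m1, m2
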