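"""Two-way factorial analysis of colony counts (log-linear ANOVA).

For a 2x2 design — e.g. siRNA knockdown (factor A) crossed with a drug
treatment (factor B) — survival is modelled multiplicatively,

    S = exp(c_j + A x1 + B x2 + D x1 x2),

with x1, x2 in {0, 1}, c_j the log plating efficiency of replicate
experiment j and D the interaction: departure of the combined effect from
log-additivity.  In the nested reading, B0 = B is the treatment effect in
control cells and B1 = B0 + D the treatment effect after modification.
Effects are reported on the log scale and as survival percentages
100*exp(effect).  The interaction is tested by the nested-model ANOVA
F-test (reduced model without the x1*x2 column), using the full model's
quasi-likelihood dispersion for ML fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm_core import (
    DesignSpec,
    GLMFit,
    LSFit,
    NestedTest,
    f_test_nested,
    f_test_nested_ls,
    irls_poisson_log,
    ols_log,
    scaled_se,
)
from .io_data import AssayTable
from .lq_model import _drop_zero_colonies, _ls_spec_from_count_spec

__all__ = ["TwoWayFit", "fit_twoway", "effects_as_percent", "interaction_test"]


@dataclass
class TwoWayFit:
    """Fitted 2x2 log-linear model with nested effect report.

    ``effect_b1 = effect_b0 + interaction`` identically; standard errors
    are dispersion-scaled for ML.  ``wald_z_interaction`` is the Wald
    statistic D/SE(D), reported alongside the F-test for transparency.
    """

    effect_a: float
    effect_b0: float
    effect_b1: float
    interaction: float
    se_a: float
    se_b0: float
    se_b1: float
    se_interaction: float
    plating_log: dict
    method: str
    df_residual: int
    interaction_test: NestedTest
    dispersion: float | None = None
    r_squared: float | None = None
    residual_ss: float | None = None
    wald_z_interaction: float | None = None
    raw_fit: GLMFit | LSFit | None = None


def _twoway_design(df: pd.DataFrame, with_interaction: bool) -> DesignSpec:
    exps = list(pd.unique(df["experiment_id"]))
    onehot = (df["experiment_id"].to_numpy()[:, None] == np.array(exps)[None, :]).astype(float)
    x1 = df["factor_a"].to_numpy(dtype=float)
    x2 = df["factor_b"].to_numpy(dtype=float)
    cols = [onehot, x1[:, None], x2[:, None]]
    names = [f"pe:{e}" for e in exps] + ["A", "B0"]
    if with_interaction:
        cols.append((x1 * x2)[:, None])
        names.append("D")
    return DesignSpec(
        design_matrix=np.hstack(cols),
        response=df["colonies"].to_numpy(dtype=float),
        offset=np.log(df["cells_seeded"].to_numpy()),
        coefficient_names=names,
    )


def _validated(table: AssayTable, a_column: str, b_column: str) -> AssayTable:
    df = table.data.copy()
    for canon, col in (("factor_a", a_column), ("factor_b", b_column)):
        if col in df.columns:
            df[canon] = df[col] if canon == col else df[col]
        if canon not in df.columns:
            raise ValueError(f"no factor column {col!r} in table")
        if not set(np.unique(df[canon])) <= {0, 1}:
            raise ValueError(f"factor {col!r} is not binary 0/1")
    cells = df.groupby(["factor_a", "factor_b"]).size()
    missing = {(a, b) for a in (0, 1) for b in (0, 1)} - set(cells.index)
    if missing:
        raise ValueError(f"missing design cell(s): {sorted(missing)}")
    if df["experiment_id"].nunique() < 2:
        raise ValueError("two-way analysis requires >= 2 replicate experiments")
    return AssayTable(df.reset_index(drop=True), dict(table.column_map))


def fit_twoway(
    table: AssayTable,
    a_column: str = "factor_a",
    b_column: str = "factor_b",
    method: str = "ml",
) -> TwoWayFit:
    """Fit the 2x2 log-linear model and test the interaction.

    ML fits a quasi-Poisson GLM on counts with offset log(cells seeded);
    LS fits ordinary least squares on log survival fractions.
    """
    if method not in ("ml", "ls"):
        raise ValueError("method must be 'ml' or 'ls'")
    table = _validated(table, a_column, b_column)
    if method == "ls":
        table = _drop_zero_colonies(table, method)
    df = table.data
    full_spec = _twoway_design(df, with_interaction=True)
    red_spec = _twoway_design(df, with_interaction=False)
    names = full_spec.coefficient_names
    ia, ib, idd = names.index("A"), names.index("B0"), names.index("D")

    if method == "ml":
        full = irls_poisson_log(full_spec)
        red = irls_poisson_log(red_spec)
        test = f_test_nested(red, full)
        coef = full.coefficients
        se = scaled_se(full)
        cov = full.unscaled_covariance * full.dispersion
        extra = dict(dispersion=full.dispersion)
    else:
        counts = df["colonies"].to_numpy(dtype=float)
        full = ols_log(_ls_spec_from_count_spec(full_spec, counts))
        red = ols_log(_ls_spec_from_count_spec(red_spec, counts))
        test = f_test_nested_ls(red, full)
        coef = full.coefficients
        se = full.standard_errors()
        cov = full.covariance
        extra = dict(r_squared=full.r_squared, residual_ss=full.residual_ss)

    b0, d = coef[ib], coef[idd]
    se_b1 = float(np.sqrt(cov[ib, ib] + cov[idd, idd] + 2 * cov[ib, idd]))
    plating = {
        e: float(coef[names.index(f"pe:{e}")]) for e in pd.unique(df["experiment_id"])
    }
    return TwoWayFit(
        effect_a=float(coef[ia]),
        effect_b0=float(b0),
        effect_b1=float(b0 + d),
        interaction=float(d),
        se_a=float(se[ia]),
        se_b0=float(se[ib]),
        se_b1=se_b1,
        se_interaction=float(se[idd]),
        plating_log=plating,
        method=method,
        df_residual=full.df_residual,
        interaction_test=test,
        wald_z_interaction=float(d / se[idd]),
        raw_fit=full,
        **extra,
    )


def effects_as_percent(fit: TwoWayFit) -> dict:
    """Effects converted to survival percentages, 100*exp(effect), 1 decimal."""
    return {
        "A": round(100.0 * float(np.exp(fit.effect_a)), 1),
        "B0": round(100.0 * float(np.exp(fit.effect_b0)), 1),
        "B1": round(100.0 * float(np.exp(fit.effect_b1)), 1),
    }


def interaction_test(
    table: AssayTable,
    a_column: str = "factor_a",
    b_column: str = "factor_b",
    method: str = "ml",
) -> NestedTest:
    """F-test of the interaction D (reduced model omits the x1*x2 column)."""
    return fit_twoway(table, a_column, b_column, method).interaction_test
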