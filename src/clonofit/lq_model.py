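"""Linear-quadratic cell-survival curves from colony counts.

The survival fraction after dose d (Gy) follows

    S(d) = exp(-c - alpha*d - beta*d^2),

where exp(-c) is the plating efficiency (PE) of an experiment — the
fraction of untreated seeded cells that form colonies — and alpha, beta
are the killing parameters per Gy and per Gy^2.  The expected colony count
on a plate with N cells seeded is N*S(d), so on the log scale the model is
a Poisson GLM with offset log N.

Plating efficiencies are either fitted jointly with alpha, beta (one
intercept per replicate experiment, ``pe_method="fit"``) or fixed at the
observed dose-0 ratio of each experiment and moved into the offset
(``pe_method="fix"``, which forces the curve through the dose-0
observation).  Fitting methods: maximum likelihood (``ml``, quasi-Poisson
IRLS), ordinary least squares on log fractions (``ls``) and least squares
weighted by colony counts (``franken``).
"""

from __future__ import annotations

import warnings
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
    wls_log,
)
from .io_data import AssayTable

__all__ = ["LQFit", "build_lq_design", "fit_lq", "predict_survival", "compare_curves"]

METHODS = ("ml", "ls", "franken")
PE_METHODS = ("fit", "fix")


@dataclass
class LQFit:
    """Fitted linear-quadratic survival curve.

    ``alpha`` and ``beta`` carry the killing sign convention of
    S(d) = exp(-c - alpha d - beta d^2): positive values mean cell kill.
    ``plating_log`` maps experiment id -> log plating efficiency (fitted
    intercept for ``pe_method="fit"``, observed dose-0 log ratio for
    ``"fix"``).  For ML fits standard errors are scaled by the square root
    of the quasi-likelihood dispersion.
    """

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    plating_log: dict
    method: str
    pe_method: str
    df_residual: int
    per_experiment_residual_share: dict
    dispersion: float | None = None
    deviance: float | None = None
    pearson_chi2: float | None = None
    r_squared: float | None = None
    residual_ss: float | None = None
    raw_fit: GLMFit | LSFit | None = None
    record_experiments: np.ndarray | None = None
    record_contributions: np.ndarray | None = None


def _single_group(table: AssayTable) -> None:
    if "group" in table.data.columns and table.data["group"].nunique() > 1:
        raise ValueError(
            "table contains several groups; subset to one group before "
            "fitting a single curve (use compare_curves for joint tests)"
        )
    if "dose" not in table.data.columns:
        raise ValueError("curve fitting requires a dose column")


def _pe_fixed(df: pd.DataFrame) -> dict:
    """Observed plating efficiency per experiment from dose-0 plates."""
    pe = {}
    for exp, sub in df.groupby("experiment_id", sort=False):
        ctrl = sub[sub["dose"] == 0]
        if len(ctrl) == 0:
            raise ValueError(f"experiment {exp!r} has no dose-0 plate; cannot fix PE")
        val = ctrl["colonies"].sum() / ctrl["cells_seeded"].sum()
        if val <= 0:
            raise ValueError(f"experiment {exp!r} has zero plating efficiency")
        pe[exp] = float(val)
    return pe


def build_lq_design(
    table: AssayTable,
    pe_method: str = "fit",
    drop_controls: bool = False,
) -> DesignSpec:
    """Build the LQ design for counts: intercepts (or fixed-PE offset) + dose + dose^2.

    ``pe_method="fit"`` uses one indicator column per experiment (no global
    intercept) so each intercept is directly a log plating efficiency.
    ``"fix"`` moves log PE into the offset; dose-0 rows are retained unless
    ``drop_controls`` is set (they still carry residual information when an
    experiment has several control plates).
    """
    if pe_method not in PE_METHODS:
        raise ValueError(f"pe_method must be one of {PE_METHODS}")
    _single_group(table)
    df = table.data
    if pe_method == "fix":
        pe = _pe_fixed(df)
        if drop_controls:
            df = df[df["dose"] > 0].reset_index(drop=True)
        dose = df["dose"].to_numpy()
        X = np.column_stack([dose, dose**2])
        names = ["dose", "dose2"]
        offset = np.log(df["cells_seeded"].to_numpy()) + np.log(
            df["experiment_id"].map(pe).to_numpy(dtype=float)
        )
    else:
        exps = list(pd.unique(df["experiment_id"]))
        dose = df["dose"].to_numpy()
        onehot = (df["experiment_id"].to_numpy()[:, None] == np.array(exps)[None, :]).astype(float)
        X = np.column_stack([onehot, dose, dose**2])
        names = [f"pe:{e}" for e in exps] + ["dose", "dose2"]
        offset = np.log(df["cells_seeded"].to_numpy())
    return DesignSpec(
        design_matrix=X,
        response=df["colonies"].to_numpy(dtype=float),
        offset=offset,
        coefficient_names=names,
    )


def _drop_zero_colonies(table: AssayTable, method: str) -> AssayTable:
    n0 = int((table.data["colonies"] == 0).sum())
    if n0:
        warnings.warn(
            f"excluding {n0} zero-colony plate(s) from the {method} fit "
            "(log of zero undefined); consider the ML method",
            stacklevel=3,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = table.subset(table.data["colonies"] > 0)
    return table


def _ls_spec_from_count_spec(spec: DesignSpec, counts: np.ndarray, weights=None) -> DesignSpec:
    """Reuse a count design for least squares on log fractions.

    The count model is log mu = X b + offset with offset = log N (+ log PE);
    dividing out the offset gives the log-fraction response log(y) - offset.
    """
    with np.errstate(divide="ignore"):
        resp = np.log(counts) - spec.offset
    return DesignSpec(
        design_matrix=spec.design_matrix,
        response=resp,
        offset=None,
        case_weights=weights,
        coefficient_names=spec.coefficient_names,
    )


def fit_lq(table: AssayTable, method: str = "ml", pe_method: str = "fit") -> LQFit:
    """Fit the LQ survival model to a single-group colony-count table."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if method in ("ls", "franken"):
        table = _drop_zero_colonies(table, method)
    spec = build_lq_design(table, pe_method)
    df = table.data
    names = spec.coefficient_names
    i_dose, i_dose2 = names.index("dose"), names.index("dose2")
    exps = df["experiment_id"].to_numpy()

    if method == "ml":
        fit = irls_poisson_log(spec)
        se = scaled_se(fit)
        coef = fit.coefficients
        contrib = fit.pearson_residuals() ** 2
        extra = dict(
            dispersion=fit.dispersion,
            deviance=fit.deviance,
            pearson_chi2=fit.pearson_chi2,
        )
    else:
        counts = df["colonies"].to_numpy(dtype=float)
        w = counts if method == "franken" else None
        ls_spec = _ls_spec_from_count_spec(spec, counts, weights=w)
        fit = wls_log(ls_spec) if method == "franken" else ols_log(ls_spec)
        se = fit.standard_errors()
        coef = fit.coefficients
        resid = ls_spec.response - fit.fitted_values
        ww = w if w is not None else np.ones(len(resid))
        contrib = ww * resid**2
        extra = dict(r_squared=fit.r_squared, residual_ss=fit.residual_ss)

    total = contrib.sum()
    shares = {
        e: float(contrib[exps == e].sum() / total) if total > 0 else np.nan
        for e in pd.unique(exps)
    }
    if pe_method == "fit":
        plating = {
            e: float(coef[names.index(f"pe:{e}")]) for e in pd.unique(exps)
        }
    else:
        plating = {e: float(np.log(v)) for e, v in _pe_fixed(df).items()}

    return LQFit(
        alpha=float(-coef[i_dose]),
        beta=float(-coef[i_dose2]),
        se_alpha=float(se[i_dose]),
        se_beta=float(se[i_dose2]),
        plating_log=plating,
        method=method,
        pe_method=pe_method,
        df_residual=fit.df_residual,
        per_experiment_residual_share=shares,
        raw_fit=fit,
        record_experiments=exps,
        record_contributions=contrib,
        **extra,
    )


def predict_survival(fit: LQFit, doses) -> np.ndarray:
    """Surviving fraction SF(d) = S(d)/S(0) = exp(-alpha d - beta d^2)."""
    d = np.asarray(doses, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    return np.exp(-fit.alpha * d - fit.beta * d**2)


def _grouped_designs(table: AssayTable, group_column: str, common: bool):
    """Design for one common curve (reduced) or per-group curves (full).

    Intercepts are always separate per (group, experiment) pair.
    """
    df = table.data
    if group_column not in df.columns:
        raise ValueError(f"no column {group_column!r} in table")
    groups = list(pd.unique(df[group_column]))
    if len(groups) < 2:
        raise ValueError("curve comparison requires at least 2 groups")
    ge = df[group_column].astype(str) + "\x1f" + df["experiment_id"].astype(str)
    levels = list(pd.unique(ge))
    onehot = (ge.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    dose = df["dose"].to_numpy()
    cols = [onehot]
    names = [f"pe:{l.replace(chr(31), '/')}" for l in levels]
    if common:
        cols += [dose[:, None], (dose**2)[:, None]]
        names += ["dose", "dose2"]
    else:
        for g in groups:
            ind = (df[group_column] == g).to_numpy().astype(float)
            cols += [(dose * ind)[:, None], (dose**2 * ind)[:, None]]
            names += [f"dose:{g}", f"dose2:{g}"]
    X = np.hstack(cols)
    return DesignSpec(
        design_matrix=X,
        response=df["colonies"].to_numpy(dtype=float),
        offset=np.log(df["cells_seeded"].to_numpy()),
        coefficient_names=names,
    )


def compare_curves(
    table: AssayTable, group_column: str = "group", method: str = "ml"
) -> NestedTest:
    """ANOVA F-test for a difference between LQ curves of several groups.

    Model 1 (reduced) fits one common (alpha, beta) to all groups; model 2
    (full) fits group-specific dose and dose^2 terms.  Per-(group,
    experiment) plating efficiencies are fitted in both models.  The
    p-value is the probability that the residual-scatter difference between
    the two models arises by chance.
    """
    if method not in ("ml", "ls"):
        raise ValueError("comparison supports methods 'ml' and 'ls'")
    if method == "ls":
        table = _drop_zero_colonies(table, method)
    reduced_spec = _grouped_designs(table, group_column, common=True)
    full_spec = _grouped_designs(table, group_column, common=False)
    if method == "ml":
        return f_test_nested(
            irls_poisson_log(reduced_spec), irls_poisson_log(full_spec)
        )
    counts = table.data["colonies"].to_numpy(dtype=float)
    red = ols_log(_ls_spec_from_count_spec(reduced_spec, counts))
    full = ols_log(_ls_spec_from_count_spec(full_spec, counts))
    return f_test_nested_ls(red, full)
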