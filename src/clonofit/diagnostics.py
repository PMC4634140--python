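"""Replicate-level quality assessment for pooled survival-curve fits.

Replicated clonogenic experiments often scatter more than Poisson counting
statistics allow (dispersion > 1).  To locate the source, each experiment
gets (i) its share of the pooled fit's total weighted residual sum of
squares — under exchangeability every one of k experiments is expected to
contribute 1/k — and (ii) its own single-experiment LQ refit, whose
within-experiment dispersion separates "internally noisy" from "internally
clean but shifted relative to the mean curve".  A pooled dispersion above
``DISPERSION_WARN`` (three Poisson standard deviations, by the three-sigma
rule) flags data worth inspecting for outlying points or experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io_data import AssayTable
from .lq_model import LQFit, fit_lq, predict_survival

__all__ = [
    "ReplicateDiagnostic",
    "per_experiment_diagnostics",
    "plot_curve",
    "plot_diagnostics",
    "DISPERSION_WARN",
]

#: default critical dispersion (~3 Poisson standard deviations)
DISPERSION_WARN = 9.0


@dataclass
class ReplicateDiagnostic:
    """Per-experiment share of the pooled residual and single-experiment refit."""

    experiment_id: str
    residual_share: float
    single_fit: LQFit | None
    within_dispersion: float | None


def per_experiment_diagnostics(
    table: AssayTable, pooled: LQFit
) -> list[ReplicateDiagnostic]:
    """Decompose the pooled fit's residual by experiment and refit each alone.

    Shares come from the pooled fit's per-plate contributions (Pearson
    weighted squared residuals for ML, squared log-residuals for LS) and
    sum to 1.  A single-experiment refit needs >= 3 distinct doses (the LQ
    curve has 3 free parameters per experiment); otherwise it is omitted
    with a warning.
    """
    known = set(table.experiments)
    if set(pooled.per_experiment_residual_share) - known:
        raise ValueError("pooled fit refers to experiment ids absent from the table")
    out = []
    for exp in table.experiments:
        share = pooled.per_experiment_residual_share[exp]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-experiment subset
            sub = table.subset(table.data["experiment_id"] == exp)
        single = None
        within = None
        if sub.data["dose"].nunique() >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                single = fit_lq(sub, method=pooled.method, pe_method=pooled.pe_method)
            if single.df_residual >= 1:
                within = (
                    single.dispersion
                    if pooled.method == "ml"
                    else single.residual_ss / single.df_residual
                )
        else:
            warnings.warn(
                f"experiment {exp!r} has < 3 distinct doses; within-experiment "
                "fit omitted",
                stacklevel=2,
            )
        out.append(
            ReplicateDiagnostic(
                experiment_id=exp,
                residual_share=share,
                single_fit=single,
                within_dispersion=within,
            )
        )
    return out


def _observed_sf(table: AssayTable, fit: LQFit):
    """Observed per-plate surviving fractions normalized by plating efficiency."""
    df = table.data
    pe = df["experiment_id"].map({k: np.exp(v) for k, v in fit.plating_log.items()})
    sf = df["colonies"] / df["cells_seeded"] / pe.to_numpy(dtype=float)
    return df["dose"].to_numpy(), sf.to_numpy(), df["experiment_id"].to_numpy()


def plot_curve(fit: LQFit, table: AssayTable, path) -> None:
    """Semi-log plot of the fitted mean survival curve with observed points."""
    doses, sf, exps = _observed_sf(table, fit)
    if len(doses) == 0 or np.ptp(doses) == 0:
        raise ValueError("empty or degenerate dose range; nothing to plot")
    grid = np.linspace(0, doses.max(), 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    for exp in dict.fromkeys(exps):
        m = exps == exp
        ax.plot(doses[m], sf[m], "o", ms=4, alpha=0.6, label=None)
    ax.plot(grid, predict_survival(fit, grid), "-", color="black", label="mean curve")
    ax.set_yscale("log")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("surviving fraction")
    ax.set_title(
        f"LQ fit ({fit.method}): alpha={fit.alpha:.3g}/Gy, beta={fit.beta:.3g}/Gy$^2$"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_diagnostics(
    diagnostics: list[ReplicateDiagnostic],
    table: AssayTable,
    pooled: LQFit,
    out_prefix,
) -> list[str]:
    """One plot per experiment: mean curve solid, single-experiment curve
    dashed, residual share annotated in the title.  Returns written paths."""
    doses, sf, exps = _observed_sf(table, pooled)
    grid = np.linspace(0, doses.max(), 200)
    paths = []
    for diag in diagnostics:
        fig, ax = plt.subplots(figsize=(5, 4))
        m = exps == diag.experiment_id
        ax.plot(doses[m], sf[m], "o", color="C0")
        ax.plot(grid, predict_survival(pooled, grid), "-", color="black")
        if diag.single_fit is not None:
            ax.plot(grid, predict_survival(diag.single_fit, grid), "--", color="C3")
        ax.set_yscale("log")
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("surviving fraction")
        ax.set_title(
            f"experiment {diag.experiment_id}: "
            f"{100 * diag.residual_share:.1f} % of residual sum"
        )
        fig.tight_layout()
        p = f"{out_prefix}_{diag.experiment_id}.png"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)
    return paths
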