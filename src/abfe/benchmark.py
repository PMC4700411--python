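"""Accuracy and precision statistics for predicted vs experimental affinities.

Ships the BRD4(1) bromodomain benchmark of eleven inhibitors: calculated
standard binding free energies starting from crystal poses (table 1) and
from docked poses (table 2), experimental affinities, and the docking
scores, all in kcal/mol.  The summary layer computes MAE, RMSE and rank
correlations with paired-bootstrap uncertainties over ligands.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkRecord",
    "BenchmarkSummary",
    "load_benchmark_table",
    "mae",
    "rmse",
    "pearson",
    "spearman",
    "bootstrap_metric",
    "summarize",
]


@dataclass(frozen=True)
class BenchmarkRecord:
    """One ligand's calculated, experimental and docking free energies."""

    ligand: int
    dG_calc: float
    dG_calc_sd: float
    dG_exp: float
    dG_exp_sd: float | None
    docking_dG: float | None
    table: int


def load_benchmark_table(table: int | None = None) -> pd.DataFrame:
    """Load the packaged per-ligand affinity table.

    ``table`` 1 selects the crystal-structure results, 2 the docking-based
    results; None returns both.  A missing experimental uncertainty
    (single measurement) is NaN, never zero.
    """
    ref = importlib.resources.files("abfe.data").joinpath("brd4_affinities.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if table is not None:
        if table not in (1, 2):
            raise ValueError(f"table must be 1 or 2, got {table}")
        df = df[df["table"] == table].reset_index(drop=True)
    return df


def records(table: int) -> list[BenchmarkRecord]:
    df = load_benchmark_table(table)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            BenchmarkRecord(
                ligand=int(row.ligand),
                dG_calc=float(row.dG_calc),
                dG_calc_sd=float(row.dG_calc_sd),
                dG_exp=float(row.dG_exp),
                dG_exp_sd=None if pd.isna(row.dG_exp_sd) else float(row.dG_exp_sd),
                docking_dG=None if pd.isna(row.docking_dG) else float(row.docking_dG),
                table=int(row.table),
            )
        )
    return out


def _paired(pred: Sequence[float], exp: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=np.float64)
    e = np.asarray(exp, dtype=np.float64)
    if p.shape != e.shape or p.ndim != 1:
        raise ValueError("pred and exp must be 1-D and equally long")
    if p.size < 1:
        raise ValueError("at least one pair is required")
    return p, e


def mae(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Mean absolute error in kcal/mol."""
    p, e = _paired(pred, exp)
    return float(np.mean(np.abs(p - e)))


def rmse(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Root mean squared error in kcal/mol."""
    p, e = _paired(pred, exp)
    return float(np.sqrt(np.mean((p - e) ** 2)))


def _check_correlation_input(p: np.ndarray, e: np.ndarray) -> None:
    if p.size < 3:
        raise ValueError("correlations need at least 3 pairs")
    if p.std() == 0 or e.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")


def pearson(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Plug-in product-moment correlation."""
    p, e = _paired(pred, exp)
    _check_correlation_input(p, e)
    return float(stats.pearsonr(p, e).statistic)


def spearman(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Rank correlation (Pearson on midranks, ties averaged)."""
    p, e = _paired(pred, exp)
    _check_correlation_input(p, e)
    return float(stats.spearmanr(p, e).statistic)


def bootstrap_metric(
    metric: Callable[[np.ndarray, np.ndarray], float],
    pred: Sequence[float],
    exp: Sequence[float],
    n_boot: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Paired bootstrap over ligands: mean and sample sd of the metric.

    Ligand records are resampled with replacement in pairs; replicates on
    which the metric is undefined (e.g. zero variance for a correlation)
    are skipped.
    """
    p, e = _paired(pred, exp)
    if p.size < 2:
        raise ValueError("bootstrap needs at least 2 pairs")
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    n_ok = 0
    for b in range(n_boot):
        idx = rng.integers(0, p.size, size=p.size)
        try:
            values[n_ok] = metric(p[idx], e[idx])
            n_ok += 1
        except ValueError:
            continue
    if n_ok < 2:
        raise ValueError("metric undefined on nearly all bootstrap replicates")
    values = values[:n_ok]
    return float(values.mean()), float(values.std(ddof=1))


@dataclass(frozen=True)
class BenchmarkSummary:
    """Plug-in metrics with paired-bootstrap mean and sd for each."""

    n: int
    mae: float
    rmse: float
    pearson_r: float
    spearman_rho: float
    bootstrap: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.mae > self.rmse + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")
        for r in (self.pearson_r, self.spearman_rho):
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "n_ligands": self.n,
            "mae_kcal_mol": self.mae,
            "rmse_kcal_mol": self.rmse,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "bootstrap": {
                name: {"mean": m, "sd": s} for name, (m, s) in self.bootstrap.items()
            },
        }


def summarize(
    pred: Sequence[float],
    exp: Sequence[float],
    n_boot: int = 10000,
    seed: int | None = 0,
) -> BenchmarkSummary:
    """Full accuracy summary of predicted vs experimental free energies."""
    p, e = _paired(pred, exp)
    boot = {
        "mae": bootstrap_metric(mae, p, e, n_boot=n_boot, seed=seed),
        "rmse": bootstrap_metric(rmse, p, e, n_boot=n_boot, seed=seed),
        "pearson_r": bootstrap_metric(pearson, p, e, n_boot=n_boot, seed=seed),
        "spearman_rho": bootstrap_metric(spearman, p, e, n_boot=n_boot, seed=seed),
    }
    return BenchmarkSummary(
        n=p.size,
        mae=mae(p, e),
        rmse=rmse(p, e),
        pearson_r=pearson(p, e),
        spearman_rho=spearman(p, e),
        bootstrap=boot,
    )
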