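"""Equilibration discard and decorrelation of per-window energy time series.

Correlated samples from a single simulation window carry less information
than independent draws; the statistical inefficiency g = 1 + 2*tau (tau the
integrated autocorrelation time) is the thinning factor that makes the
retained samples behave as approximately independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DecorrelationInfo", "statistical_inefficiency", "prepare_samples"]


@dataclass(frozen=True)
class DecorrelationInfo:
    """Decorrelation diagnostics for one time series.

    Attributes
    ----------
    g : float
        Statistical inefficiency, g = 1 + 2*tau >= 1 (dimensionless).
    tau : float
        Integrated autocorrelation time in units of samples.
    n_effective : int
        Number of samples retained after discard and strided subsampling.
    discard_fraction : float
        Fraction of the series removed from the front as equilibration.
    """

    g: float
    tau: float
    n_effective: int
    discard_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.g < 1.0:
            raise ValueError(f"statistical inefficiency must be >= 1, got {self.g}")
        if not 0.0 <= self.discard_fraction < 1.0:
            raise ValueError(
                f"discard fraction must lie in [0, 1), got {self.discard_fraction}"
            )


def statistical_inefficiency(series: Sequence[float]) -> DecorrelationInfo:
    """Estimate the statistical inefficiency of a scalar time series.

    The normalized autocovariance is summed with the triangular (1 - t/T)
    factor and truncated at the first non-positive value; a constant series
    returns g = 1 by convention.

    Parameters
    ----------
    series : array-like of float
        Scalar time series of length >= 2.

    Returns
    -------
    DecorrelationInfo
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    if n < 2:
        raise ValueError(f"series must contain at least 2 samples, got {n}")

    dx = x - x.mean()
    var = float(np.dot(dx, dx)) / n
    if var <= 0.0 or not np.isfinite(var):
        return DecorrelationInfo(g=1.0, tau=0.0, n_effective=n)

    acc = 0.0
    for t in range(1, n):
        c = float(np.dot(dx[: n - t], dx[t:])) / ((n - t) * var)
        if c <= 0.0:
            break
        acc += (1.0 - t / n) * c
    g = max(1.0, 1.0 + 2.0 * acc)
    tau = (g - 1.0) / 2.0
    stride = math.ceil(g)
    n_effective = len(range(0, n, stride))
    return DecorrelationInfo(g=g, tau=tau, n_effective=n_effective)


def prepare_samples(
    series_per_state: Sequence[Sequence[float]],
    discard_fraction: float = 0.0,
) -> tuple[list[np.ndarray], list[DecorrelationInfo]]:
    """Select equilibrated, decorrelated sample indices for each state.

    For each state the first ``floor(discard_fraction * n)`` samples are
    removed as equilibration, the statistical inefficiency g is estimated
    on the remainder, and indices are thinned with stride ``ceil(g)``
    starting at the first retained frame.

    Parameters
    ----------
    series_per_state : sequence of 1-D array-like
        One scalar time series (typically the window's own potential
        energy) per sampled state.
    discard_fraction : float
        Fraction in [0, 1) removed from the front of every series.

    Returns
    -------
    indices : list of int arrays
        Retained sample indices into each original series.
    infos : list of DecorrelationInfo
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError(
            f"discard fraction must lie in [0, 1), got {discard_fraction}"
        )
    indices: list[np.ndarray] = []
    infos: list[DecorrelationInfo] = []
    for series in series_per_state:
        x = np.asarray(series, dtype=np.float64)
        n = x.size
        start = int(math.floor(discard_fraction * n))
        kept = x[start:]
        if kept.size < 2:
            raise ValueError(
                "fewer than 2 samples remain after discarding equilibration"
            )
        info = statistical_inefficiency(kept)
        stride = math.ceil(info.g)
        idx = np.arange(start, n, stride, dtype=np.intp)
        indices.append(idx)
        infos.append(
            DecorrelationInfo(
                g=info.g,
                tau=info.tau,
                n_effective=idx.size,
                discard_fraction=discard_fraction,
            )
        )
    return indices, infos
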