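"""Clonal statistics: surviving means, rescaled/standardised distributions,
distances to reference laws and cross-model percentile bands.

All clone-size statistics are survivor-conditioned (``n > 0``): extinct
clones only enter the extinct-fraction curve. The rescaled size is
``x = n / n_bar_s`` (unit mean by construction) and the standardised size is
``x_tilde = (n - n_bar_s) / sigma_n`` (zero mean, unit variance by
construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .laws import AnalyticLaw
from .simulate import CloneEnsemble

__all__ = [
    "CloneSizeStatistics",
    "surviving_mean_curve",
    "surviving_sizes",
    "rescaled_distribution",
    "standardized_distribution",
    "ks_distance",
    "ensemble_percentile_bands",
    "statistics_table",
    "kde_mode_count",
]


def surviving_sizes(ensemble: CloneEnsemble, checkpoint: int) -> np.ndarray:
    """Total sizes of surviving clones (n > 0) at one checkpoint index."""
    total = ensemble.total[:, checkpoint]
    return total[total > 0]


def surviving_mean_curve(ensemble: CloneEnsemble) -> np.ndarray:
    """Mean clone size among surviving clones, ``n_bar_s(t)``, per checkpoint."""
    total = ensemble.total
    alive = total > 0
    n_alive = alive.sum(axis=0)
    if (n_alive == 0).any():
        first = int(np.argmax(n_alive == 0))
        raise ValueError(
            f"no surviving clones at checkpoint {first} (t = {ensemble.times[first]:g})"
        )
    return (total * alive).sum(axis=0) / n_alive


def rescaled_distribution(ensemble: CloneEnsemble, checkpoint: int = -1) -> np.ndarray:
    """Sample of ``x = n / n_bar_s`` among survivors; mean exactly 1."""
    n = surviving_sizes(ensemble, checkpoint)
    if n.size == 0:
        raise ValueError("no surviving clones at the requested checkpoint")
    return n / n.mean()


def standardized_distribution(ensemble: CloneEnsemble, checkpoint: int = -1) -> np.ndarray:
    """Sample of ``x_tilde = (n - n_bar_s) / sigma_n`` among survivors;
    zero mean and unit variance by construction."""
    n = surviving_sizes(ensemble, checkpoint).astype(float)
    if n.size == 0:
        raise ValueError("no surviving clones at the requested checkpoint")
    sigma = n.std()
    if sigma == 0:
        raise ValueError("degenerate sample: all surviving clones have equal size")
    return (n - n.mean()) / sigma


@dataclass(frozen=True)
class CloneSizeStatistics:
    """Per-checkpoint summary of one ensemble."""

    times: np.ndarray
    n_bar_s: np.ndarray
    sigma_n: np.ndarray
    extinct_fraction: np.ndarray

    @classmethod
    def from_ensemble(cls, ensemble: CloneEnsemble) -> "CloneSizeStatistics":
        total = ensemble.total
        alive = total > 0
        n_alive = alive.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n_alive > 0, (total * alive).sum(axis=0) / n_alive, np.nan)
            sq = (total.astype(float) ** 2 * alive).sum(axis=0)
            var = np.where(n_alive > 0, sq / n_alive - mean**2, np.nan)
        return cls(
            times=ensemble.times,
            n_bar_s=mean,
            sigma_n=np.sqrt(np.clip(var, 0.0, None)),
            extinct_fraction=1.0 - n_alive / ensemble.n_clones,
        )


def ks_distance(sample: np.ndarray, law: AnalyticLaw) -> float:
    """Two-sided Kolmogorov–Smirnov distance between the empirical CDF of
    ``sample`` and the law's CDF.

    For discrete laws the sup is taken over the integer support (the ECDF and
    CDF only jump there); for continuous laws this is the standard KS
    statistic.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    if law.cdf is None:
        raise ValueError(f"law {law.kind} has no CDF: unsupported comparison")
    if law.discrete:
        hi = int(sample.max())
        grid = np.arange(hi + 1)
        ecdf = np.searchsorted(np.sort(sample), grid, side="right") / sample.size
        return float(np.abs(ecdf - law.cdf(grid)).max())
    return float(sps.kstest(sample, law.cdf).statistic)


def ensemble_percentile_bands(
    distributions: list[tuple[np.ndarray, np.ndarray]],
    grid: np.ndarray,
    levels: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> pd.DataFrame:
    """Pointwise cross-model quantile envelope of curves.

    ``distributions`` holds per-model ``(x, y)`` curves (e.g. an ECDF or a
    binned density); each is interpolated onto ``grid`` and the requested
    percentiles are taken across models at each grid point.
    """
    if not distributions:
        raise ValueError("no distributions supplied")
    grid = np.asarray(grid, dtype=float)
    ys = np.array(
        [np.interp(grid, np.asarray(x, float), np.asarray(y, float)) for x, y in distributions]
    )
    data = {"x": grid}
    for lv in levels:
        data[f"p{lv:g}"] = np.percentile(ys, lv, axis=0)
    return pd.DataFrame(data)


def statistics_table(
    model_id: str,
    ensemble: CloneEnsemble,
    ks_exp: float | None = None,
    ks_norm: float | None = None,
) -> pd.DataFrame:
    """Per-checkpoint statistics table (long format, one row per time)."""
    st = CloneSizeStatistics.from_ensemble(ensemble)
    return pd.DataFrame(
        {
            "model_id": model_id,
            "t": st.times,
            "n_bar_s": st.n_bar_s,
            "sigma_n": st.sigma_n,
            "extinct_frac": st.extinct_fraction,
            "ks_exp": ks_exp,
            "ks_norm": ks_norm,
        }
    )


def kde_mode_count(
    sample: np.ndarray,
    bw_method: float | str = "scott",
    rel_height: float = 0.1,
) -> int:
    """Number of well-separated modes of a Gaussian KDE of the sample.

    A local maximum counts as a mode when it rises above ``rel_height`` times
    the global maximum and is separated from neighbouring modes by a valley
    at least ``rel_height`` of the global maximum below the smaller peak.
    Used as a pragmatic bimodality check for clone-size distributions.
    """
    sample = np.asarray(sample, dtype=float)
    kde = sps.gaussian_kde(sample, bw_method=bw_method)
    lo, hi = sample.min(), sample.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    peak = dens.max()
    maxima = [
        i
        for i in range(1, len(grid) - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1] and dens[i] > rel_height * peak
    ]
    # merge maxima not separated by a sufficiently deep valley
    modes = 0
    last_kept = None
    for i in maxima:
        if last_kept is None:
            modes += 1
            last_kept = i
            continue
        valley = dens[last_kept:i + 1].min()
        smaller = min(dens[last_kept], dens[i])
        if smaller - valley > rel_height * peak:
            modes += 1
            last_kept = i
        elif dens[i] > dens[last_kept]:
            last_kept = i
    return modes
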