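"""Reference clone-size laws: universal limits and exactly solvable cases.

The two universality classes of homeostatic cell-fate models have simple
limiting clone-size distributions: GPA models approach a unit-mean
Exponential in rescaled size ``x = n / n_bar_s``, and GIA models approach a
Normal (in standardised size) when the renewing compartment's rates are fast
compared with the committed loss rate ``gamma_C``.

The two-state GIA chain

    X1 -> X1 + X2  (rate lambda1, X1 conserved)
    X2 -> X2 + X2  (rate lambda2)
    X2 -> 0        (rate gamma, with lambda2 < gamma)

is an immigration–birth–death process for ``n2`` whose stationary law is
negative binomial with shape ``lambda1/lambda2`` and success probability
``lambda2/gamma`` (Poisson with mean ``lambda1/gamma`` when ``lambda2 = 0``),
and mean ``n_bar_2 = lambda1 / (gamma - lambda2)``. For large ``n_bar_2``
the rescaled law ``x2 = n2 / n_bar_2`` has the closed-form density
implemented by :func:`two_state_gia_density`, controlled by the
dimensionless parameters ``lhat1 = lambda1/gamma`` and
``lhat2 = lambda2/gamma``. It interpolates between an Exponential
(``lhat1 -> 1``, ``lhat2 -> 1``) and a Normal of mean 1 and variance
``1/lhat1`` (``lhat1 -> infinity``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, sparse, stats
from scipy.sparse.linalg import expm_multiply
from scipy.special import gammaln

from .models import CellFateModel, require_valid

__all__ = [
    "TwoStateGIAParams",
    "AnalyticLaw",
    "exp_unit_mean",
    "normal_std",
    "normal",
    "poisson",
    "gia0_stationary_law",
    "exact_gia0_stationary",
    "two_state_gia_density",
    "two_state_gia_law",
    "normal_limit",
    "master_equation_oracle",
]


@dataclass(frozen=True)
class TwoStateGIAParams:
    """Dimensionless parameters of the two-state GIA chain:
    ``lhat1 = lambda1/gamma > 0`` and ``0 <= lhat2 = lambda2/gamma < 1``
    (homeostasis requires the committed loss rate to exceed its division
    rate)."""

    lhat1: float
    lhat2: float

    def __post_init__(self) -> None:
        if not self.lhat1 > 0:
            raise ValueError("lhat1 must be positive")
        if not (0 <= self.lhat2 < 1):
            raise ValueError("lhat2 must lie in [0, 1): homeostasis needs lambda2 < gamma")

    @property
    def mean_committed(self) -> float:
        """Stationary mean committed-cell number lambda1/(gamma - lambda2)."""
        return self.lhat1 / (1.0 - self.lhat2)


@dataclass(frozen=True)
class AnalyticLaw:
    """A reference distribution with a CDF (and pdf or pmf).

    ``kind`` names the law; ``discrete`` laws expose ``pmf`` on integers,
    continuous ones ``pdf``. Used as the right-hand side of KS comparisons.
    """

    kind: str
    discrete: bool
    cdf: callable
    pdf: callable | None = None
    pmf: callable | None = None
    mean: float | None = None
    var: float | None = None

    def evaluate_grid(self, x: np.ndarray):
        """Tabulate (x, pdf-or-pmf, cdf) for export/plotting."""
        x = np.asarray(x, dtype=float)
        density = self.pmf(x) if self.discrete else self.pdf(x)
        return x, density, self.cdf(x)


def exp_unit_mean() -> AnalyticLaw:
    d = stats.expon()
    return AnalyticLaw("exp_unit_mean", False, d.cdf, pdf=d.pdf, mean=1.0, var=1.0)


def normal_std() -> AnalyticLaw:
    d = stats.norm()
    return AnalyticLaw("normal_std", False, d.cdf, pdf=d.pdf, mean=0.0, var=1.0)


def normal(mean: float, var: float) -> AnalyticLaw:
    d = stats.norm(loc=mean, scale=np.sqrt(var))
    return AnalyticLaw(f"normal({mean:g},{var:g})", False, d.cdf, pdf=d.pdf, mean=mean, var=var)


def poisson(mu: float) -> AnalyticLaw:
    d = stats.poisson(mu)
    return AnalyticLaw(f"poisson({mu:g})", True, d.cdf, pmf=d.pmf, mean=mu, var=mu)


def gia0_stationary_law(lambda1: float, lambda2: float, gamma: float) -> AnalyticLaw:
    """Exact stationary law of the committed-cell count in the two-state GIA
    chain: negative binomial (Poisson when ``lambda2 = 0``); mean
    ``lambda1/(gamma - lambda2)``."""
    if lambda2 >= gamma:
        raise ValueError("stationarity requires lambda2 < gamma")
    if lambda2 == 0:
        return poisson(lambda1 / gamma)
    shape = lambda1 / lambda2
    p_success = lambda2 / gamma  # per-cell birth vs death odds
    d = stats.nbinom(shape, 1.0 - p_success)
    mean = lambda1 / (gamma - lambda2)
    var = mean / (1.0 - p_success)
    return AnalyticLaw(
        f"gia0({lambda1:g},{lambda2:g},{gamma:g})", True, d.cdf, pmf=d.pmf,
        mean=mean, var=var,
    )


def exact_gia0_stationary(n, lambda1: float, lambda2: float, gamma: float):
    """Stationary probability mass at committed-cell count ``n``."""
    law = gia0_stationary_law(lambda1, lambda2, gamma)
    return law.pmf(n)


# ---------------------------------------------------------------------------
# Closed-form rescaled law of the two-state GIA chain
# ---------------------------------------------------------------------------

def two_state_gia_density(x2, params: TwoStateGIAParams):
    """Density of the rescaled committed-cell count ``x2 = n2 / n_bar_2``.

    Evaluated entirely in log-space (log-Gamma differences): the direct
    Gamma-function form overflows for ``lhat1`` beyond ~170. The
    ``lhat2 = 0`` branch is the continuity limit of the expression (the
    continuised Poisson law of the pure immigration–death chain).
    """
    l1, l2 = params.lhat1, params.lhat2
    x2 = np.asarray(x2, dtype=float)
    out = np.full(x2.shape, 0.0)
    pos = x2 > 0
    x = x2[pos]
    if l2 < 1e-10:  # continuity limit; also avoids inf/nan from r = l1/l2
        # continuised Poisson(l1) at n = l1 * x, with Jacobian n_bar = l1
        n = l1 * x
        log_p = -l1 + n * np.log(l1) - gammaln(n + 1.0) + np.log(l1)
        out[pos] = np.exp(log_p)
        return out if out.ndim else float(out)
    z = l1 * x / (1.0 - l2)  # committed-cell count at this rescaled size
    r = l1 / l2
    log_p = (
        r * np.log1p(-l2)
        + z * np.log(l2)
        + gammaln(r + z)
        - gammaln(r)
        - gammaln(z)
        - np.log(x)
    )
    out[pos] = np.exp(log_p)
    return out if out.ndim else float(out)


def _gia_two_state_grid(params: TwoStateGIAParams, n_points: int = 4001):
    """Support grid covering the bulk and tails of the rescaled law."""
    sd = 1.0 / np.sqrt(params.lhat1)  # exact: var(x2) = 1/lhat1 for the NB law
    hi = 1.0 + max(12.0 * sd, 3.0)
    return np.linspace(1e-12, hi, n_points)


def two_state_gia_law(params: TwoStateGIAParams) -> AnalyticLaw:
    """Closed-form rescaled law packaged with a tabulated CDF and moments."""
    grid = _gia_two_state_grid(params)
    pdf_grid = two_state_gia_density(grid, params)
    cdf_grid = integrate.cumulative_trapezoid(pdf_grid, grid, initial=0.0)
    total = cdf_grid[-1]

    def cdf(x):
        return np.clip(np.interp(np.asarray(x, float), grid, cdf_grid / total), 0.0, 1.0)

    mean = float(np.trapezoid(grid * pdf_grid, grid) / total)
    var = float(np.trapezoid((grid - mean) ** 2 * pdf_grid, grid) / total)
    return AnalyticLaw(
        f"two_state_gia({params.lhat1:g},{params.lhat2:g})",
        False,
        cdf,
        pdf=lambda x: two_state_gia_density(x, params),
        mean=mean,
        var=var,
    )


def normal_limit(params: TwoStateGIAParams) -> AnalyticLaw:
    """Fast-division limit of the rescaled two-state GIA law: Normal with
    unit mean and variance ``1/lhat1``. Meaningful for large ``lhat1``; for
    small ``lhat1`` the Normal form is not yet a good approximation."""
    return normal(1.0, 1.0 / params.lhat1)


# ---------------------------------------------------------------------------
# Brute-force master-equation oracle
# ---------------------------------------------------------------------------

def master_equation_oracle(
    model: CellFateModel,
    initial_state: str,
    t: float,
    cap: int = 16,
    max_cap: int = 4096,
    tail_tol: float = 1e-8,
):
    """Clone-size distribution by direct integration of the master equation.

    The continuous-time Markov chain over per-state counts ``(n_1..n_m)`` is
    truncated to ``n_i <= cap``; probability flowing past the cap is
    collected in an absorbing overflow state, and the cap doubles until the
    overflow mass at time ``t`` is below ``tail_tol``. Only practical for
    small models (m <= 3). Returns ``(sizes, probs)`` over the total clone
    size ``n = sum_i n_i``.
    """
    require_valid(model)
    m = model.n_states
    if m > 3:
        raise ValueError("master-equation oracle is limited to m <= 3 states")
    lam = model.division_rate
    omega = model.transition_rate
    gamma = model.loss_rate
    init = model.index(initial_state)
    while True:
        dims = (cap + 1,) * m
        n_lattice = int(np.prod(dims))
        overflow = n_lattice  # absorbing overflow index
        strides = np.array([int(np.prod(dims[i + 1:])) for i in range(m)], dtype=np.int64)

        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []

        def add(frm: int, to: int, rate: float) -> None:
            rows.append(to)
            cols.append(frm)
            vals.append(rate)
            rows.append(frm)
            cols.append(frm)
            vals.append(-rate)

        grids = np.indices(dims).reshape(m, -1)
        for flat in range(n_lattice):
            n_vec = grids[:, flat]
            for i in range(m):
                ni = int(n_vec[i])
                if ni == 0:
                    continue
                # divisions
                if lam[i] > 0:
                    for j, k, p in model.daughter_pairs[i]:
                        rate = lam[i] * ni * p
                        if rate == 0:
                            continue
                        delta = np.zeros(m, dtype=np.int64)
                        delta[i] -= 1
                        delta[j] += 1
                        delta[k] += 1
                        target = n_vec + delta
                        if (target > cap).any():
                            add(flat, overflow, rate)
                        else:
                            add(flat, int(flat + delta @ strides), rate)
                # transitions
                for j in range(m):
                    if omega[i, j] <= 0:
                        continue
                    rate = omega[i, j] * ni
                    if n_vec[j] + 1 > cap:
                        add(flat, overflow, rate)
                    else:
                        add(flat, flat - int(strides[i]) + int(strides[j]), rate)
                # loss
                if gamma[i] > 0:
                    add(flat, flat - int(strides[i]), gamma[i] * ni)

        Q = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n_lattice + 1, n_lattice + 1)
        )
        p0 = np.zeros(n_lattice + 1)
        p0[int(strides[init])] = 1.0  # one cell in the initial state
        pt = expm_multiply(Q * float(t), p0)
        pt = np.clip(pt, 0.0, None)
        if pt[overflow] <= tail_tol:
            totals = grids.sum(axis=0)
            sizes = np.arange(totals.max() + 1)
            probs = np.bincount(totals, weights=pt[:n_lattice], minlength=sizes.size)
            return sizes, probs / probs.sum()
        cap *= 2
        if cap > max_cap:
            raise RuntimeError(
                f"overflow mass {pt[overflow]:.2e} above {tail_tol:g} even at cap {max_cap}"
            )
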