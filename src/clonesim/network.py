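"""Cell-state network analysis: homeostasis and the GIA/GPA dichotomy.

The mean-field matrix ``A`` is read as the weighted adjacency matrix of the
*cell state network*: a directed edge ``i -> j`` exists wherever the total
transition rate ``kappa_ij`` is positive. Condensing the network into its
strongly connected components (SCCs) yields an acyclic graph; the model is
homeostatic when the condensation has a unique source ("apex") SCC whose
dominant eigenvalue (Perron root of the principal submatrix of ``A``) is
zero, while every downstream SCC has a strictly negative one.

The apex SCC is the *renewing compartment* (R); everything downstream is the
*committed compartment* (C). A homeostatic model is *Generalized Invariant
Asymmetry* (GIA) when every event conserves the number of R-cells — i.e.
divisions of R-states always yield exactly one R daughter, and R-states have
no transitions into C and no loss. Otherwise it is *Generalized Population
Asymmetry* (GPA): gain and loss of R-cells balance only on average.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .models import CellFateModel, MeanFieldSystem, build_mean_field

__all__ = [
    "HOMEOSTASIS_TOL",
    "CellStateNetwork",
    "CompartmentDecomposition",
    "EffectiveRates",
    "NotHomeostaticError",
    "build_network",
    "scc_condense",
    "dominant_eigenvalue",
    "check_homeostasis",
    "classify",
    "stationary_mean_vector",
    "effective_rates",
    "decompose",
]

#: |mu_apex| at or below this counts as zero; downstream mu must be < -tol.
HOMEOSTASIS_TOL = 1e-8


class NotHomeostaticError(ValueError):
    pass


@dataclass(frozen=True)
class CellStateNetwork:
    """Directed weighted graph over cell states with edges where kappa_ij > 0."""

    mean_field: MeanFieldSystem
    graph: nx.DiGraph

    @property
    def states(self) -> tuple[str, ...]:
        return self.mean_field.states


def build_network(mf: MeanFieldSystem) -> CellStateNetwork:
    """Edges are exactly ``{(i, j): kappa_ij > 0, i != j}``; the diagonal
    self-link weights are carried as node annotations."""
    m = len(mf.states)
    g = nx.DiGraph()
    for i in range(m):
        g.add_node(i, label=mf.states[i], self_weight=float(mf.total_transition_rate[i, i]))
    for i in range(m):
        for j in range(m):
            if i != j and mf.total_transition_rate[i, j] > 0:
                g.add_edge(i, j, weight=float(mf.total_transition_rate[i, j]))
    return CellStateNetwork(mf, g)


def scc_condense(network: CellStateNetwork) -> tuple[list[tuple[int, ...]], nx.DiGraph]:
    """Partition the states into SCCs and return the acyclic condensation.

    SCCs are returned in a deterministic order (sorted by smallest member);
    the condensation's nodes are indices into that list.
    """
    sccs = [tuple(sorted(c)) for c in nx.strongly_connected_components(network.graph)]
    sccs.sort(key=lambda c: c[0])
    cond = nx.condensation(network.graph, scc=sccs)
    return sccs, cond


def dominant_eigenvalue(A_sub: np.ndarray) -> float:
    """Dominant (Perron) eigenvalue of a principal submatrix of ``A``.

    For an irreducible matrix with non-negative off-diagonal entries the
    eigenvalue of maximal real part is real and simple; it is returned as a
    real scalar.
    """
    A_sub = np.asarray(A_sub, dtype=float)
    if A_sub.ndim != 2 or A_sub.shape[0] != A_sub.shape[1]:
        raise ValueError("dominant_eigenvalue requires a square matrix")
    if A_sub.shape[0] == 1:
        return float(A_sub[0, 0])
    eig = np.linalg.eigvals(A_sub)
    return float(eig[np.argmax(eig.real)].real)


@dataclass(frozen=True)
class EffectiveRates:
    """Compartment-level effective rates (mean event frequencies).

    ``lambda_R`` — division rate of R-cells; ``omega_RC`` — direct R-to-C
    transition rate; ``gamma_R`` — direct R loss (zero in the standard
    compartment reduction, where R losses are routed through a short-lived
    committed state); ``r_RR``/``r_CC`` — probabilities that an R division yields two
    R (resp. two C) daughters; ``lambda_C``/``gamma_C`` — occupancy-weighted
    division and loss rates in C (``None`` when C is empty);
    ``lambda_hat_R = lambda_R / gamma_C`` controls the GIA Normal limit.
    """

    lambda_R: float
    r_RR: float
    r_CC: float
    omega_RC: float
    gamma_R: float
    lambda_C: float | None
    gamma_C: float | None
    lambda_hat_R: float | None
    note: str | None = None

    def as_dict(self) -> dict:
        return {
            "lambda_R": self.lambda_R,
            "r_RR": self.r_RR,
            "r_CC": self.r_CC,
            "omega_RC": self.omega_RC,
            "gamma_R": self.gamma_R,
            "lambda_C": self.lambda_C,
            "gamma_C": self.gamma_C,
            "lambda_hat_R": self.lambda_hat_R,
            "note": self.note,
        }


@dataclass(frozen=True)
class CompartmentDecomposition:
    """Full SCC/compartment analysis of one model."""

    model: CellFateModel
    mean_field: MeanFieldSystem
    network: CellStateNetwork
    sccs: list[tuple[int, ...]]
    condensation: nx.DiGraph
    mu: np.ndarray  # dominant eigenvalue per SCC
    verdict: str  # homeostatic | supercritical | subcritical | multiple_apexes
    reasons: tuple[str, ...]
    R_states: tuple[int, ...]
    C_states: tuple[int, ...]
    model_class: str | None  # "GIA" | "GPA" | None if not homeostatic
    stationary: np.ndarray | None  # n_bar*, R-compartment normalised to 1
    effective: EffectiveRates | None

    @property
    def homeostatic(self) -> bool:
        return self.verdict == "homeostatic"

    @property
    def R_labels(self) -> tuple[str, ...]:
        return tuple(self.model.states[i] for i in self.R_states)

    @property
    def C_labels(self) -> tuple[str, ...]:
        return tuple(self.model.states[i] for i in self.C_states)

    def report(self) -> dict:
        """JSON-serialisable decomposition report with stable key names."""
        return {
            "states": list(self.model.states),
            "sccs": [[self.model.states[i] for i in c] for c in self.sccs],
            "mu": [float(x) for x in self.mu],
            "verdict": self.verdict,
            "reasons": list(self.reasons),
            "R_states": list(self.R_labels),
            "C_states": list(self.C_labels),
            "model_class": self.model_class,
            "stationary": None if self.stationary is None else [float(x) for x in self.stationary],
            "effective_rates": None if self.effective is None else self.effective.as_dict(),
        }


def check_homeostasis(
    sccs: list[tuple[int, ...]],
    condensation: nx.DiGraph,
    mu: np.ndarray,
    tol: float = HOMEOSTASIS_TOL,
) -> tuple[str, tuple[str, ...]]:
    """Homeostasis verdict from the condensed network and per-SCC eigenvalues.

    Homeostatic iff the condensation has a unique source SCC (the apex) with
    ``|mu| <= tol`` while every other SCC has ``mu < -tol``.
    """
    sources = [k for k in condensation.nodes if condensation.in_degree(k) == 0]
    reasons: list[str] = []
    if len(sources) != 1:
        return "multiple_apexes", (f"{len(sources)} source SCCs in the condensation",)
    apex = sources[0]
    mu_apex = mu[apex]
    if mu_apex > tol:
        return "supercritical", (f"apex SCC has mu = {mu_apex:.3e} > 0",)
    if mu_apex < -tol:
        return "subcritical", (f"apex SCC has mu = {mu_apex:.3e} < 0",)
    bad = [k for k in condensation.nodes if k != apex and mu[k] >= -tol]
    if bad:
        growing = [k for k in bad if mu[k] > tol]
        verdict = "supercritical" if growing else "subcritical"
        return verdict, tuple(
            f"downstream SCC {sccs[k]} has mu = {mu[k]:.3e} >= 0" for k in bad
        )
    reasons.append(f"unique apex SCC with |mu| = {abs(mu_apex):.1e} <= {tol:g}")
    reasons.append("all downstream SCCs have mu < 0")
    return "homeostatic", tuple(reasons)


def _apex(condensation: nx.DiGraph) -> int:
    sources = [k for k in condensation.nodes if condensation.in_degree(k) == 0]
    if len(sources) != 1:
        raise NotHomeostaticError("condensation has no unique apex SCC")
    return sources[0]


def classify(model: CellFateModel, R_states: tuple[int, ...]) -> str:
    """Classify a homeostatic model as GIA or GPA.

    GIA iff every event with positive rate/probability leaves the R-cell
    count unchanged: every division of an R-state yields exactly one R
    daughter, no direct transition leaves R, and no R-state has a positive
    loss rate. (Divisions of C-states can never yield an R daughter: such an
    edge would merge the SCCs.)
    """
    R = set(R_states)
    for i in R:
        if model.loss_rate[i] > 0:
            return "GPA"
        for j in range(model.n_states):
            if j not in R and model.transition_rate[i, j] > 0:
                return "GPA"
        if model.division_rate[i] > 0:
            for j, k, p in model.daughter_pairs[i]:
                if p > 0 and (j in R) + (k in R) != 1:
                    return "GPA"
    return "GIA"


def stationary_mean_vector(
    mf: MeanFieldSystem,
    R_states: tuple[int, ...],
    tol: float = 1e-9,
) -> np.ndarray:
    """Non-negative stationary mean vector ``n_bar*`` with ``A n_bar* = 0``,
    normalised so the R-compartment sums to 1."""
    A = mf.A
    _, s, vt = np.linalg.svd(A)
    scale = max(s[0], 1.0)
    null_mask = s <= 1e-7 * scale
    if not null_mask.any():
        raise NotHomeostaticError("A has no null vector: not homeostatic")
    v = vt[-1]
    if v.sum() < 0:
        v = -v
    if (v < -1e-7 * max(abs(v).max(), 1e-300)).any():
        raise NotHomeostaticError("stationary vector is not non-negative")
    v = np.clip(v, 0.0, None)
    resid = np.abs(A @ v).max() / max(abs(v).max(), 1e-300)
    if resid > tol:
        raise NotHomeostaticError(f"stationary residual {resid:.2e} exceeds {tol:g}")
    r_sum = v[list(R_states)].sum()
    if r_sum <= 0:
        raise NotHomeostaticError("stationary vector has no mass in R")
    return v / r_sum


def effective_rates(
    model: CellFateModel,
    R_states: tuple[int, ...],
    C_states: tuple[int, ...],
    stationary: np.ndarray,
) -> EffectiveRates:
    """Compartment-level effective rates from the stationary occupancies.

    ``P_i^R = n_bar_i / sum_{j in R} n_bar_j`` (and analogously ``P_i^C``)
    weight the per-state rates:
    ``lambda_R = sum_{i in R} lambda_i P_i^R``,
    ``gamma_C = sum_{i in C} gamma_i P_i^C``,
    ``omega_RC = sum_{i in R, j in C} omega_ij P_i^R``; ``r_RR`` and ``r_CC``
    are division-rate-weighted probabilities of two-R (two-C) daughter pairs.
    """
    R = list(R_states)
    C = list(C_states)
    Rset = set(R)
    n = np.asarray(stationary, float)
    PR = n[R] / n[R].sum()
    lam = model.division_rate
    lambda_R = float(lam[R] @ PR)
    gamma_R = float(model.loss_rate[R] @ PR)
    omega_RC = float(sum(model.transition_rate[i, j] * PR[a] for a, i in enumerate(R) for j in C))
    rr = cc = 0.0
    for a, i in enumerate(R):
        if lam[i] <= 0:
            continue
        p_rr = sum(p for j, k, p in model.daughter_pairs[i] if j in Rset and k in Rset)
        p_cc = sum(p for j, k, p in model.daughter_pairs[i] if j not in Rset and k not in Rset)
        rr += lam[i] * PR[a] * p_rr
        cc += lam[i] * PR[a] * p_cc
    r_RR = rr / lambda_R if lambda_R > 0 else 0.0
    r_CC = cc / lambda_R if lambda_R > 0 else 0.0
    if not C:
        return EffectiveRates(
            lambda_R, r_RR, r_CC, omega_RC, gamma_R,
            lambda_C=None, gamma_C=None, lambda_hat_R=None,
            note="no committed compartment: gamma_C and lambda_hat_R undefined",
        )
    c_sum = n[C].sum()
    if c_sum <= 0:
        # homeostatic models always feed C; guard for degenerate inputs
        return EffectiveRates(
            lambda_R, r_RR, r_CC, omega_RC, gamma_R,
            lambda_C=None, gamma_C=None, lambda_hat_R=None,
            note="committed compartment unoccupied at stationarity",
        )
    PC = n[C] / c_sum
    lambda_C = float(lam[C] @ PC)
    gamma_C = float(model.loss_rate[C] @ PC)
    lhat = lambda_R / gamma_C if gamma_C > 0 else None
    return EffectiveRates(lambda_R, r_RR, r_CC, omega_RC, gamma_R, lambda_C, gamma_C, lhat)


def decompose(model: CellFateModel, tol: float = HOMEOSTASIS_TOL) -> CompartmentDecomposition:
    """Run the full pipeline: mean field, network, SCC condensation, per-SCC
    dominant eigenvalues, homeostasis verdict, R/C split, GIA/GPA class,
    stationary vector and effective rates."""
    mf = build_mean_field(model)
    net = build_network(mf)
    sccs, cond = scc_condense(net)
    mu = np.array([dominant_eigenvalue(mf.A[np.ix_(c, c)]) for c in sccs])
    verdict, reasons = check_homeostasis(sccs, cond, mu, tol)
    R_states: tuple[int, ...] = ()
    C_states: tuple[int, ...] = ()
    model_class = None
    stationary = None
    eff = None
    if verdict == "homeostatic":
        apex = _apex(cond)
        R_states = tuple(sccs[apex])
        C_states = tuple(i for i in range(model.n_states) if i not in sccs[apex])
        model_class = classify(model, R_states)
        stationary = stationary_mean_vector(mf, R_states)
        eff = effective_rates(model, R_states, C_states, stationary)
    return CompartmentDecomposition(
        model=model,
        mean_field=mf,
        network=net,
        sccs=sccs,
        condensation=cond,
        mu=mu,
        verdict=verdict,
        reasons=reasons,
        R_states=R_states,
        C_states=C_states,
        model_class=model_class,
        stationary=stationary,
        effective=eff,
    )
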