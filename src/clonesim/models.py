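"""Generic cell-fate models and their mean-field (linear ODE) representation.

A cell-fate model over ``m`` cell states ``X_1 .. X_m`` is a continuous-time
multi-type branching process with three event types per state:

* cell division ``X_i -> X_j + X_k`` at rate ``lambda_i``, with the daughter
  pair ``{X_j, X_k}`` drawn from a per-state probability distribution over
  unordered pairs;
* direct state change ``X_i -> X_j`` at rate ``omega_ij``;
* cell loss ``X_i -> 0`` (death, shedding or emigration) at rate ``gamma_i``.

The mean cell numbers ``n_bar`` obey the linear cooperative system
``d n_bar / dt = A n_bar`` where ``A`` combines the *total transition rates*
``kappa_ij = 2 lambda_i r_i^j + omega_ij`` (``r_i^j`` is the per-daughter
probability of producing a daughter in state ``X_j``) and the *local loss
rates* ``delta_i = lambda_i + sum_j omega_ij + gamma_i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CellFateModel",
    "MeanFieldSystem",
    "DaughterPair",
    "validate_model",
    "per_daughter_probability",
    "build_mean_field",
    "min_process_rate",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

#: tolerance on daughter-pair probability normalisation
PROB_TOL = 1e-12

# An unordered daughter pair is stored as (j, k, prob) with j <= k in the
# state order, removing the redundant ordered degree of freedom; the ordered
# probabilities are recovered by splitting ``prob`` evenly over orderings.
DaughterPair = tuple[int, int, float]


@dataclass(frozen=True)
class CellFateModel:
    """A generic stochastic cell-fate model.

    Parameters
    ----------
    states
        Ordered state labels; indices are derived from this order
        (0-based internally, reported 1-based as ``X_1..X_m``).
    division_rate
        Per-state division rates ``lambda_i >= 0``, shape ``(m,)``.
    daughter_pairs
        For each state, a tuple of ``(j, k, prob)`` with ``j <= k`` giving the
        distribution over unordered daughter pairs. Empty for non-dividing
        states; must sum to 1 for dividing ones.
    transition_rate
        Dense ``(m, m)`` matrix of direct transition rates ``omega_ij``
        (zero diagonal).
    loss_rate
        Per-state loss rates ``gamma_i >= 0``, shape ``(m,)``.
    """

    states: tuple[str, ...]
    division_rate: np.ndarray
    daughter_pairs: tuple[tuple[DaughterPair, ...], ...]
    transition_rate: np.ndarray
    loss_rate: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.states)
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        lam = np.asarray(self.division_rate, dtype=float).reshape(m)
        gam = np.asarray(self.loss_rate, dtype=float).reshape(m)
        om = np.asarray(self.transition_rate, dtype=float).reshape(m, m)
        pairs = tuple(
            tuple((int(j), int(k), float(p)) for j, k, p in self.daughter_pairs[i])
            for i in range(m)
        )
        object.__setattr__(self, "division_rate", lam)
        object.__setattr__(self, "loss_rate", gam)
        object.__setattr__(self, "transition_rate", om)
        object.__setattr__(self, "daughter_pairs", pairs)

    # -- basic introspection -------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellFateModel):
            return NotImplemented
        return (
            self.states == other.states
            and np.array_equal(self.division_rate, other.division_rate)
            and np.array_equal(self.transition_rate, other.transition_rate)
            and np.array_equal(self.loss_rate, other.loss_rate)
            and self.daughter_pairs == other.daughter_pairs
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays: hash on labels
        return hash(self.states)

    # -- convenience constructor --------------------------------------------

    @classmethod
    def build(
        cls,
        states: Sequence[str],
        divisions: Mapping[str, tuple[float, Iterable[tuple[Sequence[str], float]]]] | None = None,
        transitions: Iterable[tuple[str, str, float]] = (),
        losses: Mapping[str, float] | None = None,
    ) -> "CellFateModel":
        """Assemble a model from state labels.

        ``divisions`` maps a state label to ``(rate, [( (j_label, k_label), prob ), ...])``;
        ``transitions`` is an iterable of ``(from, to, rate)``; ``losses`` maps
        labels to loss rates. Unordered daughter pairs are canonicalised.
        """
        states = tuple(states)
        m = len(states)
        idx = {s: i for i, s in enumerate(states)}
        lam = np.zeros(m)
        gam = np.zeros(m)
        om = np.zeros((m, m))
        pairs: list[tuple[DaughterPair, ...]] = [() for _ in range(m)]
        for s, (rate, outcomes) in (divisions or {}).items():
            i = idx[s]
            lam[i] = rate
            acc: dict[tuple[int, int], float] = {}
            for pair, prob in outcomes:
                j, k = sorted(idx[lbl] for lbl in pair)
                acc[(j, k)] = acc.get((j, k), 0.0) + float(prob)
            pairs[i] = tuple((j, k, p) for (j, k), p in sorted(acc.items()))
        for a, b, rate in transitions:
            om[idx[a], idx[b]] = rate
        for s, rate in (losses or {}).items():
            gam[idx[s]] = rate
        return cls(states, lam, tuple(pairs), om, gam)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model(model: CellFateModel) -> list[str]:
    """Check the model invariants; return a list of human-readable violations.

    An empty list means the model is well formed: all rates are non-negative,
    dividing states carry a normalised daughter-pair distribution, and
    non-dividing states carry none.
    """
    issues: list[str] = []
    m = model.n_states
    labels = model.states
    for i in range(m):
        if model.division_rate[i] < 0:
            issues.append(f"state {labels[i]}: negative rate lambda = {model.division_rate[i]}")
        if model.loss_rate[i] < 0:
            issues.append(f"state {labels[i]}: negative rate gamma = {model.loss_rate[i]}")
    for i in range(m):
        for j in range(m):
            if i == j and model.transition_rate[i, j] != 0.0:
                issues.append(f"state {labels[i]}: self-transition omega must be absent")
            elif model.transition_rate[i, j] < 0:
                issues.append(
                    f"transition {labels[i]}->{labels[j]}: negative rate "
                    f"omega = {model.transition_rate[i, j]}"
                )
    for i in range(m):
        pp = model.daughter_pairs[i]
        for j, k, p in pp:
            if not (0 <= j <= k < m):
                issues.append(f"state {labels[i]}: daughter pair ({j},{k}) out of range or not canonical")
            if p < 0:
                issues.append(f"state {labels[i]}: negative daughter-pair probability {p}")
        if model.division_rate[i] > 0:
            total = sum(p for _, _, p in pp)
            if abs(total - 1.0) > PROB_TOL:
                issues.append(
                    f"state {labels[i]}: daughter probabilities sum {total!r} != 1"
                )
        elif pp:
            issues.append(f"state {labels[i]}: daughter pairs given but lambda = 0")
    return issues


def require_valid(model: CellFateModel) -> None:
    issues = validate_model(model)
    if issues:
        raise ValueError("invalid cell-fate model: " + "; ".join(issues))


# ---------------------------------------------------------------------------
# Mean-field construction
# ---------------------------------------------------------------------------

def _per_daughter_matrix(model: CellFateModel) -> np.ndarray:
    """Matrix ``r[i, j]`` = probability that a division of X_i yields a daughter
    in X_j. With unordered pairs this is prob * (multiplicity of j in pair) / 2,
    which equals the symmetrised average of the ordered-outcome probabilities."""
    m = model.n_states
    r = np.zeros((m, m))
    for i in range(m):
        for j, k, p in model.daughter_pairs[i]:
            r[i, j] += 0.5 * p
            r[i, k] += 0.5 * p
    return r


def per_daughter_probability(model: CellFateModel, i: str, j: str) -> float:
    """Probability ``r_i^j`` that a division of state ``i`` produces a daughter
    in state ``j``. Raises for non-dividing states."""
    ii, jj = model.index(i), model.index(j)
    if model.division_rate[ii] <= 0:
        raise ValueError(f"state {i!r} does not divide")
    return float(_per_daughter_matrix(model)[ii, jj])


@dataclass(frozen=True)
class MeanFieldSystem:
    """Linear system ``d n_bar/dt = A n_bar`` for the mean cell numbers."""

    model: CellFateModel
    per_daughter_prob: np.ndarray  # r[i, j]
    total_transition_rate: np.ndarray  # kappa[i, j]
    local_loss_rate: np.ndarray  # delta[i]
    A: np.ndarray

    @property
    def states(self) -> tuple[str, ...]:
        return self.model.states

    def mean_trajectory(self, n0: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Solve the mean-field ODE from initial mean vector ``n0``;
        returns shape ``(len(times), m)``."""
        from scipy.linalg import expm

        n0 = np.asarray(n0, dtype=float)
        return np.array([expm(self.A * float(t)) @ n0 for t in np.asarray(times, float)])


def build_mean_field(model: CellFateModel) -> MeanFieldSystem:
    """Construct kappa, delta and the matrix A governing the mean dynamics.

    ``A[j, i] = kappa_ij`` for ``i != j`` and ``A[i, i] = kappa_ii - delta_i``;
    every column ``i`` of ``A`` sums to ``lambda_i - gamma_i`` and all
    off-diagonal entries are non-negative (cooperative system).
    """
    require_valid(model)
    lam = model.division_rate
    r = _per_daughter_matrix(model)
    kappa = 2.0 * lam[:, None] * r + model.transition_rate
    delta = lam + model.transition_rate.sum(axis=1) + model.loss_rate
    A = kappa.T - np.diag(delta)
    return MeanFieldSystem(model, r, kappa, delta, A)


def min_process_rate(model: CellFateModel) -> float:
    """Minimal strictly positive process rate ``alpha_min`` over all
    ``lambda_i``, ``omega_ij`` and ``gamma_i``; zero rates denote absent
    processes and are excluded."""
    rates = np.concatenate(
        [model.division_rate, model.loss_rate, model.transition_rate.ravel()]
    )
    positive = rates[rates > 0]
    if positive.size == 0:
        raise ValueError("no active process: all rates are zero")
    return float(positive.min())


# ---------------------------------------------------------------------------
# Model schema (YAML/JSON dialect)
# ---------------------------------------------------------------------------

def model_to_dict(model: CellFateModel) -> dict:
    """Serialise to the model schema: ``states``, ``divisions`` (per state:
    ``rate`` plus ``{pair: [j, k], prob}`` entries), ``transitions`` and
    ``losses``. The mapping round-trips bit-exactly through
    :func:`model_from_dict`."""
    labels = model.states
    divisions = {}
    for i, s in enumerate(labels):
        if model.division_rate[i] == 0 and not model.daughter_pairs[i]:
            continue
        divisions[s] = {
            "rate": float(model.division_rate[i]),
            "pairs": [
                {"pair": [labels[j], labels[k]], "prob": p}
                for j, k, p in model.daughter_pairs[i]
            ],
        }
    transitions = [
        {"from": labels[i], "to": labels[j], "rate": float(model.transition_rate[i, j])}
        for i in range(model.n_states)
        for j in range(model.n_states)
        if model.transition_rate[i, j] != 0.0
    ]
    losses = {
        labels[i]: float(model.loss_rate[i])
        for i in range(model.n_states)
        if model.loss_rate[i] != 0.0
    }
    return {
        "states": list(labels),
        "divisions": divisions,
        "transitions": transitions,
        "losses": losses,
    }


def model_from_dict(data: Mapping) -> CellFateModel:
    divisions = {
        s: (
            spec["rate"],
            [((entry["pair"][0], entry["pair"][1]), entry["prob"]) for entry in spec.get("pairs", [])],
        )
        for s, spec in (data.get("divisions") or {}).items()
    }
    transitions = [
        (t["from"], t["to"], t["rate"]) for t in (data.get("transitions") or [])
    ]
    return CellFateModel.build(
        states=data["states"],
        divisions=divisions,
        transitions=transitions,
        losses=data.get("losses") or {},
    )


def save_model(model: CellFateModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> CellFateModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
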