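"""Exact stochastic simulation of clones (Gillespie direct method).

A clone is the progeny of a single initial cell; an ensemble is many
independent clones simulated from identical initial conditions. Counts are
recorded on a fixed checkpoint grid rather than per event, bounding memory.

Stopping rules follow the two conventions used for homeostatic models:
``gia_default`` runs to ``t_max = 20 / alpha_min`` (twenty times the slowest
process timescale, by which surviving-clone statistics of conserved models
have saturated), and ``gpa_default`` runs to the ensemble time at which a
pilot ensemble first reaches 98% clone extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._ssa import _run_ensemble
from .models import CellFateModel, min_process_rate, require_valid
from .network import CompartmentDecomposition

__all__ = [
    "StoppingRule",
    "CloneEnsemble",
    "RunawayPopulationError",
    "gillespie_clone",
    "gillespie_events",
    "simulate_ensemble",
    "resolve_stopping",
]

DEFAULT_MAX_CELLS = 1_000_000
DEFAULT_N_CHECKPOINTS = 50
_PILOT_STREAM = 0x5B11D  # keeps the pilot ensemble on its own RNG stream


class RunawayPopulationError(RuntimeError):
    """Population exceeded ``max_cells``; the input is likely not homeostatic."""


@dataclass(frozen=True)
class StoppingRule:
    """When to stop a clone simulation.

    ``mode`` is one of ``fixed_time`` (use ``t_max`` as given), ``gia_default``
    (``t_max = 20 / alpha_min``) or ``gpa_default`` (``t_max`` from the
    extinction quantile of a pilot ensemble).
    """

    mode: str = "fixed_time"
    t_max: float | None = None
    extinction_quantile: float = 0.98
    max_cells: int = DEFAULT_MAX_CELLS
    checkpoints: np.ndarray | None = None
    n_checkpoints: int = DEFAULT_N_CHECKPOINTS

    def grid(self) -> np.ndarray:
        """Checkpoint times: explicit grid if given, else ``n_checkpoints``
        log-spaced times ending exactly at ``t_max``."""
        if self.checkpoints is not None:
            g = np.asarray(self.checkpoints, dtype=float)
            if g.ndim != 1 or g.size == 0 or np.any(np.diff(g) <= 0):
                raise ValueError("checkpoints must be a strictly increasing 1-d grid")
            return g
        if self.t_max is None:
            raise ValueError(f"stopping rule {self.mode!r} not yet resolved to a t_max")
        return np.geomspace(self.t_max / 100.0, self.t_max, self.n_checkpoints)


def resolve_stopping(
    model: CellFateModel,
    decomp: CompartmentDecomposition,
    rule: StoppingRule,
    pilot_seed: int = 0,
    pilot_clones: int = 2000,
    initial_state: str | None = None,
) -> StoppingRule:
    """Resolve a stopping rule to a concrete ``t_max``.

    ``gia_default``: ``20 / alpha_min`` exactly. ``gpa_default``: the time by
    which the extinct fraction of a pilot ensemble (own RNG stream) first
    reaches ``extinction_quantile``; the pilot horizon starts at
    ``20 / alpha_min`` and doubles until enough clones have died.
    """
    if rule.mode == "fixed_time":
        if rule.t_max is None and rule.checkpoints is None:
            raise ValueError("fixed_time rule requires t_max or checkpoints")
        return rule
    alpha_min = min_process_rate(model)
    if rule.mode == "gia_default":
        return replace(rule, t_max=20.0 / alpha_min)
    if rule.mode != "gpa_default":
        raise ValueError(f"unknown stopping mode {rule.mode!r}")
    if decomp.model_class == "GIA":
        raise ValueError(
            "gpa_default stopping is undefined for GIA models: the renewing "
            "cell is conserved, so clones never go extinct"
        )
    if initial_state is None:
        initial_state = model.states[decomp.R_states[0]]
    need = int(np.ceil(rule.extinction_quantile * pilot_clones))
    horizon = 20.0 / alpha_min
    for _ in range(12):
        pilot = simulate_ensemble(
            model,
            pilot_clones,
            initial_state,
            StoppingRule("fixed_time", t_max=horizon, checkpoints=np.array([horizon]),
                         max_cells=rule.max_cells),
            seed=(_PILOT_STREAM, int(pilot_seed)),
        )
        ext = np.sort(pilot.extinction_time)
        if np.isfinite(ext[need - 1]):
            return replace(rule, t_max=float(ext[need - 1]))
        horizon *= 2.0
    raise RuntimeError(
        f"pilot ensemble did not reach {rule.extinction_quantile:.0%} extinction "
        f"within horizon {horizon:g}"
    )


@dataclass(frozen=True)
class CloneEnsemble:
    """Per-clone, per-checkpoint cell counts for one model.

    ``counts`` has shape ``(n_clones, n_checkpoints, m)``; ``extinction_time``
    is +inf for clones alive at the final checkpoint. Extinction is absorbing,
    so ``total`` is zero from the extinction checkpoint onwards.
    """

    model: CellFateModel
    times: np.ndarray
    counts: np.ndarray
    extinction_time: np.ndarray
    initial_state: str
    seed: object

    @property
    def n_clones(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> np.ndarray:
        """Total clone sizes, shape (n_clones, n_checkpoints)."""
        return self.counts.sum(axis=2)

    @property
    def surviving(self) -> np.ndarray:
        """Boolean survival flags per clone and checkpoint (n > 0)."""
        return self.total > 0

    def n_surviving(self, checkpoint: int = -1) -> int:
        return int(self.surviving[:, checkpoint].sum())

    def to_frame(self):
        """Long-format table: clone_id, time, state, count."""
        import pandas as pd

        n, T, m = self.counts.shape
        return pd.DataFrame(
            {
                "clone_id": np.repeat(np.arange(n), T * m),
                "time": np.tile(np.repeat(self.times, m), n),
                "state": np.tile(np.array(self.model.states), n * T),
                "count": self.counts.ravel(),
            }
        )


def _flatten_pairs(model: CellFateModel):
    m = model.n_states
    off = np.zeros(m, dtype=np.int64)
    cnt = np.zeros(m, dtype=np.int64)
    js: list[int] = []
    ks: list[int] = []
    cum: list[float] = []
    pos = 0
    for i in range(m):
        off[i] = pos
        pairs = model.daughter_pairs[i]
        cnt[i] = len(pairs)
        acc = 0.0
        for q, (j, k, p) in enumerate(pairs):
            acc += p
            js.append(j)
            ks.append(k)
            cum.append(acc if q < len(pairs) - 1 else 1.0)
        pos += len(pairs)
    return (
        off,
        cnt,
        np.array(js, dtype=np.int64),
        np.array(ks, dtype=np.int64),
        np.array(cum, dtype=np.float64),
    )


def _coerce_entropy(seed):
    """Allow named streams: strings become stable 64-bit digests."""
    if isinstance(seed, str):
        import hashlib

        return int.from_bytes(hashlib.sha256(seed.encode()).digest()[:8], "little")
    if isinstance(seed, (tuple, list)):
        return tuple(_coerce_entropy(s) for s in seed)
    return int(seed)


def _seed_matrix(seed, n_clones: int) -> np.ndarray:
    ss = np.random.SeedSequence(_coerce_entropy(seed))
    seeds = ss.generate_state(2 * n_clones, dtype=np.uint64).reshape(n_clones, 2)
    dead = (seeds == 0).all(axis=1)
    seeds[dead] = (0x9E3779B97F4A7C15, 0xBF58476D1CE4E5B9)  # xorshift needs a nonzero state
    return seeds


def simulate_ensemble(
    model: CellFateModel,
    n_clones: int,
    initial_state: str,
    stop: StoppingRule,
    seed,
) -> CloneEnsemble:
    """Simulate ``n_clones`` independent clones from one cell in
    ``initial_state``. Fully reproducible from ``seed`` (an int or a tuple,
    e.g. a named stream ``("pilot", 3)``)."""
    require_valid(model)
    times = stop.grid()
    lam = model.division_rate
    omega = model.transition_rate
    gamma = model.loss_rate
    a_state = lam + omega.sum(axis=1) + gamma
    off, cnt, pj, pk, pcum = _flatten_pairs(model)
    seeds = _seed_matrix(seed, n_clones)
    counts, ext, status = _run_ensemble(
        lam, gamma, omega, a_state,
        off, cnt, pj, pk, pcum,
        model.index(initial_state), times, n_clones, seeds,
        int(stop.max_cells),
    )
    if (status == 1).any():
        bad = int(np.argmax(status == 1))
        raise RunawayPopulationError(
            f"clone {bad} exceeded max_cells = {stop.max_cells}; "
            "the model is likely not homeostatic"
        )
    return CloneEnsemble(model, times, counts, ext, initial_state, seed)


def gillespie_clone(
    model: CellFateModel,
    initial_state: str,
    stop: StoppingRule,
    rng_seed,
) -> CloneEnsemble:
    """Single-clone convenience wrapper around :func:`simulate_ensemble`."""
    return simulate_ensemble(model, 1, initial_state, stop, rng_seed)


def gillespie_events(
    model: CellFateModel,
    initial_state: str,
    t_max: float,
    seed,
    max_events: int = 100_000,
    max_cells: int = DEFAULT_MAX_CELLS,
):
    """Event-resolved reference simulation (pure numpy, no checkpoint grid).

    Returns ``(event_times, counts)`` with ``counts`` of shape
    ``(n_events + 1, m)`` including the initial condition; used for exact
    per-event checks such as conservation laws.
    """
    require_valid(model)
    rng = np.random.default_rng(seed)
    m = model.n_states
    lam = model.division_rate
    omega = model.transition_rate
    gamma = model.loss_rate
    a_state = lam + omega.sum(axis=1) + gamma
    n = np.zeros(m, dtype=np.int64)
    n[model.index(initial_state)] = 1
    t = 0.0
    times = [0.0]
    history = [n.copy()]
    for _ in range(max_events):
        propensity = n * a_state
        R = propensity.sum()
        if R <= 0:
            break
        t += rng.exponential(1.0 / R)
        if t > t_max:
            break
        i = rng.choice(m, p=propensity / R)
        u = rng.random() * a_state[i]
        if u < lam[i]:
            pairs = model.daughter_pairs[i]
            probs = np.array([p for _, _, p in pairs])
            q = rng.choice(len(pairs), p=probs / probs.sum())
            j, k, _ = pairs[q]
            n[i] -= 1
            n[j] += 1
            n[k] += 1
        elif u < lam[i] + omega[i].sum():
            w = u - lam[i]
            j = int(np.searchsorted(np.cumsum(omega[i]), w, side="right"))
            n[i] -= 1
            n[j] += 1
        else:
            n[i] -= 1
        if n.sum() > max_cells:
            raise RunawayPopulationError("runaway population in event-resolved run")
        times.append(t)
        history.append(n.copy())
        if n.sum() == 0:
            break
    return np.array(times), np.array(history)
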