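"""Canonical fixtures and random generation of homeostatic cell-fate models.

Canonical models
----------------
``IA``/``PA``  — the classical stem/differentiated two-type strategies: S
divides at rate ``lam`` into S+S, S+D or D+D with probabilities ``r``,
``1-2r``, ``r`` (IA is the ``r = 0`` case); D is lost at rate ``gamma``.

``DH``         — dynamic heterogeneity: only asymmetric S -> S+D divisions,
with reversible switching S <-> D. The switching rate named ``omega_S`` is
the D -> S rate and ``omega_D`` the S -> D rate; with this convention the
homeostatic balance reads ``gamma/lam = omega_S/omega_D``.

``GIA0``       — the two-state GIA chain (conserved X1 feeding an
ephemeral X2); ``GPA2`` — its population-asymmetry counterpart with
symmetric X1 divisions and direct X1 -> X2 transitions; ``GIAB`` — a GIA
model with two renewing states A, B connected by slow direct switching,
each dividing asymmetrically into a committed state (the bimodal test case).

Random generation
-----------------
The random generator is this package's own procedure: it samples an apex
SCC topology (a cycle through the renewing states plus density-controlled
extra edges) and a downstream DAG of committed states ending in loss, draws
all rates i.i.d. Uniform(rate range), and — for GPA targets — tunes a single
multiplier on all transition outflows from the renewing compartment until
the apex dominant eigenvalue is zero (the eigenvalue is strictly decreasing
in that multiplier, so a bracketed root-find converges to machine
precision). GIA targets are homeostatic at the apex by construction, since
every renewing-state division is fixed to yield exactly one renewing
daughter; only the committed side needs its loss rates set above its
division rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .models import CellFateModel
from .network import (
    HOMEOSTASIS_TOL,
    CompartmentDecomposition,
    decompose,
    dominant_eigenvalue,
)

__all__ = [
    "GeneratorConfig",
    "canonical",
    "random_homeostatic",
    "rescale_renewing",
]

_CONSTRAINT_TOL = 1e-9


def _check(condition: bool, identity: str) -> None:
    if not condition:
        raise ValueError(f"homeostasis constraint violated: {identity}")


def canonical(name: str, **params) -> CellFateModel:
    """Build a named canonical model; parameter sets violating the fixture's
    homeostasis constraint are rejected with the violated identity named."""
    name = name.upper()
    if name == "IA":
        return canonical("PA", lam=params["lam"], r=0.0, gamma=params["gamma"])
    if name == "PA":
        lam, r, gamma = params["lam"], params["r"], params["gamma"]
        _check(0.0 <= r <= 0.5, f"0 <= r <= 1/2 (got r = {r})")
        outcomes = [((("S", "D")), 1.0 - 2.0 * r)]
        if r > 0:
            outcomes += [((("S", "S")), r), ((("D", "D")), r)]
        return CellFateModel.build(
            states=("S", "D"),
            divisions={"S": (lam, outcomes)},
            losses={"D": gamma},
        )
    if name == "DH":
        lam, omega_S, omega_D, gamma = (
            params["lam"], params["omega_S"], params["omega_D"], params["gamma"],
        )
        _check(
            abs(gamma * omega_D - lam * omega_S) <= _CONSTRAINT_TOL * max(gamma * omega_D, lam * omega_S),
            f"gamma/lam = omega_S/omega_D (got {gamma / lam:g} vs {omega_S / omega_D:g})",
        )
        return CellFateModel.build(
            states=("S", "D"),
            divisions={"S": (lam, [(("S", "D"), 1.0)])},
            transitions=[("S", "D", omega_D), ("D", "S", omega_S)],
            losses={"D": gamma},
        )
    if name == "GIA0":
        lam1, lam2, gamma = params["lam1"], params["lam2"], params["gamma"]
        _check(lam2 < gamma, f"lam2 < gamma (got {lam2} >= {gamma})")
        divisions = {"X1": (lam1, [(("X1", "X2"), 1.0)])}
        if lam2 > 0:
            divisions["X2"] = (lam2, [(("X2", "X2"), 1.0)])
        return CellFateModel.build(
            states=("X1", "X2"), divisions=divisions, losses={"X2": gamma},
        )
    if name == "GPA2":
        lam1, r1, r2, omega, lam2, gamma = (
            params["lam1"], params["r1"], params["r2"],
            params["omega"], params["lam2"], params["gamma"],
        )
        _check(lam2 < gamma, f"lam2 < gamma (got {lam2} >= {gamma})")
        _check(
            abs(lam1 * r1 - lam1 * r2 - omega) <= _CONSTRAINT_TOL,
            f"lam1*r1 = lam1*r2 + omega (got {lam1 * r1:g} vs {lam1 * r2 + omega:g})",
        )
        outcomes = [(("X1", "X1"), r1), (("X1", "X2"), 1.0 - r1 - r2), (("X2", "X2"), r2)]
        divisions = {"X1": (lam1, [(p, w) for p, w in outcomes if w > 0])}
        if lam2 > 0:
            divisions["X2"] = (lam2, [(("X2", "X2"), 1.0)])
        transitions = [("X1", "X2", omega)] if omega > 0 else []
        return CellFateModel.build(
            states=("X1", "X2"), divisions=divisions, transitions=transitions,
            losses={"X2": gamma},
        )
    if name == "GIAB":
        lam_a, lam_b = params["lam_a"], params["lam_b"]
        omega_ab, omega_ba = params["omega_ab"], params["omega_ba"]
        gamma = params["gamma"]
        lam_c = params.get("lam_c", 0.0)
        _check(lam_c < gamma, f"lam_c < gamma (got {lam_c} >= {gamma})")
        _check(omega_ab > 0 and omega_ba > 0, "omega_ab, omega_ba > 0 (A and B must form one SCC)")
        divisions = {
            "A": (lam_a, [(("A", "C"), 1.0)]),
            "B": (lam_b, [(("B", "C"), 1.0)]),
        }
        if lam_c > 0:
            divisions["C"] = (lam_c, [(("C", "C"), 1.0)])
        return CellFateModel.build(
            states=("A", "B", "C"),
            divisions=divisions,
            transitions=[("A", "B", omega_ab), ("B", "A", omega_ba)],
            losses={"C": gamma},
        )
    raise ValueError(f"unknown canonical model {name!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the random-model generator.

    ``n_states = None`` draws m uniformly from [3, 8]. Rates are i.i.d.
    Uniform(rate_low, rate_high); ``density`` controls extra network edges
    beyond the backbone. ``lambda_hat_target`` applies a final renewing-side
    rescaling so that ``lambda_R / gamma_C`` hits the target.
    """

    seed: int
    class_target: str = "GPA"
    n_states: int | None = None
    density: float = 0.5
    rate_low: float = 0.1
    rate_high: float = 1.0
    lambda_hat_target: float | None = None
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.class_target not in ("GIA", "GPA"):
            raise ValueError("class_target must be 'GIA' or 'GPA'")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if not (0 < self.rate_low <= self.rate_high):
            raise ValueError("rate range must be strictly positive")
        if self.n_states is not None and self.n_states < 2:
            raise ValueError("need at least 2 states (a renewing and a committed one)")


def _uniform(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    return float(rng.uniform(cfg.rate_low, cfg.rate_high))


def _sample_structure(cfg: GeneratorConfig, attempt: int):
    """Draw topology and rates; return the raw ingredients plus the list of
    tunable outflow transitions (for GPA targets)."""
    rng_topo = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0, attempt)))
    rng_rate = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1, attempt)))
    m = cfg.n_states or int(rng_topo.integers(3, 9))
    n_R = int(rng_topo.integers(1, m))
    R = list(range(n_R))
    C = list(range(n_R, m))
    states = [f"X{i + 1}" for i in range(m)]
    gia = cfg.class_target == "GIA"

    transitions: list[tuple[int, int, float]] = []
    outflow: list[tuple[int, int, float]] = []  # (from R, to C, base rate); scaled later
    divisions: dict[int, tuple[float, list[tuple[tuple[int, int], float]]]] = {}
    losses: dict[int, float] = {}

    # renewing backbone: a cycle through R plus density-controlled extras
    if n_R > 1:
        order = list(rng_topo.permutation(R))
        for a, b in zip(order, order[1:] + order[:1]):
            transitions.append((a, b, _uniform(rng_rate, cfg)))
        for a in R:
            for b in R:
                if a != b and rng_topo.random() < cfg.density * 0.3:
                    transitions.append((a, b, _uniform(rng_rate, cfg)))

    # renewing divisions
    for i in R:
        lam = _uniform(rng_rate, cfg)
        if gia:
            # every division yields exactly one renewing daughter
            n_out = 1 + int(rng_topo.random() < cfg.density)
            probs = rng_rate.dirichlet(np.ones(n_out))
            outs = []
            for q in range(n_out):
                rj = int(rng_topo.choice(R))
                ck = int(rng_topo.choice(C))
                outs.append(((rj, ck), float(probs[q])))
            divisions[i] = (lam, outs)
        else:
            # symmetric renewal must outweigh symmetric commitment so the
            # untuned apex grows (mu(0) > 0); the outflow multiplier then
            # brings it down to exactly zero
            p_cc = float(rng_rate.uniform(0.05, 0.25))
            p_rr = p_cc + float(rng_rate.uniform(0.1, 0.5))
            p_rc = 1.0 - p_rr - p_cc
            rr = (int(rng_topo.choice(R)), int(rng_topo.choice(R)))
            rc = (int(rng_topo.choice(R)), int(rng_topo.choice(C)))
            cc = (int(rng_topo.choice(C)), int(rng_topo.choice(C)))
            divisions[i] = (lam, [(rr, p_rr), (rc, p_rc), (cc, p_cc)])
        if not gia:
            outflow.append((i, int(rng_topo.choice(C)), _uniform(rng_rate, cfg)))

    # committed DAG: optional duplication divisions, forward transitions,
    # and losses exceeding the local division rate
    c_omega_out: dict[int, float] = {j: 0.0 for j in C}
    for a_pos, a in enumerate(C):
        for b in C[a_pos + 1:]:
            if rng_topo.random() < cfg.density * 0.5:
                w = _uniform(rng_rate, cfg)
                transitions.append((a, b, w))
                c_omega_out[a] += w
    for j in C:
        lam_c = _uniform(rng_rate, cfg) if rng_topo.random() < 0.6 else 0.0
        if lam_c > 0:
            divisions[j] = (lam_c, [((j, j), 1.0)])
        losses[j] = lam_c + _uniform(rng_rate, cfg)

    # every committed state must be reachable from the renewing compartment;
    # unreached ones get a feed from a reachable earlier node
    def _reachable() -> set[int]:
        adj: dict[int, set[int]] = {i: set() for i in range(m)}
        for i, (lam, outs) in divisions.items():
            for (j, k), p in outs:
                if p > 0:
                    adj[i].update((j, k))
        for a, b, w in transitions:
            adj[a].add(b)
        for a, b, w in outflow:
            adj[a].add(b)
        seen = set(R)
        stack = list(R)
        while stack:
            for b in adj[stack.pop()]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        return seen

    for pos, j in enumerate(C):
        reach = _reachable()
        if j in reach:
            continue
        earlier = [c for c in C[:pos] if c in reach]
        if earlier and rng_topo.random() < 0.5:
            src = int(rng_topo.choice(earlier))
            w = _uniform(rng_rate, cfg)
            transitions.append((src, j, w))
            losses[src] = losses[src] + w  # keep the source strictly subcritical
        elif gia:
            # GIA forbids direct R -> C transitions; feed via a division route
            i = int(rng_topo.choice(R))
            lam, outs = divisions[i]
            outs = [(pair, p * 0.8) for pair, p in outs]
            outs.append(((int(rng_topo.choice(R)), j), 0.2))
            divisions[i] = (lam, outs)
        else:
            outflow.append((int(rng_topo.choice(R)), j, _uniform(rng_rate, cfg)))

    return states, R, C, divisions, transitions, outflow, losses


def _assemble(states, divisions, transitions, outflow, losses, theta: float) -> CellFateModel:
    div = {
        states[i]: (lam, [((states[j], states[k]), p) for (j, k), p in outs])
        for i, (lam, outs) in divisions.items()
    }
    trans = [(states[a], states[b], w) for a, b, w in transitions]
    trans += [(states[a], states[b], theta * w) for a, b, w in outflow]
    loss = {states[j]: g for j, g in losses.items()}
    return CellFateModel.build(states=states, divisions=div, transitions=trans, losses=loss)


def _mu_apex(model: CellFateModel, R: list[int]) -> float:
    from .models import build_mean_field

    A = build_mean_field(model).A
    return dominant_eigenvalue(A[np.ix_(R, R)])


def random_homeostatic(
    config: GeneratorConfig,
) -> tuple[CellFateModel, CompartmentDecomposition]:
    """Generate a random homeostatic model of the requested class.

    Fully reproducible from ``config.seed``; raises with a diagnostic if no
    attempt within ``max_retries`` passes the homeostasis certificate.
    """
    last_error: Exception | None = None
    for attempt in range(config.max_retries):
        states, R, C, divisions, transitions, outflow, losses = _sample_structure(
            config, attempt
        )
        try:
            if config.class_target == "GPA":
                def mu_of(theta: float) -> float:
                    return _mu_apex(
                        _assemble(states, divisions, transitions, outflow, losses, theta), R
                    )

                if mu_of(0.0) <= HOMEOSTASIS_TOL:
                    raise RuntimeError("apex not supercritical at zero outflow; resampling")
                hi = 1.0
                while mu_of(hi) > 0.0:
                    hi *= 2.0
                    if hi > 1e6:
                        raise RuntimeError("could not bracket the homeostatic outflow")
                theta = brentq(mu_of, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
                model = _assemble(states, divisions, transitions, outflow, losses, theta)
            else:
                model = _assemble(states, divisions, transitions, outflow, losses, 0.0)
            decomp = decompose(model)
            if not decomp.homeostatic:
                raise RuntimeError(
                    f"decomposition verdict {decomp.verdict}: {decomp.reasons}"
                )
            if decomp.model_class != config.class_target:
                raise RuntimeError(
                    f"generated class {decomp.model_class} != target {config.class_target}"
                )
            if config.lambda_hat_target is not None:
                eff = decomp.effective
                if eff is None or eff.lambda_hat_R is None:
                    raise RuntimeError("lambda_hat_R undefined for generated model")
                model = rescale_renewing(
                    model, config.lambda_hat_target / eff.lambda_hat_R, decomp
                )
                decomp = decompose(model)
            return model, decomp
        except RuntimeError as exc:
            last_error = exc
    raise RuntimeError(
        f"random_homeostatic failed after {config.max_retries} attempts "
        f"(seed {config.seed}, target {config.class_target}): {last_error}"
    )


def rescale_renewing(
    model: CellFateModel,
    factor: float,
    decomp: CompartmentDecomposition | None = None,
) -> CellFateModel:
    """Multiply every rate attached to renewing states (division, outgoing
    transitions, loss) by ``factor``. Homeostasis is preserved — the apex
    block of A simply scales — and ``lambda_hat_R`` scales by ``factor``."""
    if factor <= 0:
        raise ValueError("rescaling factor must be positive")
    if decomp is None:
        decomp = decompose(model)
    if not decomp.homeostatic:
        raise ValueError("rescale_renewing requires a homeostatic model")
    R = list(decomp.R_states)
    lam = model.division_rate.copy()
    omega = model.transition_rate.copy()
    gamma = model.loss_rate.copy()
    lam[R] *= factor
    omega[R, :] *= factor
    gamma[R] *= factor
    return CellFateModel(model.states, lam, model.daughter_pairs, omega, gamma)
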