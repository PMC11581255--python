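"""Boosted hawk/shepherd hybrid metaheuristic for bounded black-box search.

The optimizer is a Harris Hawks Optimization (HHO) variant with three
modifications:

* the random reference hawk of the exploration step is replaced by the
  mean of the best, worst and current positions ("boosted" reference);
* the escape energy is modulated by a chaotic multiplier drawn from a
  logistic map, ``Eg = 2 C Eg0 (1 - t/t*)``;
* after a plain hard besiege the hawk takes an extra shepherd-style
  step toward the best solution plus a Mantegna Levy flight, accepted
  greedily.

Exploration applies while ``|Eg| >= 1``; otherwise one of four besiege
strategies is chosen by ``(|Eg|, r)`` with ``r ~ U(0,1)``: soft
(``|Eg| >= 0.5, r >= 0.5``), hard (``< 0.5, >= 0.5``), and the two
progressive-quick-dive variants for ``r < 0.5``.  All candidate
positions are clamped to the box ``[lb, ub]`` before evaluation; runs
are fully reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# chaotic escape energy


def logistic_step(phi: float, a: float) -> float:
    """One step of the logistic map ``phi -> a phi (1 - phi)``.

    Chaotic for ``a = 4``; stays inside [0, 1] for ``a in (0, 4]``.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if not 0.0 < a <= 4.0:
        raise ValueError("logistic parameter a must lie in (0, 4]")
    return a * phi * (1.0 - phi)


def escape_energy(eg0: float, c: float, t: int, t_max: int) -> float:
    """Escape energy ``Eg = 2 C Eg0 (1 - t/t_max)``.

    Decays linearly to zero over the run; ``C`` injects chaotic
    iteration-to-iteration variation.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    return 2.0 * c * eg0 * (1.0 - t / t_max)


# ---------------------------------------------------------------------------
# Levy flight (Mantegna)


def levy_sigma(gamma: float) -> float:
    """Mantegna scale ``sigma`` for a Levy-stable step of index ``gamma``.

    ``sigma = [Gamma(1+g) sin(pi g/2) / (Gamma((1+g)/2) g 2^((g-1)/2))]^(1/g)``.
    For ``gamma = 1`` every factor is 1, so ``sigma = 1`` exactly.
    """
    if not 0.0 < gamma <= 2.0:
        raise ValueError("gamma must lie in (0, 2]")
    num = math.gamma(1.0 + gamma) * math.sin(math.pi * gamma / 2.0)
    den = math.gamma((1.0 + gamma) / 2.0) * gamma * 2.0 ** ((gamma - 1.0) / 2.0)
    return (num / den) ** (1.0 / gamma)


#: Step-length multiplier applied to raw Mantegna draws so Levy jumps
#: stay commensurate with unit-scale search boxes.
LEVY_SCALE = 0.01


def levy_flight(dim: int, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed random step: ``0.01 * l * sigma / |m|^(1/gamma)``
    with ``l, m`` standard normal (Mantegna's algorithm)."""
    sigma = levy_sigma(gamma)
    l = rng.standard_normal(dim)
    m = rng.standard_normal(dim)
    return LEVY_SCALE * l * sigma / np.abs(m) ** (1.0 / gamma)


# ---------------------------------------------------------------------------
# position updates


def boosted_srand(best: np.ndarray, worst: np.ndarray,
                  current: np.ndarray) -> np.ndarray:
    """Boosted reference position: mean of best, worst and current."""
    best, worst, current = map(np.asarray, (best, worst, current))
    if not best.shape == worst.shape == current.shape:
        raise ValueError("best/worst/current must have equal dimensions")
    return (best + worst + current) / 3.0


def explore_step(position: np.ndarray, prey: np.ndarray, mean: np.ndarray,
                 srand: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Exploration move (perching on the boosted reference or relative
    to prey and flock mean), clamped to bounds."""
    q, r1, r2, r3, r4 = rng.uniform(size=5)
    if q >= 0.5:
        new = srand - r1 * np.abs(srand - 2.0 * r2 * position)
    else:
        u = r3 * (lb + r4 * (ub - lb))
        new = (prey - mean) - u
    return np.clip(new, lb, ub)


def soft_besiege(position: np.ndarray, prey: np.ndarray, eg: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Soft besiege: ``dS - Eg |Jp*prey - S|`` with ``Jp = 2(1 - r5)``."""
    jp = 2.0 * (1.0 - rng.uniform())
    ds = prey - position
    return ds - eg * np.abs(jp * prey - position)


def hard_besiege(position: np.ndarray, prey: np.ndarray, eg: float) -> np.ndarray:
    """Hard besiege: ``prey - Eg |prey - S|``."""
    return prey - eg * np.abs(prey - position)


def ssoa_step(position: np.ndarray, prey: np.ndarray, gamma: float,
              rng: np.random.Generator) -> np.ndarray:
    """Shepherd-style boost: best + attraction step + Levy flight.

    ``S_new = S_best + r (S_prey - S_i) + Levy(gamma)`` with ``r``
    uniform elementwise; the caller accepts the candidate greedily.
    """
    r = rng.uniform(size=position.shape)
    return prey + r * (prey - position) + levy_flight(position.size, gamma, rng)


def _dive_pair(base_ref: np.ndarray, position: np.ndarray, prey: np.ndarray,
               eg: float, gamma: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    jp = 2.0 * (1.0 - rng.uniform())
    u = prey - eg * np.abs(jp * prey - base_ref)
    q = rng.uniform(size=position.shape)
    v = u + q * levy_flight(position.size, gamma, rng)
    return u, v


def soft_besiege_dives(position, prey, eg, gamma, rng):
    """Soft besiege with progressive quick dives: candidates U (direct
    dive) and V (U plus Levy team dive)."""
    return _dive_pair(position, position, prey, eg, gamma, rng)


def hard_besiege_dives(position, prey, mean, eg, gamma, rng):
    """Hard besiege with progressive quick dives; the direct dive is
    taken relative to the flock mean position."""
    return _dive_pair(mean, position, prey, eg, gamma, rng)


# ---------------------------------------------------------------------------
# driver


@dataclass
class OptimizerConfig:
    """Run parameters for :func:`optimize`.

    ``sense`` selects minimization (canonical internal sense) or
    maximization (objective negated at the boundary).
    """

    n_hawks: int = 30
    n_iter: int = 100
    lb: np.ndarray | float = -1.0
    ub: np.ndarray | float = 1.0
    dim: int | None = None
    gamma: float = 1.5
    logistic_a: float = 4.0
    phi0: float = 0.7
    seed: int = 0
    sense: str = "minimize"

    def __post_init__(self) -> None:
        if self.n_hawks < 2:
            raise ValueError("need at least 2 hawks")
        if self.n_iter < 1:
            raise ValueError("need at least 1 iteration")
        if self.sense not in ("minimize", "maximize"):
            raise ValueError("sense must be 'minimize' or 'maximize'")
        lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.dim is not None:
            lb = np.broadcast_to(lb, (self.dim,)).copy()
            ub = np.broadcast_to(ub, (self.dim,)).copy()
        elif lb.size != ub.size:
            lb, ub = np.broadcast_arrays(lb, ub)
            lb, ub = lb.copy(), ub.copy()
        if not np.all(lb < ub):
            raise ValueError("lb must be strictly below ub componentwise")
        self.lb, self.ub = lb, ub
        self.dim = lb.size


@dataclass
class OptimizerResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[dict] = field(default_factory=list)
    n_rejected_nonfinite: int = 0


def optimize(objective, config: OptimizerConfig,
             init_positions=None) -> OptimizerResult:
    """Run the hawk/shepherd hybrid on a bounded objective.

    ``objective`` maps a position vector in ``[lb, ub]`` to a scalar.
    Non-finite objective values are treated as infinitely bad (the
    candidate is rejected and counted).  ``init_positions`` optionally
    warm-starts the population: the given rows (clamped to bounds)
    replace the first hawks, so a known incumbent is always part of the
    search.  The returned history holds the best and mean fitness per
    iteration in the caller's sense; the best-so-far trace is monotone.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sign = 1.0 if cfg.sense == "minimize" else -1.0

    n_rejected = 0

    def f(x: np.ndarray) -> float:
        nonlocal n_rejected
        val = objective(x)
        val = sign * float(val)
        if not np.isfinite(val):
            n_rejected += 1
            return np.inf
        return val

    lb, ub = cfg.lb, cfg.ub
    positions = rng.uniform(lb, ub, size=(cfg.n_hawks, cfg.dim))
    if init_positions is not None:
        init = np.clip(np.atleast_2d(np.asarray(init_positions, dtype=float)),
                       lb, ub)
        positions[:min(len(init), cfg.n_hawks)] = init[:cfg.n_hawks]
    fitness = np.array([f(p) for p in positions])

    best_i = int(np.argmin(fitness))
    prey = positions[best_i].copy()
    prey_fit = float(fitness[best_i])

    phi = cfg.phi0
    history: list[dict] = []

    for t in range(cfg.n_iter):
        phi = logistic_step(phi, cfg.logistic_a)  # chaotic multiplier C
        mean_pos = positions.mean(axis=0)
        worst = positions[int(np.argmax(fitness))].copy()

        for i in range(cfg.n_hawks):
            pos = positions[i]
            eg0 = rng.uniform(-1.0, 1.0)
            eg = escape_energy(eg0, phi, t, cfg.n_iter)

            if abs(eg) >= 1.0:
                srand = boosted_srand(prey, worst, pos)
                cand = explore_step(pos, prey, mean_pos, srand, lb, ub, rng)
                positions[i] = cand
                fitness[i] = f(cand)
            else:
                r = rng.uniform()
                if r >= 0.5 and abs(eg) >= 0.5:
                    cand = np.clip(soft_besiege(pos, prey, eg, rng), lb, ub)
                    positions[i] = cand
                    fitness[i] = f(cand)
                elif r >= 0.5:
                    cand = np.clip(hard_besiege(pos, prey, eg), lb, ub)
                    positions[i] = cand
                    fitness[i] = f(cand)
                    # shepherd-style boosted post-step, greedy acceptance
                    boost = np.clip(ssoa_step(positions[i], prey, cfg.gamma,
                                              rng), lb, ub)
                    boost_fit = f(boost)
                    if boost_fit < fitness[i]:
                        positions[i] = boost
                        fitness[i] = boost_fit
                else:
                    if abs(eg) >= 0.5:
                        u, v = soft_besiege_dives(pos, prey, eg, cfg.gamma, rng)
                    else:
                        u, v = hard_besiege_dives(pos, prey, mean_pos, eg,
                                                  cfg.gamma, rng)
                    u = np.clip(u, lb, ub)
                    fu = f(u)
                    if fu < fitness[i]:
                        positions[i] = u
                        fitness[i] = fu
                    else:
                        v = np.clip(v, lb, ub)
                        fv = f(v)
                        if fv < fitness[i]:
                            positions[i] = v
                            fitness[i] = fv

            if fitness[i] < prey_fit:  # ties keep the incumbent
                prey_fit = float(fitness[i])
                prey = positions[i].copy()

        finite = fitness[np.isfinite(fitness)]
        history.append({
            "iteration": t,
            "best_fitness": sign * prey_fit,
            "mean_fitness": sign * float(finite.mean()) if finite.size else float("nan"),
        })

    return OptimizerResult(best_position=prey, best_fitness=sign * prey_fit,
                           history=history, n_rejected_nonfinite=n_rejected)


def history_to_csv(history: list[dict], path) -> None:
    """Write a convergence trace as CSV (iteration, best, mean)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["iteration", "best_fitness", "mean_fitness"])
        writer.writeheader()
        writer.writerows(history)
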