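"""Particle-swarm optimization of the four panel-selection hyperparameters.

Each particle is a point in the 4-D box (libsize-correlation floor, FDR
threshold, label-correlation floor, ranked-transcript count); its fitness is
the ROC-AUC, on the evaluation series, of the panel built from the training
series at that setting.  The update is the standard inertia-weight rule

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x);  x <- clamp(x + v)

with w = 0.72, c1 = c2 = 1.49, zero initial velocities and box clamping.
The ranked-count dimension flies as a continuous value and is rounded only
at evaluation time.  One particle is pinned to a documented default setting
so the swarm can never end below the default's fitness; ties for the global
best keep the earliest-found particle, making the whole search deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ParamBounds
from .panel import BiomarkerPanel, ParticleParams, build_panel, tep_score

__all__ = ["SwarmState", "init_swarm", "step", "optimize", "OptimizeResult"]

INERTIA = 0.72
COGNITIVE = 1.49
SOCIAL = 1.49


@dataclass
class SwarmState:
    bounds: np.ndarray  # (d, 2)
    positions: np.ndarray  # (n, d)
    velocities: np.ndarray  # (n, d)
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    gbest_pos: np.ndarray | None
    gbest_fit: float
    iteration: int
    rng: np.random.Generator
    int_dims: tuple[int, ...] = ()
    trace: list = field(default_factory=list)  # (iteration, particle, position, fitness)

    def eval_position(self, i: int) -> np.ndarray:
        """Particle position as evaluated (integer dims rounded)."""
        x = self.positions[i].copy()
        for d in self.int_dims:
            x[d] = np.clip(round(x[d]), self.bounds[d, 0], self.bounds[d, 1])
        return x


def _vec_to_params(x: np.ndarray) -> ParticleParams:
    return ParticleParams(
        libsize_cor_lo=float(x[0]),
        fdr_threshold=float(x[1]),
        cor_threshold=float(x[2]),
        n_ranked=int(round(x[3])),
    )


def _params_to_vec(p: ParticleParams) -> np.ndarray:
    return np.array(
        [p.libsize_cor_lo, p.fdr_threshold, p.cor_threshold, float(p.n_ranked)]
    )


def init_swarm(
    bounds: np.ndarray | ParamBounds,
    n_particles: int,
    seed: int | np.random.Generator = 0,
    pinned: np.ndarray | None = None,
    int_dims: tuple[int, ...] = (),
) -> SwarmState:
    """Uniform in-bounds positions, zero velocities; particle 0 is pinned.

    For the 4-D panel search pass a :class:`ParamBounds`; the pinned
    particle then defaults to (FDR 0.05, floor -0.1, correlation 0.5,
    top min(1000, n_detected)) and the ranked dimension is integral.
    """
    if isinstance(bounds, ParamBounds):
        if pinned is None:
            pinned = _params_to_vec(ParticleParams.default(int(bounds.n_ranked[1])))
        int_dims = (3,)
        bounds = bounds.as_array()
    bounds = np.asarray(bounds, dtype=float)
    if n_particles < 1:
        raise ValueError("need at least 1 particle")
    if np.all(bounds[:, 0] == bounds[:, 1]):
        import warnings

        warnings.warn("degenerate bounds: all particles identical", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = bounds.shape[0]
    pos = bounds[:, 0] + rng.random((n_particles, d)) * (bounds[:, 1] - bounds[:, 0])
    if pinned is not None:
        pos[0] = np.clip(pinned, bounds[:, 0], bounds[:, 1])
    for k in int_dims:
        pos[:, k] = np.clip(np.round(pos[:, k]), bounds[k, 0], bounds[k, 1])
    n = n_particles
    return SwarmState(
        bounds=bounds,
        positions=pos,
        velocities=np.zeros_like(pos),
        pbest_pos=pos.copy(),
        pbest_fit=np.full(n, -np.inf),
        gbest_pos=None,
        gbest_fit=-np.inf,
        iteration=0,
        rng=rng,
        int_dims=tuple(int_dims),
    )


def _evaluate_and_update_bests(state: SwarmState, fitness_fn, check_unit: bool) -> None:
    for i in range(state.positions.shape[0]):
        x = state.eval_position(i)
        fit = float(fitness_fn(x))
        if check_unit and not (0.0 <= fit <= 1.0):
            raise ValueError(f"fitness {fit} outside [0, 1]")
        state.trace.append((state.iteration, i, x.copy(), fit))
        if fit > state.pbest_fit[i]:
            state.pbest_fit[i] = fit
            state.pbest_pos[i] = state.positions[i].copy()
        if fit > state.gbest_fit:  # strict: ties keep the earliest particle
            state.gbest_fit = fit
            state.gbest_pos = state.positions[i].copy()


def step(state: SwarmState, fitness_fn, _check_unit: bool = True) -> SwarmState:
    """Evaluate every particle, update bests, then fly one PSO update.

    ``fitness_fn`` maps an evaluated position vector to a fitness in [0, 1]
    (an AUC); the global-best fitness is non-decreasing across steps by
    construction.  Mutates and returns ``state``.
    """
    _evaluate_and_update_bests(state, fitness_fn, _check_unit)
    n, d = state.positions.shape
    r1 = state.rng.random((n, d))
    r2 = state.rng.random((n, d))
    state.velocities = (
        INERTIA * state.velocities
        + COGNITIVE * r1 * (state.pbest_pos - state.positions)
        + SOCIAL * r2 * (state.gbest_pos - state.positions)
    )
    state.positions = np.clip(
        state.positions + state.velocities, state.bounds[:, 0], state.bounds[:, 1]
    )
    state.iteration += 1
    return state


def run_pso(
    bounds,
    fitness_fn,
    n_particles: int,
    n_iterations: int,
    seed: int = 0,
    pinned: np.ndarray | None = None,
    int_dims: tuple[int, ...] = (),
    check_unit: bool = True,
) -> SwarmState:
    """Convenience loop: ``n_iterations`` swarm steps from a fresh state."""
    state = init_swarm(bounds, n_particles, seed, pinned=pinned, int_dims=int_dims)
    for _ in range(n_iterations):
        step(state, fitness_fn, _check_unit=check_unit)
    return state


@dataclass(frozen=True)
class OptimizeResult:
    best_params: ParticleParams
    best_fitness: float  # evaluation-series AUC of the best particle
    panel: BiomarkerPanel  # locked
    trace: pd.DataFrame  # iteration, particle, params, eval AUC


def optimize(
    norm_train,
    labels_train: pd.Series,
    norm_eval,
    labels_eval: pd.Series,
    bounds: ParamBounds,
    n_particles: int = 100,
    n_iterations: int = 10,
    seed: int = 0,
) -> OptimizeResult:
    """Swarm-search the panel hyperparameters; lock the winning panel.

    Fitness of a particle is the evaluation-series AUC of the panel built on
    the training series alone; evaluation samples never enter selection or
    fitting.  The winner (earliest particle on ties) is rebuilt on the
    training series and locked.
    """
    from .evaluation import auc_mann_whitney

    overlap = norm_train.samples.intersection(norm_eval.samples)
    if len(overlap):
        raise ValueError(f"training and evaluation series overlap: {list(overlap)[:5]}")
    for name, lab in (("training", labels_train), ("evaluation", labels_eval)):
        if lab.nunique() < 2:
            raise ValueError(f"{name} series must contain both classes")

    y_eval = (labels_eval == "sarcoma").astype(int)

    def fitness(x: np.ndarray) -> float:
        params = _vec_to_params(x)
        p = build_panel(norm_train, labels_train, params, seed=seed)
        if p.degenerate:
            return 0.5
        scores = tep_score(p, norm_eval)
        return auc_mann_whitney(scores.to_numpy(), y_eval.loc[scores.index].to_numpy())

    state = run_pso(
        bounds.with_n_detected(int(min(bounds.n_ranked[1], norm_train.values.shape[0]))),
        fitness,
        n_particles=n_particles,
        n_iterations=n_iterations,
        seed=seed,
    )
    best = _vec_to_params(state.gbest_pos)
    panel = build_panel(norm_train, labels_train, best, seed=seed).lock()
    trace = pd.DataFrame(
        [
            {
                "iteration": it,
                "particle": i,
                "libsize_cor_lo": x[0],
                "fdr_threshold": x[1],
                "cor_threshold": x[2],
                "n_ranked": int(round(x[3])),
                "eval_auc": fit,
            }
            for it, i, x, fit in state.trace
        ]
    )
    return OptimizeResult(
        best_params=best, best_fitness=float(state.gbest_fit), panel=panel, trace=trace
    )
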