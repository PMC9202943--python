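"""Core agent-population model and single-run simulator.

A population of ``M`` agents repeatedly decides whether to visit a venue
whose capacity limit is ``B``. Agent ``i`` attends in period ``t`` with
probability ``p_i(t)`` (an independent Bernoulli draw), and total attendance
is ``N(t) = sum_i x_i(t)``. After each period the attendance probabilities
are adjusted by a stochastic-approximation step of size ``mu`` that pushes
them down when the venue was crowded (``N > B``) and up when it was not,
under one of two information regimes:

* ``partial`` -- only agents who attended observe the crowding outcome and
  update; stay-at-home agents keep their probability unchanged.
* ``full`` -- every agent observes ``N(t)`` and updates, attended or not.

Probabilities are clipped to the closed interval [0, 1] after every update.
Under partial information ``p = 0`` is therefore absorbing: an agent that
never attends receives no further information and never updates again.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Regime",
    "SimulationParams",
    "AttendanceDraw",
    "RunResult",
    "initialize_probabilities",
    "draw_attendance",
    "update_partial",
    "update_full",
    "simulate_run",
]

Regime = Literal["partial", "full"]

REGIMES: tuple[str, ...] = ("partial", "full")


@dataclass(frozen=True)
class SimulationParams:
    """All model constants for one simulation run.

    Parameters
    ----------
    n_agents
        Population size ``M`` (>= 1).
    capacity
        Crowding threshold ``B`` (>= 0). The venue is crowded iff strictly
        more than ``B`` agents attend; ``B > M`` means it is never crowded.
    stepsize
        Learning rate ``mu`` (>= 0) scaling the adjustment ``-mu * (N - B)``.
    horizon
        Number of periods ``T`` (>= 1).
    regime
        ``"partial"`` or ``"full"`` information.
    benefit
        Payoff ``b`` (> 0) for attending an uncrowded venue; used only by
        the strategic-form equilibrium analysis, never by the dynamics.
    seed
        Optional default seed for :func:`simulate_run` when no generator
        is passed explicitly.
    """

    n_agents: int = 100
    capacity: int = 60
    stepsize: float = 0.01
    horizon: int = 300
    regime: str = "partial"
    benefit: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError(f"n_agents must be >= 1, got {self.n_agents}")
        if self.capacity < 0:
            raise ValueError(f"capacity must be >= 0, got {self.capacity}")
        if self.stepsize < 0:
            raise ValueError(f"stepsize must be >= 0, got {self.stepsize}")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if self.regime not in REGIMES:
            raise ValueError(
                f"regime must be one of {REGIMES}, got {self.regime!r}"
            )
        if self.benefit <= 0:
            raise ValueError(f"benefit must be > 0, got {self.benefit}")

    def replace(self, **changes) -> "SimulationParams":
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class AttendanceDraw:
    """One period's realized decisions: 0/1 vector ``x`` and total ``N``."""

    x: np.ndarray
    n_attending: int

    def __post_init__(self) -> None:
        n = int(self.x.sum())
        if n != self.n_attending:
            raise ValueError("n_attending does not equal sum(x)")


@dataclass(frozen=True)
class RunResult:
    """One simulated trajectory.

    ``prob_history`` has shape (T, M); row ``t`` (0-based ``t-1``) holds the
    probabilities ``p(t)`` in force *before* period ``t``'s draw, so the
    first row is the initialization. ``attendance_history[t-1]`` is ``N(t)``
    drawn from that same row.
    """

    params: SimulationParams
    prob_history: np.ndarray
    attendance_history: np.ndarray

    @property
    def final_probs(self) -> np.ndarray:
        """Final-period probabilities ``p(T)``."""
        return self.prob_history[-1]

    @property
    def final_attendance(self) -> int:
        """Final-period total attendance ``N(T)``."""
        return int(self.attendance_history[-1])


def initialize_probabilities(
    params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw the initial attendance probabilities ``p(1)``.

    Each agent's initial propensity is an independent Uniform(0, 1) draw,
    the maximum-entropy choice on the admissible support.
    """
    return rng.random(params.n_agents)


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("probability vector is empty")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("attendance probabilities must lie in [0, 1]")
    return p


def draw_attendance(p: np.ndarray, rng: np.random.Generator) -> AttendanceDraw:
    """Draw each agent's decision ``x_i ~ Bernoulli(p_i)`` independently."""
    p = _check_probs(p)
    x = (rng.random(p.shape[0]) < p).astype(np.int8)
    return AttendanceDraw(x=x, n_attending=int(x.sum()))


def update_partial(
    p: np.ndarray, draw: AttendanceDraw, params: SimulationParams
) -> np.ndarray:
    """Partial-information update.

    Only agents who attended adjust: ``p_i' = clip(p_i - mu*(N - B)*x_i)``.
    Stay-at-home agents observe nothing and keep ``p_i`` exactly.
    """
    step = params.stepsize * (draw.n_attending - params.capacity)
    return np.clip(p - step * draw.x, 0.0, 1.0)


def update_full(
    p: np.ndarray, n_attending: int, params: SimulationParams
) -> np.ndarray:
    """Full-information update: every agent shifts by ``-mu*(N - B)``."""
    step = params.stepsize * (n_attending - params.capacity)
    return np.clip(p - step, 0.0, 1.0)


def simulate_run(
    params: SimulationParams, rng: np.random.Generator | int | None = None
) -> RunResult:
    """Simulate one trajectory of ``T`` periods.

    For each period ``t = 1..T``: draw attendance from ``p(t)``, record
    ``N(t)``, then apply the regime's update to obtain ``p(t+1)``. The
    update is synchronous -- all agents react to the same ``N(t)``, which
    includes an attendee's own visit. Identical parameters and seed give a
    bitwise-identical result.
    """
    if rng is None:
        rng = params.seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    m, t_max = params.n_agents, params.horizon
    prob_history = np.empty((t_max, m), dtype=float)
    attendance = np.empty(t_max, dtype=np.int64)

    p = initialize_probabilities(params, rng)
    for t in range(t_max):
        prob_history[t] = p
        draw = draw_attendance(p, rng)
        attendance[t] = draw.n_attending
        if t < t_max - 1:
            if params.regime == "partial":
                p = update_partial(p, draw, params)
            else:
                p = update_full(p, draw.n_attending, params)

    return RunResult(
        params=params, prob_history=prob_history, attendance_history=attendance
    )
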