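"""Monte Carlo ensembles, the fairness statistic, and sensitivity sweeps.

Fairness is measured inversely by the population variance of the agents'
final-period attendance probabilities,

    (1/M) * sum_i (p_i(T) - mean(p(T)))^2,

so 0 means perfectly equal access and larger values mean a more segmented
population. An ensemble repeats the single-run simulation on independent,
reproducible random substreams and records final attendance N(T) and the
fairness statistic per run; summaries report means and population
variances across runs (the n/(n-1) correction is far below Monte Carlo
noise at the ensemble sizes used here).

Random-stream discipline: a base seed (or an explicit ``SeedSequence``)
roots the ensemble; run ``k`` uses the substream with spawn key ``(k,)``,
so runs are independent and exchangeable, any single run can be reproduced
in isolation, and sweep cells derive disjoint roots from their grid
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import REGIMES, RunResult, SimulationParams, simulate_run

__all__ = [
    "EnsembleResult",
    "EnsembleSummary",
    "RegimeComparison",
    "fairness_variance",
    "run_ensemble",
    "summarize_ensemble",
    "compare_regimes",
    "attendance_variability_profile",
    "segmentation_fraction",
    "sensitivity_sweep",
]


def fairness_variance(final_probs: np.ndarray) -> float:
    """Population variance (divisor M) of a probability vector.

    Bounded by 0.25, attained when half the agents sit at 0 and half at 1.
    """
    p = np.asarray(final_probs, dtype=float)
    if p.size == 0:
        raise ValueError("cannot compute fairness of an empty vector")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("attendance probabilities must lie in [0, 1]")
    return float(np.var(p))


def _root_seedseq(base_seed) -> np.random.SeedSequence:
    if isinstance(base_seed, np.random.SeedSequence):
        return base_seed
    return np.random.SeedSequence(base_seed)


@dataclass(frozen=True)
class EnsembleResult:
    """Per-run final attendance and fairness across an ensemble."""

    params: SimulationParams
    n_runs: int
    base_seed: object
    final_attendance: np.ndarray
    fairness: np.ndarray

    def __post_init__(self) -> None:
        if len(self.final_attendance) != self.n_runs or len(self.fairness) != self.n_runs:
            raise ValueError("result vectors must have length n_runs")


@dataclass(frozen=True)
class EnsembleSummary:
    """The four headline ensemble statistics for one regime."""

    mean_attendance: float
    var_attendance: float
    mean_fairness: float
    var_fairness: float

    def to_dict(self) -> dict:
        return {
            "mean_attendance": self.mean_attendance,
            "var_attendance": self.var_attendance,
            "mean_fairness": self.mean_fairness,
            "var_fairness": self.var_fairness,
        }


@dataclass(frozen=True)
class RegimeComparison:
    """Fairness comparison between a partial- and a full-information ensemble."""

    mean_fairness_partial: float
    mean_fairness_full: float
    full_fairer_on_average: bool
    strict_dominance: bool  # max over full runs < min over partial runs


def run_ensemble(
    params: SimulationParams, n_runs: int, base_seed
) -> EnsembleResult:
    """Run ``n_runs`` independent simulations on substreams of ``base_seed``.

    ``base_seed`` may be an integer or a ``numpy.random.SeedSequence``; run
    ``k`` uses the child sequence with spawn key ``(k,)``. Reproducible:
    the same base seed yields an identical ensemble.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    root = _root_seedseq(base_seed)
    final_attendance = np.empty(n_runs, dtype=np.int64)
    fairness = np.empty(n_runs, dtype=float)
    for k in range(n_runs):
        child = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=tuple(root.spawn_key) + (k,)
        )
        run = simulate_run(params, np.random.default_rng(child))
        final_attendance[k] = run.final_attendance
        fairness[k] = fairness_variance(run.final_probs)
    return EnsembleResult(
        params=params,
        n_runs=n_runs,
        base_seed=base_seed,
        final_attendance=final_attendance,
        fairness=fairness,
    )


def summarize_ensemble(ens: EnsembleResult) -> EnsembleSummary:
    """Mean and population variance of final attendance and fairness."""
    return EnsembleSummary(
        mean_attendance=float(np.mean(ens.final_attendance)),
        var_attendance=float(np.var(ens.final_attendance)),
        mean_fairness=float(np.mean(ens.fairness)),
        var_fairness=float(np.var(ens.fairness)),
    )


def compare_regimes(
    partial: EnsembleResult, full: EnsembleResult
) -> RegimeComparison:
    """Compare fairness between regimes.

    The ensembles must share every parameter except the regime. Strict
    dominance holds when the worst (largest) full-information fairness
    variance is still below the best (smallest) partial-information one,
    i.e. full information is fairer in every pair of runs, not just on
    average. The ensembles are unpaired; no run-index matching is assumed.
    """
    if partial.params.regime != "partial" or full.params.regime != "full":
        raise ValueError("expected a partial-regime and a full-regime ensemble")
    if partial.params.replace(regime="full") != full.params:
        raise ValueError("ensembles differ in parameters other than regime")
    mean_partial = float(np.mean(partial.fairness))
    mean_full = float(np.mean(full.fairness))
    return RegimeComparison(
        mean_fairness_partial=mean_partial,
        mean_fairness_full=mean_full,
        full_fairer_on_average=mean_full < mean_partial,
        strict_dominance=float(np.max(full.fairness)) < float(np.min(partial.fairness)),
    )


def attendance_variability_profile(
    run: RunResult, window: int
) -> tuple[float, float]:
    """Population variance of N(t) over the first and last ``window`` periods.

    A declining profile (late < early) is the signature of the
    partial-information regime settling toward a pure equilibrium; under
    full information aggregate attendance keeps fluctuating.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    t = len(run.attendance_history)
    if 2 * window > t:
        raise ValueError(f"2*window = {2 * window} exceeds horizon {t}")
    early = float(np.var(run.attendance_history[:window]))
    late = float(np.var(run.attendance_history[-window:]))
    return early, late


def segmentation_fraction(
    final_probs: np.ndarray, threshold: float = 0.1
) -> float:
    """Fraction of agents with near-extreme final probabilities.

    Counts agents with ``p <= threshold`` or ``p >= 1 - threshold``; high
    values indicate the population has split into habitual attendees and
    permanently excluded agents.
    """
    p = np.asarray(final_probs, dtype=float)
    return float(np.mean((p <= threshold) | (p >= 1.0 - threshold)))


def sensitivity_sweep(
    base: SimulationParams,
    capacity_values: Sequence[int],
    stepsize_values: Sequence[float],
    n_runs: int,
    base_seed,
    regimes: Sequence[str] = REGIMES,
) -> pd.DataFrame:
    """Full factorial sweep over capacity and stepsize, per regime.

    Each grid cell runs an independent ensemble whose root seed sequence is
    derived from ``base_seed`` and the cell's grid coordinates (capacity
    index, stepsize index), so the grid is reproducible and cells are
    independent; both regimes in a cell share the root and therefore see
    the same initializations. Returns a tidy frame with one row per
    (capacity, stepsize, regime) holding the four summary statistics.
    """
    if len(capacity_values) == 0 or len(stepsize_values) == 0:
        raise ValueError("sweep grids must be non-empty")
    for b in capacity_values:
        if not 1 <= b <= base.n_agents:
            raise ValueError(f"capacity {b} outside [1, {base.n_agents}]")
    for mu in stepsize_values:
        if mu < 0:
            raise ValueError(f"stepsize {mu} must be >= 0")

    root = _root_seedseq(base_seed)
    rows = []
    for bi, b in enumerate(capacity_values):
        for mj, mu in enumerate(stepsize_values):
            cell_seed = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=tuple(root.spawn_key) + (bi, mj)
            )
            for regime in regimes:
                params = base.replace(capacity=b, stepsize=mu, regime=regime)
                summary = summarize_ensemble(
                    run_ensemble(params, n_runs, cell_seed)
                )
                rows.append(
                    {"capacity": b, "stepsize": mu, "regime": regime}
                    | summary.to_dict()
                )
    return pd.DataFrame(rows)
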