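"""Result serialization: CSV/JSON export with full provenance.

Every artifact embeds the resolved parameter set and seed so a run can be
reproduced from its files alone. Floats are written with ``repr`` (the
shortest round-trip representation), which makes repeated invocations with
the same configuration byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .core import RunResult, SimulationParams
from .experiments import EnsembleResult, EnsembleSummary

__all__ = [
    "params_to_dict",
    "write_run_csv",
    "write_run_sidecar",
    "write_ensemble_csv",
    "read_ensemble_csv",
    "write_summary_json",
    "write_sweep_csv",
]


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def _seed_to_jsonable(seed):
    if isinstance(seed, np.random.SeedSequence):
        return {"entropy": seed.entropy, "spawn_key": list(seed.spawn_key)}
    return seed


def params_to_dict(params: SimulationParams) -> dict:
    return {
        "M": params.n_agents,
        "B": params.capacity,
        "mu": params.stepsize,
        "T": params.horizon,
        "regime": params.regime,
        "b": params.benefit,
        "seed": params.seed,
    }


def write_run_csv(run: RunResult, path: str | Path) -> Path:
    """One row per period: ``t`` (1-based), attendance ``N``, then p_1..p_M."""
    path = Path(path)
    m = run.params.n_agents
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "N"] + [f"p_{i}" for i in range(1, m + 1)])
        for t in range(run.params.horizon):
            writer.writerow(
                [t + 1, int(run.attendance_history[t])]
                + [_fmt(v) for v in run.prob_history[t]]
            )
    return path


def write_run_sidecar(run: RunResult, path: str | Path, seed=None) -> Path:
    path = Path(path)
    payload = {"params": params_to_dict(run.params), "seed": _seed_to_jsonable(seed)}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def write_ensemble_csv(ens: EnsembleResult, path: str | Path) -> Path:
    """One row per run: run index, substream spawn key, N(T), fairness."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["run", "spawn_key", "final_attendance", "fairness"])
        for k in range(ens.n_runs):
            writer.writerow(
                [k, k, int(ens.final_attendance[k]), _fmt(ens.fairness[k])]
            )
    return path


def read_ensemble_csv(
    path: str | Path, params: SimulationParams, base_seed=None
) -> EnsembleResult:
    """Re-read an exported ensemble; inverse of :func:`write_ensemble_csv`."""
    path = Path(path)
    attendance, fairness = [], []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            attendance.append(int(row["final_attendance"]))
            fairness.append(float(row["fairness"]))
    return EnsembleResult(
        params=params,
        n_runs=len(attendance),
        base_seed=base_seed,
        final_attendance=np.asarray(attendance, dtype=np.int64),
        fairness=np.asarray(fairness, dtype=float),
    )


def write_summary_json(
    summaries: dict[str, EnsembleSummary],
    params: SimulationParams,
    path: str | Path,
    *,
    n_runs: int,
    seeds: dict | None = None,
) -> Path:
    """Summary statistics per regime, with parameters and seeds embedded."""
    path = Path(path)
    payload = {
        "params": params_to_dict(params),
        "n_runs": n_runs,
        "seeds": {k: _seed_to_jsonable(v) for k, v in (seeds or {}).items()},
        "summaries": {regime: s.to_dict() for regime, s in summaries.items()},
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def write_sweep_csv(sweep, path: str | Path) -> Path:
    """Long-format sweep export: one row per (capacity, stepsize, regime, statistic)."""
    path = Path(path)
    long = sweep.melt(
        id_vars=["capacity", "stepsize", "regime"],
        var_name="statistic",
        value_name="value",
    )
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["capacity", "stepsize", "regime", "statistic", "value"])
        for row in long.itertuples(index=False):
            writer.writerow(
                [row.capacity, _fmt(row.stepsize), row.regime, row.statistic, _fmt(row.value)]
            )
    return path
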