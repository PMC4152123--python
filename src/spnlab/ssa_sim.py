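"""Exact stochastic simulation of matrix bundles (Gillespie direct method).

The marking x evolves as a continuous-time Markov chain. Each transition j has
propensity

    a_j(x) = c_j * prod_i C(x_i, Pre[i][j])

where C is the binomial coefficient: the number of distinct ways to pick the
reactant tokens (combinatorial mass action, the standard stochastic-Petri-net
convention). a_j vanishes whenever some input place is under-resourced, so no
firing can drive a token count negative.

The direct method draws the waiting time to the next event from
Exponential(a0), a0 = sum_j a_j, and picks the firing transition with
probability a_j / a0. Exactly two uniform draws are consumed per event (one
for the waiting time, one for the cumulative-sum transition choice, scanned in
column order), so a trajectory is a pure function of (bundle, t_max, seed,
max_events) and reproduces bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .matrix_engine import MatrixBundle

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "propensities",
    "simulate",
    "simulate_ensemble",
    "sample_on_grid",
    "trajectory_to_csv",
    "trajectory_to_json",
    "ensemble_to_csv",
]


@dataclass(eq=False)
class Trajectory:
    """Event-time series of markings.

    ``markings[0]`` is the initial marking M0; ``fired[k]`` is the transition
    index whose firing produced ``markings[k+1]`` at time ``times[k+1]``.
    ``absorbed`` records whether the run ended because all propensities were 0.
    """

    times: np.ndarray
    markings: np.ndarray
    fired: np.ndarray
    seed: int
    absorbed: bool = False

    @property
    def n_events(self) -> int:
        return len(self.fired)

    def final_marking(self) -> np.ndarray:
        return self.markings[-1]

    def time_average(self, t_start: float, t_end: float) -> np.ndarray:
        """Time-weighted mean marking over [t_start, t_end] (step function)."""
        if t_end <= t_start:
            raise DomainError("t_end must exceed t_start")
        total = np.zeros(self.markings.shape[1], dtype=np.float64)
        edges = np.append(self.times, t_end)
        for k in range(len(self.times)):
            lo = max(edges[k], t_start)
            hi = min(edges[k + 1], t_end)
            if hi > lo:
                total += (hi - lo) * self.markings[k]
        return total / (t_end - t_start)

    def time_average_second_moment(self, t_start: float, t_end: float) -> np.ndarray:
        if t_end <= t_start:
            raise DomainError("t_end must exceed t_start")
        total = np.zeros(self.markings.shape[1], dtype=np.float64)
        edges = np.append(self.times, t_end)
        for k in range(len(self.times)):
            lo = max(edges[k], t_start)
            hi = min(edges[k + 1], t_end)
            if hi > lo:
                total += (hi - lo) * self.markings[k].astype(np.float64) ** 2
        return total / (t_end - t_start)


@dataclass(eq=False)
class EnsembleSummary:
    """Per-timepoint mean/variance of the marking across replicates."""

    grid_times: np.ndarray
    mean: np.ndarray        # (len(grid), |P|)
    variance: np.ndarray    # (len(grid), |P|), sample variance (ddof=1)
    n_replicates: int
    seeds: list[int] = field(default_factory=list)


def propensities(bundle: MatrixBundle, x: np.ndarray) -> np.ndarray:
    """Vector a with a_j = c_j * prod_i C(x_i, Pre[i][j])."""
    x = np.asarray(x)
    if (x < 0).any():
        raise DomainError("marking entries must be >= 0")
    a = np.empty(bundle.n_transitions, dtype=np.float64)
    for j in range(bundle.n_transitions):
        combos = 1
        for i in np.nonzero(bundle.pre[:, j])[0]:
            combos *= math.comb(int(x[i]), int(bundle.pre[i, j]))
            if combos == 0:
                break
        a[j] = bundle.rates[j] * combos
    return a


def simulate(
    bundle: MatrixBundle,
    t_max: float,
    seed: int,
    max_events: int = 1_000_000,
) -> Trajectory:
    """Run one exact trajectory until t_max, max_events, or absorption."""
    if t_max <= 0:
        raise DomainError("t_max must be > 0")
    rng = np.random.default_rng(seed)
    stoich = bundle.stoichiometry
    # per-column reactant lists keep the inner loop cheap at desk scale
    reactants = [
        [(int(i), int(bundle.pre[i, j])) for i in np.nonzero(bundle.pre[:, j])[0]]
        for j in range(bundle.n_transitions)
    ]
    rates = bundle.rates
    x = bundle.initial_marking.astype(np.int64).copy()
    t = 0.0
    times = [0.0]
    markings = [x.copy()]
    fired: list[int] = []
    absorbed = False
    while len(fired) < max_events:
        a = np.empty(len(rates))
        for j, pairs in enumerate(reactants):
            combos = 1
            for i, k in pairs:
                combos *= math.comb(int(x[i]), k)
                if combos == 0:
                    break
            a[j] = rates[j] * combos
        a0 = a.sum()
        if a0 == 0.0:
            absorbed = True
            break
        dt = -math.log1p(-rng.random()) / a0
        threshold = rng.random() * a0
        running = 0.0
        j = len(a) - 1
        for candidate in range(len(a)):
            running += a[candidate]
            if running > threshold:
                j = candidate
                break
        if t + dt > t_max:
            break
        t += dt
        x = x + stoich[:, j]
        times.append(t)
        markings.append(x.copy())
        fired.append(j)
    return Trajectory(
        times=np.array(times, dtype=np.float64),
        markings=np.array(markings, dtype=np.int64),
        fired=np.array(fired, dtype=np.int64),
        seed=seed,
        absorbed=absorbed,
    )


def sample_on_grid(trajectory: Trajectory, grid_times: np.ndarray) -> np.ndarray:
    """Resample onto grid times by last-event-carried-forward.

    The marking is a right-continuous step function; ``markings[k]`` holds on
    [times[k], times[k+1]).
    """
    grid_times = np.asarray(grid_times, dtype=np.float64)
    idx = np.searchsorted(trajectory.times, grid_times, side="right") - 1
    idx = np.clip(idx, 0, len(trajectory.times) - 1)
    return trajectory.markings[idx]


def simulate_ensemble(
    bundle: MatrixBundle,
    t_max: float,
    grid_times,
    n_replicates: int,
    base_seed: int,
) -> EnsembleSummary:
    """Replicate simulate() with seeds base_seed..base_seed+n-1 and summarise."""
    grid = np.asarray(grid_times, dtype=np.float64)
    if grid.size == 0:
        raise DomainError("grid_times must be non-empty")
    if (grid < 0).any() or (grid > t_max).any():
        raise DomainError("grid_times must lie within [0, t_max]")
    if n_replicates < 2:
        raise DomainError("n_replicates must be >= 2")
    seeds = [base_seed + k for k in range(n_replicates)]
    samples = np.empty((n_replicates, grid.size, bundle.n_places), dtype=np.int64)
    for k, seed in enumerate(seeds):
        samples[k] = sample_on_grid(simulate(bundle, t_max, seed), grid)
    return EnsembleSummary(
        grid_times=grid,
        mean=samples.mean(axis=0),
        variance=samples.var(axis=0, ddof=1),
        n_replicates=n_replicates,
        seeds=seeds,
    )


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def _format_number(value: float) -> str:
    return repr(float(value))


def trajectory_to_csv(
    trajectory: Trajectory, place_ids: list[str], comments: list[str] | None = None
) -> str:
    """CSV with a time column plus one column per place; optional '#' header."""
    lines = [f"# {c}" for c in (comments or [])]
    lines.append(",".join(["time"] + list(place_ids)))
    for k in range(len(trajectory.times)):
        row = [_format_number(trajectory.times[k])]
        row.extend(str(int(v)) for v in trajectory.markings[k])
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"


def trajectory_to_json(trajectory: Trajectory, place_ids: list[str]) -> str:
    doc = {
        "absorbed": trajectory.absorbed,
        "fired": trajectory.fired.tolist(),
        "markings": trajectory.markings.tolist(),
        "place_ids": list(place_ids),
        "seed": trajectory.seed,
        "times": trajectory.times.tolist(),
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def ensemble_to_csv(
    summary: EnsembleSummary, place_ids: list[str], comments: list[str] | None = None
) -> str:
    """CSV: time, then mean_<place> and var_<place> columns."""
    lines = [f"# {c}" for c in (comments or [])]
    header = ["time"]
    header += [f"mean_{pid}" for pid in place_ids]
    header += [f"var_{pid}" for pid in place_ids]
    lines.append(",".join(header))
    for k in range(len(summary.grid_times)):
        row = [_format_number(summary.grid_times[k])]
        row.extend(_format_number(v) for v in summary.mean[k])
        row.extend(_format_number(v) for v in summary.variance[k])
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"
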