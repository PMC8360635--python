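"""Exact stochastic simulation (direct-method SSA) of the nonlinear
circuits, and stationary-statistics estimation.

The simulator samples the continuous-time Markov jump process exactly: the
next event time is exponential in the total propensity, the event is
chosen proportionally to the propensities, burst events add a freshly
sampled burst size and death events decrement by one, with all
propensities recomputed after every event.  No linearization is involved,
which is what makes SSA estimates an independent check on the linear noise
approximation.

Stationary means and CV² are time-weighted averages over post-burn-in
trajectory segments, pooled across replicates; standard errors come from a
replicate-level jackknife (time-correlated samples make naive i.i.d.
standard errors invalid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .circuits import (
    BurstKind,
    CircuitModel,
    CircuitTopology,
    SteadyMeans,
    solve_steady_means,
)
from .exceptions import InvalidWindowError, RunawayPopulationError
from .lna import decompose_noise

__all__ = [
    "Trajectory",
    "SummaryStats",
    "simulate",
    "simulate_stats",
    "stationary_stats",
    "default_burn_in",
    "validate_against_lna",
]

_TOPO_CODE = {CircuitTopology.OPEN: 0, CircuitTopology.PROPORTIONAL: 1,
              CircuitTopology.INTEGRAL: 2, CircuitTopology.DERIVATIVE: 3}
_KIND_CODE = {BurstKind.DETERMINISTIC: 0, BurstKind.SHIFTED_GEOMETRIC: 1}

# parameter-vector layout for the kernel
(_KX, _GX, _BX_MEAN, _BX_KIND, _XBAR, _XDYN,
 _KY, _GY, _BY_MEAN, _BY_KIND,
 _KZ, _GZ, _BZ_MEAN, _BZ_KIND, _HAS_Z,
 _ZC, _H, _YSET) = range(18)

_DEFAULT_CAP = 1_000_000.0


@njit(cache=False)
def _draw_burst(kind: int, mean: float) -> int:
    if kind == 0:
        return int(round(mean))
    p = 1.0 / mean
    if p >= 1.0:
        return 1
    u = np.random.random()
    j = int(math.ceil(math.log(1.0 - u) / math.log(1.0 - p)))
    return j if j >= 1 else 1


@njit(cache=False)
def _ssa_kernel(topo, par, x0, y0, z0, t_end, burn_in, seed,
                times, states, record, cap):
    """Direct-method SSA.  Returns

    ``(status, n_recorded, acc_T, acc_y, acc_y2, x, y, z)``

    with status 0 = ok, -1 = population cap exceeded, -2 = record buffer
    full.  ``acc_*`` are the post-burn-in time integrals of 1, y, y².
    """
    np.random.seed(seed)
    t = 0.0
    x, y, z = x0, y0, z0
    n = 0
    if record:
        times[0] = 0.0
        states[0, 0] = x
        states[0, 1] = y
        states[0, 2] = z
        n = 1
    acc_t = 0.0
    acc_y = 0.0
    acc_y2 = 0.0
    xdyn = par[_XDYN] > 0.5
    has_z = par[_HAS_Z] > 0.5
    while True:
        # --- propensities -------------------------------------------------
        xf = x / par[_XBAR] if xdyn else 1.0
        if topo == 0:
            a1 = par[_KY] * xf
        elif topo == 1 or topo == 2:
            a1 = par[_KY] * xf / (1.0 + (z / par[_ZC]) ** par[_H])
        else:
            yy = y if y >= 1.0 else 1.0
            a1 = 0.0 if z <= 0.0 else par[_KY] * xf * (z / yy) ** par[_H]
        a2 = par[_GY] * y
        a3 = 0.0
        a4 = 0.0
        if has_z:
            if topo == 2:
                a3 = par[_KZ] * y / par[_BZ_MEAN]
                a4 = par[_KZ] * par[_YSET] if z > 0.0 else 0.0
            else:
                a3 = par[_KZ] * y
                a4 = par[_GZ] * z
        a5 = par[_KX] if xdyn else 0.0
        a6 = par[_GX] * x if xdyn else 0.0
        a0 = a1 + a2 + a3 + a4 + a5 + a6
        # --- time advance and occupancy accumulation ----------------------
        if a0 <= 0.0:
            tn = t_end
        else:
            tn = t - math.log(np.random.random()) / a0
        seg0 = t if t > burn_in else burn_in
        seg1 = tn if tn < t_end else t_end
        if seg1 > seg0:
            w = seg1 - seg0
            acc_t += w
            acc_y += y * w
            acc_y2 += y * y * w
        if tn >= t_end or a0 <= 0.0:
            return 0, n, acc_t, acc_y, acc_y2, x, y, z
        t = tn
        # --- event selection ----------------------------------------------
        r = np.random.random() * a0
        if r < a1:
            y += _draw_burst(int(par[_BY_KIND]), par[_BY_MEAN])
        elif r < a1 + a2:
            y -= 1.0
        elif r < a1 + a2 + a3:
            z += _draw_burst(int(par[_BZ_KIND]), par[_BZ_MEAN])
        elif r < a1 + a2 + a3 + a4:
            z -= 1.0
        elif r < a1 + a2 + a3 + a4 + a5:
            x += _draw_burst(int(par[_BX_KIND]), par[_BX_MEAN])
        else:
            x -= 1.0
        if x > cap or y > cap or z > cap:
            return -1, n, acc_t, acc_y, acc_y2, x, y, z
        if record:
            if n >= times.shape[0]:
                return -2, n, acc_t, acc_y, acc_y2, x, y, z
            times[n] = t
            states[n, 0] = x
            states[n, 1] = y
            states[n, 2] = z
            n += 1


def _param_vector(circuit: CircuitModel) -> tuple[int, np.ndarray]:
    par = np.zeros(18)
    topo = _TOPO_CODE[circuit.topology]
    if circuit.has_disturbance:
        xp = circuit.disturbance.params
        par[_KX] = xp.burst_rate
        par[_GX] = xp.decay_rate
        par[_BX_MEAN] = xp.burst.mean_size
        par[_BX_KIND] = _KIND_CODE[xp.burst.kind]
        par[_XDYN] = 1.0
    par[_XBAR] = circuit.disturbance.mean
    par[_KY] = circuit.target.burst_rate
    par[_GY] = circuit.target.decay_rate
    par[_BY_MEAN] = circuit.target.burst.mean_size
    par[_BY_KIND] = _KIND_CODE[circuit.target.burst.kind]
    if circuit.sensor is not None:
        par[_KZ] = circuit.sensor.burst_rate
        par[_GZ] = circuit.sensor.decay_rate
        par[_BZ_MEAN] = circuit.sensor.burst.mean_size
        par[_BZ_KIND] = _KIND_CODE[circuit.sensor.burst.kind]
        par[_HAS_Z] = 1.0
    reg = circuit.regulation
    par[_ZC] = reg.half_max if reg.half_max is not None else 1.0
    par[_H] = reg.hill_coeff
    par[_YSET] = reg.set_point if reg.set_point is not None else 0.0
    return topo, par


def _initial_state(circuit: CircuitModel, init: str | tuple,
                   means: SteadyMeans) -> tuple[float, float, float]:
    if init == "means":
        x = round(means.x) if circuit.has_disturbance else means.x
        z = round(means.z) if circuit.sensor is not None else 0.0
        return float(x), float(round(means.y)), float(z)
    if init == "zeros":
        x = round(means.x) if circuit.has_disturbance else means.x
        return float(x), 0.0, 0.0
    x, y, z = init
    return float(x), float(y), float(z)


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Piecewise-constant sample path of ``(x, y, z)`` counts.

    ``times[0] = 0`` holds the initial state; the state is constant between
    consecutive event times and the last state extends to ``t_end``.
    """

    times: np.ndarray
    states: np.ndarray   # (n, 3) int64 columns x, y, z
    t_end: float
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy event table (time, x, y, z) for CSV export."""
        return pd.DataFrame({"time": self.times,
                             "x": self.states[:, 0],
                             "y": self.states[:, 1],
                             "z": self.states[:, 2]})

    def weights(self, burn_in: float = 0.0) -> np.ndarray:
        """Post-burn-in occupancy time of each recorded state."""
        starts = np.maximum(self.times, burn_in)
        ends = np.minimum(np.append(self.times[1:], self.t_end), self.t_end)
        return np.maximum(ends - starts, 0.0)


def _estimate_events(circuit: CircuitModel, means: SteadyMeans,
                     t_end: float) -> int:
    """Rough mean total event rate at the stationary point, for sizing the
    record buffers (the simulate loop regrows on overflow anyway)."""
    rate = circuit.target.burst_rate + circuit.target.decay_rate * means.y
    if circuit.has_disturbance:
        xp = circuit.disturbance.params
        rate += xp.burst_rate + xp.decay_rate * means.x
    if circuit.sensor is not None:
        zp = circuit.sensor
        if circuit.topology is CircuitTopology.INTEGRAL:
            rate += (zp.burst_rate * means.y / zp.burst.moments[0]
                     + zp.burst_rate * circuit.regulation.set_point)
        else:
            rate += zp.burst_rate * means.y + zp.decay_rate * means.z
    return int(3.0 * rate * t_end) + 1024


def simulate(circuit: CircuitModel, t_end: float, seed: int, *,
             init: str | tuple = "means",
             population_cap: float = _DEFAULT_CAP) -> Trajectory:
    """Exact SSA sample path.  Identical ``(circuit, t_end, seed)`` yield
    bit-identical trajectories.

    ``init`` is ``"means"`` (deterministic at the rounded steady means,
    the default — it shortens burn-in), ``"zeros"``, or an explicit
    ``(x, y, z)`` triple.
    """
    if not t_end > 0.0:
        raise InvalidWindowError(f"t_end must be positive, got {t_end}")
    topo, par = _param_vector(circuit)
    means = solve_steady_means(circuit)
    x0, y0, z0 = _initial_state(circuit, init, means)
    n_max = _estimate_events(circuit, means, t_end)
    while True:
        times = np.empty(n_max)
        states = np.empty((n_max, 3), dtype=np.int64)
        status, n, *_rest = _ssa_kernel(
            topo, par, x0, y0, z0, t_end, 0.0, np.uint32(seed),
            times, states, True, population_cap)
        if status == -1:
            raise RunawayPopulationError(
                f"population exceeded cap {population_cap:g} at event {n} "
                f"(seed {seed}); check circuit parameters")
        if status == 0:
            return Trajectory(times=times[:n].copy(),
                              states=states[:n].copy(),
                              t_end=t_end, seed=seed)
        n_max *= 2  # buffer full: rerun (same seed => same path) with room


# --------------------------------------------------------------------------
# stationary statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    """Pooled stationary mean and CV² of the target with jackknife
    standard errors across replicates."""

    mean_y: float
    cv2_y: float
    se_mean: float
    se_cv2: float
    n_replicates: int
    burn_in: float

    def as_dict(self) -> dict:
        return {"mean_y": self.mean_y, "cv2_y": self.cv2_y,
                "se_mean": self.se_mean, "se_cv2": self.se_cv2,
                "n_replicates": self.n_replicates, "burn_in": self.burn_in}


def _pooled(trip: np.ndarray) -> tuple[float, float]:
    """(mean, cv²) from stacked (T, ∫y, ∫y²) rows."""
    T, sy, sy2 = trip.sum(axis=0)
    mean = sy / T
    var = sy2 / T - mean * mean
    return mean, var / (mean * mean)


def _aggregate(triples: np.ndarray, burn_in: float) -> SummaryStats:
    n = triples.shape[0]
    mean, cv2 = _pooled(triples)
    if n < 2:
        return SummaryStats(mean, cv2, float("nan"), float("nan"), n, burn_in)
    loo = np.empty((n, 2))
    for i in range(n):
        loo[i] = _pooled(np.delete(triples, i, axis=0))
    se = np.sqrt((n - 1) / n * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))
    return SummaryStats(mean, cv2, se[0], se[1], n, burn_in)


def stationary_stats(trajectories: Sequence[Trajectory], burn_in: float
                     ) -> SummaryStats:
    """Time-weighted stationary statistics from recorded trajectories."""
    for tr in trajectories:
        if burn_in >= tr.t_end:
            raise InvalidWindowError(
                f"burn_in {burn_in} >= t_end {tr.t_end}: empty window")
    triples = np.empty((len(trajectories), 3))
    for i, tr in enumerate(trajectories):
        w = tr.weights(burn_in)
        y = tr.states[:, 1].astype(float)
        triples[i] = (w.sum(), (w * y).sum(), (w * y * y).sum())
    return _aggregate(triples, burn_in)


def default_burn_in(circuit: CircuitModel) -> float:
    """``10 / min(decay rates)`` including the disturbance clock; the
    slowest relaxation sets the mixing time.  The integral controller's
    zero-order decay has no rate constant, so only first-order clocks
    enter."""
    rates = [circuit.target.decay_rate]
    if circuit.has_disturbance:
        rates.append(circuit.disturbance.params.decay_rate)
    if (circuit.sensor is not None
            and circuit.topology is not CircuitTopology.INTEGRAL):
        rates.append(circuit.sensor.decay_rate)
    return 10.0 / min(rates)


def simulate_stats(circuit: CircuitModel, *, n_reps: int, t_end: float,
                   seed: int, burn_in: float | None = None,
                   init: str | tuple = "means",
                   population_cap: float = _DEFAULT_CAP) -> SummaryStats:
    """Run ``n_reps`` independent replicates (seeds spawned from ``seed``)
    accumulating time-averaged moments in the kernel without storing
    events; suitable for long horizons."""
    if burn_in is None:
        burn_in = default_burn_in(circuit)
    if burn_in >= t_end:
        raise InvalidWindowError(
            f"burn_in {burn_in} >= t_end {t_end}: empty window")
    topo, par = _param_vector(circuit)
    means = solve_steady_means(circuit)
    x0, y0, z0 = _initial_state(circuit, init, means)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps,
                                                        dtype=np.uint32)
    dummy_t = np.empty(1)
    dummy_s = np.empty((1, 3), dtype=np.int64)
    triples = np.empty((n_reps, 3))
    for i, s in enumerate(seeds):
        status, _n, acc_t, acc_y, acc_y2, *_ = _ssa_kernel(
            topo, par, x0, y0, z0, t_end, burn_in, s,
            dummy_t, dummy_s, False, population_cap)
        if status == -1:
            raise RunawayPopulationError(
                f"population exceeded cap {population_cap:g} in replicate "
                f"{i} (seed {int(s)})")
        triples[i] = (acc_t, acc_y, acc_y2)
    return _aggregate(triples, burn_in)


# --------------------------------------------------------------------------
# SSA vs LNA cross-validation
# --------------------------------------------------------------------------

def validate_against_lna(circuit: CircuitModel, *, n_reps: int = 8,
                         t_end: float = 500.0, seed: int = 0,
                         burn_in: float | None = None) -> dict:
    """Simulated stationary CV² against the linearized-moment prediction.

    Returns a record with the simulated estimate ± SE, the closed
    moment-solver total, the z-score of the difference, and a flag at
    ``|z| > 3``.  Meaningful in small-noise regimes (total CV² ≲ 0.5),
    where the linear noise approximation is accurate.
    """
    stats = simulate_stats(circuit, n_reps=n_reps, t_end=t_end, seed=seed,
                           burn_in=burn_in)
    predicted = decompose_noise(circuit)
    z = (stats.cv2_y - predicted.total) / stats.se_cv2
    return {
        "cv2_sim": stats.cv2_y,
        "se_cv2": stats.se_cv2,
        "mean_sim": stats.mean_y,
        "se_mean": stats.se_mean,
        "cv2_predicted": predicted.total,
        "z_score": z,
        "flagged": bool(abs(z) > 3.0),
        "n_replicates": n_reps,
        "t_end": t_end,
        "burn_in": stats.burn_in,
        "seed": seed,
    }
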