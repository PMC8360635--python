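"""Linear noise approximation: exact moment dynamics of the linearized
circuit, assembled from the infinitesimal generator.

The only nonlinearity in any of the circuits is the target's burst
frequency (Hill repression or the ``(z/y)^h`` ratio).  Expanding it to
first order around the stationary means leaves every event propensity
affine in the state, so the first and second uncentered moments of
``(x, y, z)`` close exactly into a linear ODE system ``μ̇ = â + Aμ``.  Each
row of ``(â, A)`` is the generator expansion: for every event, (rate) ×
(expected change of the monomial), summed over events.  Stationary moments
solve ``Aμ̄ = -â``.

Noise components are attributed by *source silencing*: the stationary
covariance of a linear system is additive in the shot-noise contributions
of its event sources (the drift matrix is shared), so re-solving with the
disturbance frozen at ``x̄`` and then additionally with the controller's
shot terms replaced by their drift-only (Liouville) parts splits the total
``CV²_Y`` into external-disturbance, controller, and intrinsic components
by differencing.  Both the burst second-moment terms and the ±1 death shot
terms of the controller are silenced: the controller's stationary noise
``CV²_Z = (⟨B_z⟩+⟨B_z²⟩)/(2⟨B_z⟩z̄)`` receives its ``⟨B_z⟩`` part from
death events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .circuits import (
    CircuitModel,
    CircuitTopology,
    SteadyMeans,
    burst_moments,
    feedback_gain,
    solve_steady_means,
)
from .exceptions import (
    DegenerateLinearizationError,
    NumericalConditioningError,
    StabilityError,
)

__all__ = [
    "LinearizedRates",
    "MomentSystem",
    "NoiseDecomposition",
    "linearize",
    "assemble_moment_system",
    "steady_state_moments",
    "decompose_noise",
]


# --------------------------------------------------------------------------
# linearization of the target's burst frequency
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearizedRates:
    """Affine approximation of the target's burst frequency.

    ``rate ≈ base_rate · (1 + Σ_s coeffs[s]·(s/s̄ - 1))`` where the sum runs
    over the species the regulation actually reads.  At stationarity
    ``base_rate·⟨B_y⟩ = γ_y·ȳ``.
    """

    base_rate: float
    coeffs: Mapping[str, float]


def linearize(circuit: CircuitModel, means: SteadyMeans | None = None
              ) -> LinearizedRates:
    """First-order expansion of the burst frequency around the means.

    Coefficients on the normalized deviations are ``+1`` on ``x`` (when the
    disturbance is bursty), ``-f_p``/``-f_i`` on ``z`` for Hill repression,
    and ``±f_d·γ_z/γ_y = ±h`` on ``z``/``y`` for the ratio form.
    """
    if means is None:
        means = solve_steady_means(circuit)
    topo = circuit.topology
    ky = circuit.target.burst_rate
    coeffs: dict[str, float] = {}
    if circuit.has_disturbance:
        coeffs["x"] = 1.0

    if topo is CircuitTopology.OPEN:
        return LinearizedRates(base_rate=ky, coeffs=coeffs)

    if not (means.z > 0.0) or not np.isfinite(means.z):
        raise DegenerateLinearizationError(
            f"controller mean z̄ = {means.z}; cannot linearize around zero")

    if topo in (CircuitTopology.PROPORTIONAL, CircuitTopology.INTEGRAL):
        base = ky * circuit.regulation.hill(means.z)
        coeffs["z"] = -feedback_gain(circuit, means)
        return LinearizedRates(base_rate=base, coeffs=coeffs)

    # derivative: rate = k_y (x/x̄)(z/y)^h
    if not (means.y > 0.0):
        raise DegenerateLinearizationError(
            f"target mean ȳ = {means.y}; cannot linearize around zero")
    h = circuit.regulation.hill_coeff
    base = ky * (means.z / means.y) ** h
    coeffs["z"] = h     # = f_d·γ_z/γ_y
    coeffs["y"] = -h
    return LinearizedRates(base_rate=base, coeffs=coeffs)


# --------------------------------------------------------------------------
# events and generator expansion
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Event:
    """One reaction channel with affine propensity and an i.i.d. jump in a
    single species.  ``m1``/``m2`` are the first/second moments of the jump
    (``-1``/``1`` for deaths).  ``shot=False`` keeps only the drift part of
    the jump in the generator expansion (Liouville limit), which is how a
    source's noise is silenced without touching the means."""

    species: str
    m1: float
    m2: float
    const: float
    lin: Mapping[str, float]
    shot: bool = True


def _build_events(circuit: CircuitModel, lin: LinearizedRates,
                  means: SteadyMeans, *, silence_disturbance: bool = False,
                  silence_controller: bool = False
                  ) -> tuple[list[str], list[_Event]]:
    species: list[str] = []
    x_dynamic = circuit.has_disturbance and not silence_disturbance
    if x_dynamic:
        species.append("x")
    species.append("y")
    if circuit.sensor is not None:
        species.append("z")

    mean_of = {"x": means.x, "y": means.y, "z": means.z}
    events: list[_Event] = []

    if x_dynamic:
        xp = circuit.disturbance.params
        m1, m2 = burst_moments(xp.burst)
        events.append(_Event("x", m1, m2, xp.burst_rate, {}))
        events.append(_Event("x", -1.0, 1.0, 0.0, {"x": xp.decay_rate}))

    # target bursts: base·(1 + Σ c_s (s/s̄ - 1)); coefficients on absent
    # (frozen) species contribute zero deviation and drop out
    active = {s: c for s, c in lin.coeffs.items() if s in species}
    const = lin.base_rate * (1.0 - sum(active.values()))
    linpart = {s: lin.base_rate * c / mean_of[s] for s, c in active.items()}
    m1, m2 = burst_moments(circuit.target.burst)
    events.append(_Event("y", m1, m2, const, linpart))
    events.append(_Event("y", -1.0, 1.0, 0.0,
                         {"y": circuit.target.decay_rate}))

    if circuit.sensor is not None:
        zshot = not silence_controller
        zp = circuit.sensor
        m1, m2 = burst_moments(zp.burst)
        if circuit.topology is CircuitTopology.INTEGRAL:
            # bursty births at rate (k_z/⟨B_z⟩)·y, zero-order decay k_z·y_set
            events.append(_Event("z", m1, m2, 0.0,
                                 {"y": zp.burst_rate / m1}, zshot))
            events.append(_Event(
                "z", -1.0, 1.0,
                zp.burst_rate * circuit.regulation.set_point, {}, zshot))
        else:
            events.append(_Event("z", m1, m2, 0.0,
                                 {"y": zp.burst_rate}, zshot))
            events.append(_Event("z", -1.0, 1.0, 0.0,
                                 {"z": zp.decay_rate}, zshot))
    return species, events


def _moment_indices(n: int) -> list[tuple[int, ...]]:
    """Means first, then second moments in lexicographic order."""
    out = [tuple(1 if j == i else 0 for j in range(n)) for i in range(n)]
    for i in range(n):
        for j in range(i, n):
            m = [0] * n
            m[i] += 1
            m[j] += 1
            out.append(tuple(m))
    return out


def _index_label(m: tuple[int, ...], species: Sequence[str]) -> str:
    return "".join(s * k for s, k in zip(species, m))


@dataclass
class MomentSystem:
    """Linear moment dynamics ``μ̇ = â + Aμ`` over first and second
    uncentered moments of the present species.

    ``scales`` holds the stationary-mean monomials ``∏ s̄^m`` used to
    precondition the stationary solve (moments span many orders of
    magnitude for high-copy circuits)."""

    species: list[str]
    labels: list[str]
    indices: list[tuple[int, ...]]
    a: np.ndarray
    A: np.ndarray
    scales: Optional[np.ndarray] = None
    _pos: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._pos = {lbl: i for i, lbl in enumerate(self.labels)}

    def loc(self, label: str) -> int:
        return self._pos[label]

    def rhs(self, mu: np.ndarray) -> np.ndarray:
        """ODE right-hand side ``â + Aμ`` (transient moment dynamics)."""
        return self.a + self.A @ mu

    def to_text(self) -> str:
        """Plain-text dump (labels + dense rows) for debugging and
        cross-language checks."""
        lines = ["# moments: " + " ".join(self.labels)]
        for i, lbl in enumerate(self.labels):
            row = " ".join(f"{v:.17g}" for v in self.A[i])
            lines.append(f"d<{lbl}>/dt = {self.a[i]:.17g} | {row}")
        return "\n".join(lines)


def _expand_event(event: _Event, m: tuple[int, ...], species: Sequence[str],
                  sp_index: Mapping[str, int]) -> dict[tuple[int, ...], float]:
    """Rate × expected change of the monomial ``m``, as a polynomial in the
    state (multi-index -> coefficient)."""
    s = sp_index[event.species]
    ms = m[s]
    if ms == 0:
        return {}
    # expected change of the monomial under the jump
    drop1 = list(m)
    drop1[s] -= 1
    change: dict[tuple[int, ...], float] = {}
    if ms == 1:
        change[tuple(drop1)] = event.m1
    else:  # ms == 2: (s+δ)² - s² = 2sδ + δ²
        change[tuple(drop1)] = 2.0 * event.m1
        if event.shot:
            drop2 = list(m)
            drop2[s] -= 2
            change[tuple(drop2)] = event.m2
    # affine rate as a polynomial
    zero = tuple(0 for _ in m)
    rate: dict[tuple[int, ...], float] = {zero: event.const}
    for sp, c in event.lin.items():
        mi = tuple(1 if j == sp_index[sp] else 0 for j in range(len(m)))
        rate[mi] = rate.get(mi, 0.0) + c
    out: dict[tuple[int, ...], float] = {}
    for mi1, c1 in change.items():
        if c1 == 0.0:
            continue
        for mi2, c2 in rate.items():
            if c2 == 0.0:
                continue
            mi = tuple(a + b for a, b in zip(mi1, mi2))
            out[mi] = out.get(mi, 0.0) + c1 * c2
    return out


def assemble_moment_system(circuit: CircuitModel,
                           lin: LinearizedRates | None = None,
                           means: SteadyMeans | None = None, *,
                           silence_disturbance: bool = False,
                           silence_controller: bool = False) -> MomentSystem:
    """Assemble ``μ̇ = â + Aμ`` for the linearized circuit.

    Every propensity is affine after linearization, so second-order
    monomials close exactly; a product exceeding second order would be an
    internal contract violation and raises.
    """
    if means is None:
        means = solve_steady_means(circuit)
    if lin is None:
        lin = linearize(circuit, means)
    species, events = _build_events(
        circuit, lin, means, silence_disturbance=silence_disturbance,
        silence_controller=silence_controller)
    sp_index = {s: i for i, s in enumerate(species)}
    indices = _moment_indices(len(species))
    pos = {mi: i for i, mi in enumerate(indices)}
    n = len(indices)
    a = np.zeros(n)
    A = np.zeros((n, n))
    for i, m in enumerate(indices):
        for ev in events:
            for mi, c in _expand_event(ev, m, species, sp_index).items():
                order = sum(mi)
                if order == 0:
                    a[i] += c
                elif order <= 2:
                    A[i, pos[mi]] += c
                else:  # pragma: no cover
                    raise AssertionError(
                        "non-affine propensity reached moment assembly")
    labels = [_index_label(m, species) for m in indices]
    mean_of = {"x": means.x, "y": means.y, "z": means.z}
    scales = np.array([
        np.prod([max(mean_of[s], 1.0) ** k for s, k in zip(species, m)])
        for m in indices])
    return MomentSystem(species=species, labels=labels, indices=indices,
                        a=a, A=A, scales=scales)


# --------------------------------------------------------------------------
# stationary solve
# --------------------------------------------------------------------------

def steady_state_moments(sys: MomentSystem, *, hurwitz_tol: float = 1e-9,
                         var_tol: float = 1e-8) -> np.ndarray:
    """Solve ``Aμ̄ = -â`` after verifying ``A`` is Hurwitz.

    Raises :class:`StabilityError` naming the offending eigenvalue if any
    real part exceeds ``-hurwitz_tol`` (borderline systems are rejected
    rather than solved), and :class:`NumericalConditioningError` if the
    residual or an implied variance is out of tolerance.
    """
    eig = np.linalg.eigvals(sys.A)
    worst = eig[np.argmax(eig.real)]
    if worst.real > -hurwitz_tol:
        raise StabilityError(
            f"moment dynamics not Hurwitz: eigenvalue {worst} has real part "
            f"> -{hurwitz_tol}")
    # precondition with the diagonal similarity D = diag(mean monomials):
    # the scaled unknowns are all O(1), which keeps the solve accurate for
    # high-copy circuits whose raw moments span many orders of magnitude
    d = sys.scales if sys.scales is not None else np.ones_like(sys.a)
    A_s = sys.A * (d[None, :] / d[:, None])
    a_s = sys.a / d
    lu = lu_factor(A_s)
    mu_s = lu_solve(lu, -a_s)
    # one round of iterative refinement: the stationary residual then sits
    # at machine level, which matters because noise components are later
    # recovered by differencing nearby solves
    mu_s -= lu_solve(lu, a_s + A_s @ mu_s)
    mu = mu_s * d
    resid = np.linalg.norm(a_s + A_s @ mu_s)
    scale = np.linalg.norm(A_s) * np.linalg.norm(mu_s) + np.linalg.norm(a_s)
    if resid > 1e-10 * max(scale, 1.0):
        raise NumericalConditioningError(
            f"stationary residual {resid} above tolerance")
    for s in sys.species:
        mean = mu[sys.loc(s)]
        var = mu[sys.loc(s + s)] - mean * mean
        if var < -var_tol * max(mean * mean, 1.0):
            raise NumericalConditioningError(
                f"negative stationary variance for {s}: {var}")
    return mu


def _cv2_of(sys: MomentSystem, mu: np.ndarray, s: str = "y") -> float:
    mean = mu[sys.loc(s)]
    var = mu[sys.loc(s + s)] - mean * mean
    return var / (mean * mean)


# --------------------------------------------------------------------------
# noise decomposition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseDecomposition:
    """Additive split of the target's stationary ``CV²_Y`` into the
    contribution of its own bursty expression (intrinsic), the upstream
    disturbance (external), and the controller species' shot noise
    (controller).  ``total = intrinsic + external + controller``."""

    intrinsic: float
    external: float
    controller: float

    @property
    def total(self) -> float:
        return self.intrinsic + self.external + self.controller

    def as_dict(self) -> dict[str, float]:
        return {"intrinsic": self.intrinsic, "external": self.external,
                "controller": self.controller, "total": self.total}


def _clamp(v: float, tol: float = 1e-12) -> float:
    return 0.0 if -tol < v < 0.0 else v


def decompose_noise(circuit: CircuitModel, *, means: SteadyMeans | None = None
                    ) -> NoiseDecomposition:
    """Three moment solves, components recovered by differencing.

    (i) the full system; (ii) disturbance silenced (``x ≡ x̄``); (iii)
    additionally the controller's shot noise silenced.  Then external =
    (i)−(ii), controller = (ii)−(iii), intrinsic = (iii); the total equals
    the full solve exactly because stationary covariance is additive in the
    independent shot-noise sources of a linear system.
    """
    if means is None:
        means = solve_steady_means(circuit)
    lin = linearize(circuit, means)

    def solve(**kw) -> float:
        sys = assemble_moment_system(circuit, lin, means, **kw)
        return _cv2_of(sys, steady_state_moments(sys))

    total = solve()
    if circuit.has_disturbance:
        no_x = solve(silence_disturbance=True)
    else:
        no_x = total
    if circuit.sensor is not None:
        intrinsic = solve(silence_disturbance=True, silence_controller=True)
    else:
        intrinsic = no_x
    return NoiseDecomposition(intrinsic=_clamp(intrinsic),
                              external=_clamp(total - no_x),
                              controller=_clamp(no_x - intrinsic))
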