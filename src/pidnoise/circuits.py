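"""Circuit definitions: burst-size laws, species parameters, regulation
functions, topologies, deterministic steady states and feedback gains.

The modeling frame is a set of coupled bursty birth--death processes.  A
species ``S`` is produced in bursts arriving at a Poisson rate (the *burst
frequency*); each burst adds an i.i.d. random number of molecules (the
*burst size* ``B``), and molecules decay one at a time.  The target protein
``Y`` may be modulated by an upstream disturbance species ``X`` (its burst
frequency is scaled by ``x/x̄``) and regulated by a controller species ``Z``
in one of three ways:

``proportional``
    ``Z`` is a noisy sensor produced at rate ``k_z·y`` with first-order
    decay; it represses ``Y``'s burst frequency through a decreasing Hill
    function ``g(z) = 1/(1+(z/z_c)^h)``.
``integral``
    ``Z`` is a stochastic integrator: produced in bursts at rate
    ``k_z·y/⟨B_z⟩`` and degraded by a *zero-order* process at constant rate
    ``k_z·y_set`` (a saturated protease), so ``⟨z⟩`` integrates the error
    ``y - y_set``.  ``Z`` represses ``Y`` through the same Hill form.
``derivative``
    an incoherent feedforward loop folded back on ``Y``: ``Y`` activates
    ``Z`` (a delayed copy of itself) and the burst frequency of ``Y`` is
    proportional to ``(z/y)^h``, i.e. ``Z`` activates while ``Y``
    self-represses with matched Hill coefficients.

Everything here is deterministic bookkeeping: moments of burst laws, Hill
functions, fixed points of the mean equations, and log-sensitivity gains.
Stochastic treatments live in :mod:`pidnoise.lna` (moment dynamics) and
:mod:`pidnoise.ssa` (exact simulation).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import brentq

from .exceptions import InvalidParameterError

__all__ = [
    "BurstKind",
    "BurstDistribution",
    "SpeciesParams",
    "DisturbanceMode",
    "DisturbanceSpec",
    "RegulationVariant",
    "RegulationSpec",
    "CircuitTopology",
    "CircuitModel",
    "SteadyMeans",
    "burst_moments",
    "regulation_value",
    "solve_steady_means",
    "feedback_gain",
    "static_sensitivity",
    "circuit_to_dict",
    "circuit_from_dict",
    "save_circuit",
    "load_circuit",
    "load_fixture",
    "list_fixtures",
]


# --------------------------------------------------------------------------
# burst-size distributions
# --------------------------------------------------------------------------

class BurstKind(str, enum.Enum):
    """Supported burst-size laws on the support {1, 2, ...}."""

    DETERMINISTIC = "deterministic"
    SHIFTED_GEOMETRIC = "shifted_geometric"


@dataclass(frozen=True)
class BurstDistribution:
    """Burst-size law ``B`` with closed-form first and second moments.

    Parameters
    ----------
    kind
        ``deterministic`` (every burst adds exactly ``mean_size`` molecules,
        which must be a positive integer) or ``shifted_geometric``
        (``P(B=j) = (1-p)^{j-1} p`` on {1, 2, ...} with ``p = 1/mean_size``,
        the law observed for protein bursts in E. coli).
    mean_size
        ``⟨B⟩ >= 1`` in molecules.

    Notes
    -----
    For the shifted geometric, ``⟨B²⟩ = 2⟨B⟩² - ⟨B⟩``; at ``⟨B⟩ = 1`` it
    degenerates to the deterministic unit burst (Poisson birth--death).
    """

    kind: BurstKind
    mean_size: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", BurstKind(self.kind))
        if not (self.mean_size >= 1.0) or not math.isfinite(self.mean_size):
            raise InvalidParameterError(
                f"burst mean size must be >= 1, got {self.mean_size}")
        if self.kind is BurstKind.DETERMINISTIC and abs(
                self.mean_size - round(self.mean_size)) > 1e-9:
            raise InvalidParameterError(
                "deterministic burst size must be a positive integer, "
                f"got {self.mean_size}")

    @property
    def moments(self) -> tuple[float, float]:
        """``(⟨B⟩, ⟨B²⟩)`` from the distribution's closed form."""
        b = self.mean_size
        if self.kind is BurstKind.DETERMINISTIC:
            b = float(round(b))
            return b, b * b
        return b, 2.0 * b * b - b

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw burst sizes from {1, 2, ...}."""
        if self.kind is BurstKind.DETERMINISTIC:
            b = int(round(self.mean_size))
            return b if size is None else np.full(size, b, dtype=np.int64)
        p = 1.0 / self.mean_size
        return rng.geometric(p, size=size)


def burst_moments(dist: BurstDistribution) -> tuple[float, float]:
    """Return ``(⟨B⟩, ⟨B²⟩)`` for a burst-size distribution."""
    return dist.moments


# --------------------------------------------------------------------------
# species, disturbance, regulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesParams:
    """Kinetic parameters of one bursty birth--death species.

    ``burst_rate`` is the Poisson burst-arrival frequency ``k`` (1/time),
    ``decay_rate`` the per-molecule degradation rate ``γ`` (1/time).  A
    zero burst rate is a degenerate but legitimate silent gene.  For the
    integral topology the controller decays by a zero-order process at
    rate ``k_z·y_set``, so its ``decay_rate`` is inert (kept positive for
    uniformity).
    """

    burst_rate: float
    decay_rate: float
    burst: BurstDistribution

    def __post_init__(self) -> None:
        if not (self.burst_rate >= 0.0 and math.isfinite(self.burst_rate)):
            raise InvalidParameterError(
                f"burst_rate must be non-negative, got {self.burst_rate}")
        if not (self.decay_rate > 0.0 and math.isfinite(self.decay_rate)):
            raise InvalidParameterError(
                f"decay_rate must be positive, got {self.decay_rate}")

    @property
    def open_loop_mean(self) -> float:
        """Unregulated stationary mean ``k⟨B⟩/γ``."""
        return self.burst_rate * self.burst.moments[0] / self.decay_rate


class DisturbanceMode(str, enum.Enum):
    NONE = "none"
    BURSTY = "bursty"


@dataclass(frozen=True)
class DisturbanceSpec:
    """Upstream disturbance ``X`` modulating the target's burst frequency.

    ``bursty`` mode gives ``X`` its own bursty birth--death dynamics with
    stationary mean ``x̄ = k_x⟨B_x⟩/γ_x``; ``none`` pins ``x(t) ≡ level``
    with probability one (the burst frequency scale ``x/x̄`` is then 1).
    """

    mode: DisturbanceMode
    params: Optional[SpeciesParams] = None
    level: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", DisturbanceMode(self.mode))
        if self.mode is DisturbanceMode.BURSTY and self.params is None:
            raise InvalidParameterError("bursty disturbance requires params")
        if self.mode is DisturbanceMode.NONE and not (self.level > 0):
            raise InvalidParameterError(
                f"constant disturbance level must be positive, got {self.level}")

    @property
    def mean(self) -> float:
        """Stationary mean ``x̄`` (analytic, never a simulation estimate)."""
        if self.mode is DisturbanceMode.BURSTY:
            return self.params.open_loop_mean
        return self.level

    @property
    def cv2(self) -> float:
        """Stationary ``CV²_X = (⟨B_x⟩+⟨B_x²⟩)/(2⟨B_x⟩x̄)``; zero if constant."""
        if self.mode is DisturbanceMode.NONE:
            return 0.0
        m1, m2 = self.params.burst.moments
        return (m1 + m2) / (2.0 * m1 * self.mean)


class RegulationVariant(str, enum.Enum):
    OPEN_LOOP = "open_loop"
    HILL_REPRESSION = "hill_repression"
    ZERO_ORDER_INTEGRAL = "zero_order_integral"
    RATIO_DERIVATIVE = "ratio_derivative"


@dataclass(frozen=True)
class RegulationSpec:
    """How the controller shapes the target's burst frequency.

    ``hill_repression`` and ``zero_order_integral`` multiply the frequency
    by ``g(z) = 1/(1+(z/z_c)^h)``; ``ratio_derivative`` multiplies by
    ``(z/y)^h`` (the matched-Hill incoherent-feedforward limit);
    ``open_loop`` leaves it untouched.  ``set_point`` is the integral
    topology's target mean ``y_set`` (it fixes the zero-order decay rate
    ``k_z·y_set``).
    """

    variant: RegulationVariant
    half_max: Optional[float] = None       # z_c, molecules
    hill_coeff: float = 1.0                # h, dimensionless
    set_point: Optional[float] = None      # y_set, molecules

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", RegulationVariant(self.variant))
        v = self.variant
        if v in (RegulationVariant.HILL_REPRESSION,
                 RegulationVariant.ZERO_ORDER_INTEGRAL):
            if self.half_max is None or not (self.half_max > 0):
                raise InvalidParameterError(
                    f"{v.value} requires a positive half_max, got {self.half_max}")
        if v is not RegulationVariant.OPEN_LOOP and not (self.hill_coeff > 0):
            raise InvalidParameterError(
                f"hill_coeff must be positive, got {self.hill_coeff}")
        if v is RegulationVariant.ZERO_ORDER_INTEGRAL:
            if self.set_point is None or not (self.set_point > 0):
                raise InvalidParameterError(
                    f"integral regulation requires a positive set_point, "
                    f"got {self.set_point}")

    def hill(self, z: float) -> float:
        """Repression factor ``g(z) = 1/(1+(z/z_c)^h)``."""
        if z <= 0.0:
            return 1.0
        return 1.0 / (1.0 + (z / self.half_max) ** self.hill_coeff)


def regulation_value(reg: RegulationSpec, y: float, z: float) -> float:
    """Burst-frequency multiplier of the regulation at counts ``(y, z)``.

    Total on ``y, z >= 0``.  The ratio form evaluates ``(z/max(y,1))^h``:
    the propensity ``(z/y)^h`` is undefined at ``y = 0`` and the unit floor
    keeps it finite; the substitution is invisible in the small-noise
    regime where the closed-form analysis holds.
    """
    v = reg.variant
    if v is RegulationVariant.OPEN_LOOP:
        return 1.0
    if v in (RegulationVariant.HILL_REPRESSION,
             RegulationVariant.ZERO_ORDER_INTEGRAL):
        return reg.hill(z)
    # ratio_derivative
    y_eff = max(y, 1.0)
    if z <= 0.0:
        return 0.0
    return (z / y_eff) ** reg.hill_coeff


# --------------------------------------------------------------------------
# circuit model
# --------------------------------------------------------------------------

class CircuitTopology(str, enum.Enum):
    OPEN = "open"
    PROPORTIONAL = "proportional"
    INTEGRAL = "integral"
    DERIVATIVE = "derivative"


_TOPOLOGY_REGULATION = {
    CircuitTopology.OPEN: RegulationVariant.OPEN_LOOP,
    CircuitTopology.PROPORTIONAL: RegulationVariant.HILL_REPRESSION,
    CircuitTopology.INTEGRAL: RegulationVariant.ZERO_ORDER_INTEGRAL,
    CircuitTopology.DERIVATIVE: RegulationVariant.RATIO_DERIVATIVE,
}


@dataclass(frozen=True)
class CircuitModel:
    """Full specification of a (possibly disturbed, possibly regulated)
    gene circuit: disturbance ``X``, target ``Y``, controller ``Z`` and the
    feedback topology."""

    topology: CircuitTopology
    disturbance: DisturbanceSpec
    target: SpeciesParams
    regulation: RegulationSpec = field(
        default_factory=lambda: RegulationSpec(RegulationVariant.OPEN_LOOP))
    sensor: Optional[SpeciesParams] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "topology", CircuitTopology(self.topology))
        expected = _TOPOLOGY_REGULATION[self.topology]
        if self.regulation.variant is not expected:
            raise InvalidParameterError(
                f"{self.topology.value} topology requires regulation variant "
                f"{expected.value}, got {self.regulation.variant.value}")
        if self.topology is CircuitTopology.OPEN:
            if self.sensor is not None:
                raise InvalidParameterError("open topology has no sensor")
        elif self.sensor is None:
            raise InvalidParameterError(
                f"{self.topology.value} topology requires a sensor species")

    @property
    def has_disturbance(self) -> bool:
        return self.disturbance.mode is DisturbanceMode.BURSTY


@dataclass(frozen=True)
class SteadyMeans:
    """Deterministic stationary means (molecules).  ``z`` is NaN when the
    circuit has no controller species."""

    x: float
    y: float
    z: float = float("nan")


# --------------------------------------------------------------------------
# steady-state means
# --------------------------------------------------------------------------

def solve_steady_means(circuit: CircuitModel, *, rtol: float = 1e-12
                       ) -> SteadyMeans:
    """Stationary means of the deterministic (mean-field) dynamics.

    open
        ``ȳ = k_y⟨B_y⟩/γ_y``.
    proportional
        the unique root of ``k_y·g(k_z⟨B_z⟩ȳ/γ_z)·⟨B_y⟩ = γ_y·ȳ``; since
        ``g <= 1`` the root is bracketed by ``[0, k_y⟨B_y⟩/γ_y]`` and found
        by Brent's method to relative tolerance ``rtol``.
    integral
        ``ȳ = y_set`` by construction; ``z̄`` inverts the Hill repression so
        the burst frequency balances decay, which requires
        ``y_set < k_y⟨B_y⟩/γ_y`` (repression can only lower the mean).
    derivative
        ``ȳ = (k_y⟨B_y⟩/γ_y)(k_z⟨B_z⟩/γ_z)^h`` and ``z̄ = k_z⟨B_z⟩ȳ/γ_z``.
    """
    xbar = circuit.disturbance.mean
    y_open = circuit.target.open_loop_mean
    topo = circuit.topology

    if topo is CircuitTopology.OPEN:
        return SteadyMeans(x=xbar, y=y_open)

    ky = circuit.target.burst_rate
    gy = circuit.target.decay_rate
    by1, _ = circuit.target.burst.moments
    bz1, _ = circuit.sensor.burst.moments
    reg = circuit.regulation

    if topo is CircuitTopology.PROPORTIONAL:
        c = circuit.sensor.burst_rate * bz1 / circuit.sensor.decay_rate
        f = lambda y: ky * reg.hill(c * y) * by1 - gy * y
        hi = y_open
        if f(hi) > 0.0:  # pragma: no cover - g<=1 makes this unreachable
            for _ in range(64):
                hi *= 2.0
                if f(hi) <= 0.0:
                    break
            else:
                raise InvalidParameterError(
                    "steady-mean bracketing failed after expansion; "
                    f"f({hi}) = {f(hi)}")
        ybar = brentq(f, 0.0, hi, xtol=1e-14 * max(1.0, hi), rtol=8.9e-16)
        return SteadyMeans(x=xbar, y=ybar, z=c * ybar)

    if topo is CircuitTopology.INTEGRAL:
        y_set = reg.set_point
        g_star = gy * y_set / (ky * by1)  # required repression level
        if not (0.0 < g_star < 1.0):
            raise InvalidParameterError(
                f"integral set point {y_set} is not below the open-loop mean "
                f"{y_open}; repression cannot reach it")
        zbar = reg.half_max * (1.0 / g_star - 1.0) ** (1.0 / reg.hill_coeff)
        return SteadyMeans(x=xbar, y=y_set, z=zbar)

    # derivative
    h = reg.hill_coeff
    ratio = circuit.sensor.burst_rate * bz1 / circuit.sensor.decay_rate
    ybar = y_open * ratio ** h
    return SteadyMeans(x=xbar, y=ybar, z=ratio * ybar)


# --------------------------------------------------------------------------
# gains and sensitivities
# --------------------------------------------------------------------------

def feedback_gain(circuit: CircuitModel, means: SteadyMeans | None = None
                  ) -> float:
    """Dimensionless feedback gain at the operating point.

    For Hill repression (proportional and integral topologies) this is the
    log-sensitivity ``f = -(z̄/g(z̄))·g'(z̄) = h·(1 - g(z̄))``, strictly below
    the Hill coefficient ``h`` for finite ``z̄``.  For the derivative
    topology ``f_d = h·γ_y/γ_z``.  Open loop has gain 0.
    """
    topo = circuit.topology
    if topo is CircuitTopology.OPEN:
        return 0.0
    if topo is CircuitTopology.DERIVATIVE:
        return (circuit.regulation.hill_coeff
                * circuit.target.decay_rate / circuit.sensor.decay_rate)
    if means is None:
        means = solve_steady_means(circuit)
    reg = circuit.regulation
    return reg.hill_coeff * (1.0 - reg.hill(means.z))


def static_sensitivity(circuit: CircuitModel, *, rel_step: float = 1e-4
                       ) -> float:
    """Static log-sensitivity ``S = (k_y/ȳ)·dȳ/dk_y`` of the closed-loop
    mean to the environmental input rate, by centered finite difference
    over two steady-state solves at ``k_y(1 ± rel_step)``.

    Analytically ``S = 1`` for the open and derivative topologies (mean
    proportional to ``k_y``), ``S = 1/(1+f_p)`` for proportional feedback,
    and ``S = 0`` for integral feedback (perfect adaptation).
    """
    ky = circuit.target.burst_rate
    y0 = solve_steady_means(circuit).y

    def y_at(scale: float) -> float:
        c = replace(circuit, target=replace(circuit.target,
                                            burst_rate=ky * scale))
        return solve_steady_means(c).y

    return (y_at(1.0 + rel_step) - y_at(1.0 - rel_step)) / (2.0 * rel_step * y0)


# --------------------------------------------------------------------------
# config (YAML) round-trip and figure fixtures
# --------------------------------------------------------------------------

def _burst_to_dict(b: BurstDistribution) -> dict:
    return {"kind": b.kind.value, "mean_size": b.mean_size}


def _species_to_dict(s: SpeciesParams) -> dict:
    return {"burst_rate": s.burst_rate, "decay_rate": s.decay_rate,
            "burst": _burst_to_dict(s.burst)}


def _species_from_dict(d: dict) -> SpeciesParams:
    return SpeciesParams(burst_rate=float(d["burst_rate"]),
                         decay_rate=float(d["decay_rate"]),
                         burst=BurstDistribution(**d["burst"]))


def circuit_to_dict(circuit: CircuitModel) -> dict:
    """Plain-dict (YAML-ready) form of a circuit."""
    dist = circuit.disturbance
    d: dict = {
        "topology": circuit.topology.value,
        "disturbance": {"mode": dist.mode.value},
        "target": _species_to_dict(circuit.target),
        "regulation": {"variant": circuit.regulation.variant.value},
    }
    if dist.mode is DisturbanceMode.BURSTY:
        d["disturbance"]["params"] = _species_to_dict(dist.params)
    else:
        d["disturbance"]["level"] = dist.level
    reg = circuit.regulation
    if reg.half_max is not None:
        d["regulation"]["half_max"] = reg.half_max
    d["regulation"]["hill_coeff"] = reg.hill_coeff
    if reg.set_point is not None:
        d["regulation"]["set_point"] = reg.set_point
    if circuit.sensor is not None:
        d["sensor"] = _species_to_dict(circuit.sensor)
    return d


def circuit_from_dict(d: dict) -> CircuitModel:
    """Inverse of :func:`circuit_to_dict`."""
    dist_d = d["disturbance"]
    mode = DisturbanceMode(dist_d["mode"])
    if mode is DisturbanceMode.BURSTY:
        dist = DisturbanceSpec(mode=mode,
                               params=_species_from_dict(dist_d["params"]))
    else:
        dist = DisturbanceSpec(mode=mode, level=float(dist_d.get("level", 1.0)))
    reg_d = dict(d["regulation"])
    reg = RegulationSpec(
        variant=RegulationVariant(reg_d["variant"]),
        half_max=(None if reg_d.get("half_max") is None
                  else float(reg_d["half_max"])),
        hill_coeff=float(reg_d.get("hill_coeff", 1.0)),
        set_point=(None if reg_d.get("set_point") is None
                   else float(reg_d["set_point"])),
    )
    sensor = _species_from_dict(d["sensor"]) if "sensor" in d else None
    return CircuitModel(topology=CircuitTopology(d["topology"]),
                        disturbance=dist,
                        target=_species_from_dict(d["target"]),
                        regulation=reg, sensor=sensor)


def save_circuit(circuit: CircuitModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(circuit_to_dict(circuit),
                                         sort_keys=False))


def load_circuit(path: str | Path) -> CircuitModel:
    doc = yaml.safe_load(Path(path).read_text())
    # fixture files may wrap the circuit beside sweep metadata
    if "circuit" in doc and "topology" not in doc:
        doc = doc["circuit"]
    return circuit_from_dict(doc)


def _fixture_dir() -> Path:
    return Path(__file__).parent / "fixtures"


def list_fixtures() -> list[str]:
    return sorted(p.stem for p in _fixture_dir().glob("*.yaml"))


def load_fixture(name: str) -> dict:
    """Load a named figure fixture (e.g. ``fig5``) as a raw dict with keys
    like ``circuit``, ``noise_inputs``, ``sweep``."""
    path = _fixture_dir() / f"{name}.yaml"
    if not path.exists():
        raise FileNotFoundError(
            f"no fixture {name!r}; available: {list_fixtures()}")
    return yaml.safe_load(path.read_text())
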