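"""Closed-form noise formulas, limits, optimal gains and extremum
identities for the open-loop, proportional, integral and derivative
circuits.

All functions are pure and total over valid :class:`NoiseInputs`; each one
is cross-validated against the generator-assembled moment solver in the
test suite (the moment solver is the authority if a transcription and the
generator ever disagree).

Notation: ``CV²_int`` is the target's own bursty-expression noise
``(⟨B_y⟩+⟨B_y²⟩)/(2⟨B_y⟩ȳ)``, ``CV²_X`` the stationary disturbance noise,
``CV²_Z = (⟨B_z⟩+⟨B_z²⟩)/(2⟨B_z⟩z̄)`` the controller's own expression
noise, and ``f`` the dimensionless feedback gain (``f_p``, ``f_i`` or
``f_d`` depending on topology).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .circuits import (
    CircuitModel,
    CircuitTopology,
    SteadyMeans,
    burst_moments,
    feedback_gain,
    solve_steady_means,
)
from .exceptions import InvalidParameterError, NoInteriorMinimumError
from .lna import NoiseDecomposition

__all__ = [
    "NoiseInputs",
    "OptimalGainMode",
    "IntegralDesign",
    "noise_inputs_from_circuit",
    "cv2_open_loop",
    "cv2_proportional",
    "cv2_proportional_fast_sensor",
    "optimal_gain_proportional",
    "noise_floor_burst_events",
    "cv2_integral",
    "integral_peak_disturbance_rate",
    "optimal_gain_integral",
    "cv2_derivative",
    "cv2_for_topology",
]


@dataclass(frozen=True)
class NoiseInputs:
    """Dimensionless noise magnitudes, rates and gain entering the closed
    forms.  ``ybar``/``zbar``/``k_z`` are only needed by the integral
    formulas; ``gamma_x`` is irrelevant (but must stay positive) when
    ``cv2_x = 0``."""

    cv2_int: float
    cv2_x: float = 0.0
    cv2_z: float = 0.0
    gamma_x: float = 1.0
    gamma_y: float = 1.0
    gamma_z: float = 1.0
    k_z: float = 1.0
    gain: float = 0.0
    ybar: float = float("nan")
    zbar: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("cv2_int", "cv2_x", "cv2_z"):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("gamma_x", "gamma_y", "gamma_z", "k_z"):
            if not getattr(self, name) > 0.0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.gain < 0.0:
            raise InvalidParameterError("gain must be >= 0")


class OptimalGainMode(str, enum.Enum):
    EXTERNAL_ONLY = "external_only"
    INTRINSIC_ONLY = "intrinsic_only"


class IntegralDesign(str, enum.Enum):
    ZERO_ORDER = "zero_order"          # bursty births, zero-order decay
    AUTOCATALYTIC = "autocatalytic"    # self-activating Z degraded by Y


def noise_inputs_from_circuit(circuit: CircuitModel,
                              means: SteadyMeans | None = None) -> NoiseInputs:
    """Evaluate the noise-input magnitudes at a circuit's operating point."""
    if means is None:
        means = solve_steady_means(circuit)
    m1, m2 = burst_moments(circuit.target.burst)
    cv2_int = (m1 + m2) / (2.0 * m1 * means.y)
    cv2_x = circuit.disturbance.cv2
    gamma_x = (circuit.disturbance.params.decay_rate
               if circuit.has_disturbance else 1.0)
    cv2_z = 0.0
    gamma_z = 1.0
    k_z = 1.0
    if circuit.sensor is not None:
        z1, z2 = burst_moments(circuit.sensor.burst)
        cv2_z = (z1 + z2) / (2.0 * z1 * means.z)
        gamma_z = circuit.sensor.decay_rate
        k_z = circuit.sensor.burst_rate
    return NoiseInputs(cv2_int=cv2_int, cv2_x=cv2_x, cv2_z=cv2_z,
                       gamma_x=gamma_x, gamma_y=circuit.target.decay_rate,
                       gamma_z=gamma_z, k_z=k_z,
                       gain=feedback_gain(circuit, means),
                       ybar=means.y, zbar=means.z)


# --------------------------------------------------------------------------
# open loop
# --------------------------------------------------------------------------

def cv2_open_loop(inputs: NoiseInputs) -> NoiseDecomposition:
    """Two-component open-loop noise: the external term is the disturbance
    noise filtered by the time-averaging factor ``γ_y/(γ_y+γ_x)``."""
    gy, gx = inputs.gamma_y, inputs.gamma_x
    return NoiseDecomposition(
        intrinsic=inputs.cv2_int,
        external=gy / (gy + gx) * inputs.cv2_x,
        controller=0.0)


# --------------------------------------------------------------------------
# proportional controller
# --------------------------------------------------------------------------

def cv2_proportional(inputs: NoiseInputs) -> NoiseDecomposition:
    """Three-component noise of the Hill-repression proportional loop.

    The intrinsic term decreases with gain toward the floor
    ``γ_y CV²_int/(γ_y+γ_z)``, the external term decreases to zero, and the
    sensor term grows as ``f_p²``; at ``f_p = 0`` the split reduces to the
    open loop.
    """
    f = inputs.gain
    gx, gy, gz = inputs.gamma_x, inputs.gamma_y, inputs.gamma_z
    intrinsic = ((gy + f * gy + gz) / ((f + 1.0) * (gy + gz))
                 * inputs.cv2_int)
    external = (gy * ((gz + gy) * (gx + gz) + gx * gy * f)
                / ((1.0 + f) * (gy + gz)
                   * ((gx + gy) * (gx + gz) + gy * gz * f))
                * inputs.cv2_x)
    sensor = f * f * gy / ((f + 1.0) * (gy + gz)) * inputs.cv2_z
    return NoiseDecomposition(intrinsic=intrinsic, external=external,
                              controller=sensor)


def cv2_proportional_fast_sensor(inputs: NoiseInputs) -> NoiseDecomposition:
    """Fast-sensor / slow-disturbance limit (``γ_z ≫ γ_y``, ``γ_x ≪ γ_y``)
    of :func:`cv2_proportional`: intrinsic ``CV²_int/(1+f_p)``, external
    ``CV²_X/(1+f_p)²``, sensor ``f_p²γ_y CV²_Z/((f_p+1)γ_z)``."""
    f = inputs.gain
    return NoiseDecomposition(
        intrinsic=inputs.cv2_int / (1.0 + f),
        external=inputs.cv2_x / (1.0 + f) ** 2,
        controller=f * f * inputs.gamma_y * inputs.cv2_z
        / ((f + 1.0) * inputs.gamma_z))


def optimal_gain_proportional(inputs: NoiseInputs,
                              mode: OptimalGainMode | str
                              ) -> tuple[float, float]:
    """Strong-feedback (``f_p ≫ 1``) optimum of the fast-sensor noise.

    ``external_only`` (``CV²_int = 0``): minimizing
    ``CV²_X/f² + f·γ_y CV²_Z/γ_z`` gives
    ``f* = (2 CV²_X γ_z/(CV²_Z γ_y))^{1/3}`` and minimum
    ``3·(CV_X CV²_Z γ_y/(2γ_z))^{2/3}``, so the floor scales as
    ``CV_X^{2/3}``.

    ``intrinsic_only`` (``CV²_X = 0``): minimizing
    ``CV²_int/f + f·γ_y CV²_Z/γ_z`` gives
    ``f* = (CV_int/CV_Z)·√(γ_z/γ_y)`` and minimum
    ``2 CV_int CV_Z √(γ_y/γ_z)``.

    Both are the exact extremizers of the leading strong-feedback terms of
    the fast-sensor expression (re-derived by elementary calculus and
    pinned by a numeric argmin oracle in the tests).
    """
    mode = OptimalGainMode(mode)
    if inputs.cv2_z <= 0.0:
        raise NoInteriorMinimumError(
            "CV²_Z = 0: noise is monotone decreasing in the gain, no "
            "interior minimum")
    gy, gz = inputs.gamma_y, inputs.gamma_z
    if mode is OptimalGainMode.EXTERNAL_ONLY:
        f_opt = (2.0 * inputs.cv2_x * gz / (inputs.cv2_z * gy)) ** (1.0 / 3.0)
        min_cv2 = 3.0 * (math.sqrt(inputs.cv2_x) * inputs.cv2_z * gy
                         / (2.0 * gz)) ** (2.0 / 3.0)
    else:
        cv_int = math.sqrt(inputs.cv2_int)
        cv_z = math.sqrt(inputs.cv2_z)
        f_opt = (cv_int / cv_z) * math.sqrt(gz / gy)
        min_cv2 = 2.0 * cv_int * cv_z * math.sqrt(gy / gz)
    return f_opt, min_cv2


def noise_floor_burst_events(ybar: float, mean_burst_y: float, zbar: float,
                             mean_burst_z: float, gamma_y: float,
                             gamma_z: float) -> float:
    """Minimal proportional-feedback noise for geometric bursts, written in
    burst-event counts: ``2/√(N_y N_z)`` with ``N_y = ȳ/⟨B_y⟩`` and
    ``N_z = γ_z z̄/(γ_y⟨B_z⟩)`` the numbers of target and controller burst
    events per ``1/γ_y``.  The floor decays as the square root of the
    number of burst events."""
    n_y = ybar / mean_burst_y
    n_z = gamma_z * zbar / (gamma_y * mean_burst_z)
    return 2.0 / math.sqrt(n_y * n_z)


# --------------------------------------------------------------------------
# integral controller
# --------------------------------------------------------------------------

def cv2_integral(inputs: NoiseInputs,
                 design: IntegralDesign | str = IntegralDesign.ZERO_ORDER
                 ) -> NoiseDecomposition:
    """Noise under integral feedback (stochastic integrator ``Z``).

    The intrinsic component equals ``CV²_int`` for every gain (integral
    feedback leaves the target's own expression noise untouched), the
    integrator contributes ``f_i·CV²_Z``, and the external component is a
    band-pass in ``γ_x``:

    zero-order design
        ``z̄γ_xγ_y CV²_X / (ȳ f_i k_z γ_y + z̄(γ_yγ_x + γ_x²))``
    autocatalytic design
        same with the ``z̄`` factors dropped (the self-activating variant's
        rate constants carry different units).
    """
    design = IntegralDesign(design)
    f = inputs.gain
    gx, gy = inputs.gamma_x, inputs.gamma_y
    if design is IntegralDesign.ZERO_ORDER:
        external = (inputs.zbar * gx * gy
                    / (inputs.ybar * f * inputs.k_z * gy
                       + inputs.zbar * (gy * gx + gx * gx))
                    * inputs.cv2_x)
    else:
        external = (gx * gy
                    / (inputs.ybar * f * inputs.k_z * gy + gy * gx + gx * gx)
                    * inputs.cv2_x)
    return NoiseDecomposition(intrinsic=inputs.cv2_int, external=external,
                              controller=f * inputs.cv2_z)


def integral_peak_disturbance_rate(inputs: NoiseInputs) -> float:
    """Disturbance time-scale ``γ_x`` maximizing the external component of
    the zero-order integral noise: ``√(k_z f_i ȳ γ_y / z̄)`` (the exact
    stationary point of the band-pass expression)."""
    if not inputs.gain > 0.0:
        raise InvalidParameterError("peak rate requires f_i > 0")
    return math.sqrt(inputs.k_z * inputs.gain * inputs.ybar * inputs.gamma_y
                     / inputs.zbar)


def optimal_gain_integral(inputs: NoiseInputs) -> tuple[float, float]:
    """Slow-disturbance (``γ_x ≪ γ_y``) optimum of the integral noise.

    Minimizing ``A/f + CV²_Z·f + CV²_int`` with
    ``A = z̄γ_x CV²_X/(ȳ k_z)`` gives the exact interior optimum
    ``f* = (CV_X/CV_Z)·√(z̄γ_x/(ȳ k_z))`` and minimum
    ``2·√(z̄γ_x/(ȳ k_z))·CV_X CV_Z + CV²_int`` — excess noise linear in
    ``CV_X`` and arbitrarily reducible by raising ``k_z``."""
    if inputs.cv2_z <= 0.0:
        raise NoInteriorMinimumError(
            "CV²_Z = 0: external noise is monotone decreasing in f_i, no "
            "interior minimum")
    s = math.sqrt(inputs.zbar * inputs.gamma_x / (inputs.ybar * inputs.k_z))
    cv_x = math.sqrt(inputs.cv2_x)
    cv_z = math.sqrt(inputs.cv2_z)
    return (cv_x / cv_z) * s, 2.0 * s * cv_x * cv_z + inputs.cv2_int


# --------------------------------------------------------------------------
# derivative controller
# --------------------------------------------------------------------------

def cv2_derivative(inputs: NoiseInputs) -> NoiseDecomposition:
    """Noise under the incoherent-feedforward derivative controller with
    gain ``f_d = h·γ_y/γ_z``.

    Intrinsic and external components both decrease with ``f_d`` (the
    intrinsic one much faster), the sensor component grows, and for slow
    disturbances (``γ_x ≪ γ_y, γ_z``) the external component saturates at
    ``CV²_X``: derivative action cannot reject low-frequency disturbances.
    At ``f_d = 0`` the split reduces to the open loop.
    """
    f = inputs.gain
    gx, gy, gz = inputs.gamma_x, inputs.gamma_y, inputs.gamma_z
    den = gy + gz * f + gz
    intrinsic = (gy + gz) / den * inputs.cv2_int
    external = (gy * (gy * (gx + gz) + gz * (gx + gz + gz * f))
                / (den * (gy * (gx + gz) + gx * (gx + gz * f + gz)))
                * inputs.cv2_x)
    sensor = f * f * gz * gz / (gy * den) * inputs.cv2_z
    return NoiseDecomposition(intrinsic=intrinsic, external=external,
                              controller=sensor)


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

_DISPATCH = {
    CircuitTopology.OPEN: cv2_open_loop,
    CircuitTopology.PROPORTIONAL: cv2_proportional,
    CircuitTopology.INTEGRAL: cv2_integral,
    CircuitTopology.DERIVATIVE: cv2_derivative,
}


def cv2_for_topology(topology: CircuitTopology | str,
                     inputs: NoiseInputs) -> NoiseDecomposition:
    """Closed-form noise decomposition matching a circuit topology."""
    return _DISPATCH[CircuitTopology(topology)](inputs)
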