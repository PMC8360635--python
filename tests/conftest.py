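"""Shared fixtures: canonical circuits and a random-circuit factory."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pidnoise import (
    BurstDistribution,
    CircuitModel,
    DisturbanceSpec,
    RegulationSpec,
    SpeciesParams,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def geo(mean: float) -> BurstDistribution:
    return BurstDistribution("shifted_geometric", mean)


def make_open(ky=2.0, gy=0.2, by=20.0, disturbance=None) -> CircuitModel:
    return CircuitModel(
        topology="open",
        disturbance=disturbance or DisturbanceSpec("none"),
        target=SpeciesParams(ky, gy, geo(by)))


def make_bursty_disturbance(kx=1.0, gx=0.5, bx=5.0) -> DisturbanceSpec:
    return DisturbanceSpec("bursty", SpeciesParams(kx, gx, geo(bx)))


def make_proportional(*, ky=2.0, gy=1.0, by=20.0, kz=1.0, gz=5.0, bz=1.0,
                      zc=20.0, h=2.0, disturbance=None) -> CircuitModel:
    return CircuitModel(
        topology="proportional",
        disturbance=disturbance or DisturbanceSpec("none"),
        target=SpeciesParams(ky, gy, geo(by)),
        sensor=SpeciesParams(kz, gz, geo(bz)),
        regulation=RegulationSpec("hill_repression", half_max=zc,
                                  hill_coeff=h))


def make_integral(*, ky=10.0, gy=1.0, by=20.0, kz=1.0, bz=10.0, zc=100.0,
                  h=1.0, y_set=100.0, disturbance=None) -> CircuitModel:
    return CircuitModel(
        topology="integral",
        disturbance=disturbance or make_bursty_disturbance(2/3, 1/3, 10.0),
        target=SpeciesParams(ky, gy, geo(by)),
        sensor=SpeciesParams(kz, 1.0, geo(bz)),
        regulation=RegulationSpec("zero_order_integral", half_max=zc,
                                  hill_coeff=h, set_point=y_set))


def make_derivative(*, ky=2.0, gy=0.2, by=20.0, kz=1.0, gz=1.0, bz=1.0,
                    h=1.0, disturbance=None) -> CircuitModel:
    """The printed derivative-validation circuit by default (k_z = γ_z)."""
    return CircuitModel(
        topology="derivative",
        disturbance=disturbance or DisturbanceSpec("none"),
        target=SpeciesParams(ky, gy, geo(by)),
        sensor=SpeciesParams(kz, gz, geo(bz)),
        regulation=RegulationSpec("ratio_derivative", hill_coeff=h))


def random_circuit(topology: str, rng: np.random.Generator) -> CircuitModel:
    """Valid random circuit with log-uniform rates and moderate noise
    (stationary CV² of order 0.01–1), for cross-validation sweeps."""
    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    gy = logu(0.1, 10.0)
    by = logu(1.0, 30.0)
    ybar = logu(50.0, 2000.0)
    ky = ybar * gy / by

    gx = logu(0.1, 10.0) * gy
    bx = logu(1.0, 15.0)
    xbar = logu(20.0, 500.0)
    dist = DisturbanceSpec(
        "bursty", SpeciesParams(xbar * gx / bx, gx, geo(bx)))
    target = SpeciesParams(ky, gy, geo(by))

    if topology == "open":
        return CircuitModel(topology="open", disturbance=dist, target=target)

    gz = logu(0.3, 20.0) * gy
    bz = logu(1.0, 15.0)
    h = logu(0.5, 4.0)

    if topology == "proportional":
        kz = logu(0.01, 1.0) * gz / bz   # keeps z̄ = k_z⟨B_z⟩ȳ/γ_z moderate
        zc = logu(0.2, 2.0) * kz * bz * ybar / gz
        return CircuitModel(
            topology="proportional", disturbance=dist, target=target,
            sensor=SpeciesParams(kz, gz, geo(bz)),
            regulation=RegulationSpec("hill_repression", half_max=zc,
                                      hill_coeff=h))
    if topology == "integral":
        y_set = float(rng.uniform(0.2, 0.8)) * ybar
        kz = logu(0.1, 10.0)
        zc = logu(20.0, 500.0)
        return CircuitModel(
            topology="integral", disturbance=dist, target=target,
            sensor=SpeciesParams(kz, 1.0, geo(bz)),
            regulation=RegulationSpec("zero_order_integral", half_max=zc,
                                      hill_coeff=h, set_point=y_set))
    # derivative
    kz = logu(0.05, 2.0) * gz / bz
    return CircuitModel(
        topology="derivative", disturbance=dist, target=target,
        sensor=SpeciesParams(kz, gz, geo(bz)),
        regulation=RegulationSpec("ratio_derivative", hill_coeff=h))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211009)
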