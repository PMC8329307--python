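"""Tumor–immune–estrogen competition model and the generic fractional system.

Five coupled populations: cancer stem cells C, tumor cells T, healthy cells H,
immune cells I (all in cells) and excess estrogen E (pg/mL), with logistic
growth, immune predation, estrogen-driven proliferation/mutation, a constant
immune source and continuous estrogen infusion.  Time is measured in days.

The fractional variant replaces d/dt by Caputo derivatives of orders
eta_1..eta_5 in (0, 1].  Dimensional consistency then requires every rate
constant of dimension day^-1 appearing in equation i to be raised to the
power eta_i (so it carries day^-eta_i); at eta_i = 1 the classical system is
recovered exactly.

All right-hand sides are vectorized over trailing axes and accept complex
state arrays, so complex-step differentiation works through them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "StateVector",
    "FractionalOrders",
    "FractionalSystem",
    "default_parameters",
    "classical_rhs",
    "fractional_rhs",
    "example_initial_conditions",
    "fbccm_system",
]


class StateVector(NamedTuple):
    """One point of the five-compartment state."""

    C: float  # cancer stem cells (cells)
    T: float  # tumor cells (cells)
    H: float  # healthy cells (cells)
    I: float  # immune cells (cells)
    E: float  # excess estrogen (pg/mL)


@dataclass(frozen=True)
class ModelParameters:
    """Rate/capacity/threshold constants of the competition model.

    Units: division/death/washout/absorption rates in day^-1; carrying
    capacities and thresholds in cells (v in pg/mL); interaction kill rates in
    cell^-1 day^-1; estrogen proliferation rates in cell day^-1 (pg/mL)^-1;
    s in cell day^-1; tau in pg mL^-1 day^-1.
    """

    k1: float
    k2: float
    q: float
    M1: float
    M2: float
    M3: float
    gamma1: float
    gamma2: float
    gamma3: float
    p1: float
    p2: float
    p3: float
    a1: float
    a2: float
    a3: float
    n1: float
    n2: float
    delta: float
    s: float
    rho: float
    omega: float
    u: float
    v: float
    tau: float
    mu: float
    d1: float
    d2: float
    d3: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls(**json.loads(text))

    def replace(self, **overrides) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)


def default_parameters() -> ModelParameters:
    """Baseline parameter set of the competition model (time unit: day)."""
    M1, M2, M3 = 2.27e6, 2.27e7, 2.5e7
    return ModelParameters(
        k1=0.75, k2=0.514, q=0.70,
        M1=M1, M2=M2, M3=M3,
        gamma1=3e-7, gamma2=3e-6, gamma3=1e-7,
        p1=600.0, p2=0.0, p3=100.0,
        a1=M1 / 2, a2=M2 / 2, a3=M3 / 2,
        n1=0.01, n2=0.29,
        delta=6e-8,
        s=1.3e4, rho=0.20, omega=3e5, u=0.20,
        v=400.0, tau=2000.0, mu=0.97,
        d1=0.01, d2=0.01, d3=0.01,
    )


@dataclass(frozen=True)
class FractionalOrders:
    """The five Caputo orders, each in (0, 1]."""

    eta1: float
    eta2: float
    eta3: float
    eta4: float
    eta5: float

    def __post_init__(self):
        for name, eta in zip(self.__dataclass_fields__, self.as_array()):
            if not 0 < eta <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {eta}")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta1, self.eta2, self.eta3, self.eta4, self.eta5])

    @classmethod
    def from_sequence(cls, seq: Sequence[float]) -> "FractionalOrders":
        return cls(*map(float, seq))


CLASSICAL_ORDERS = FractionalOrders(1.0, 1.0, 1.0, 1.0, 1.0)


def _rhs(state, params: ModelParameters, powers, immune_kill_target: str = "C"):
    """Shared right-hand side; ``powers`` are the per-equation rate exponents."""
    p = params
    C, T, H, I, E = state
    e1, e2, e3, e4, e5 = powers
    kill = C if immune_kill_target == "C" else T
    dC = (
        p.k1**e1 * C * (1 - C / p.M1)
        - p.gamma1**e1 * I * C
        + p.p1**e1 * C * E / (p.a1 + C)
    )
    dT = (
        p.k2**e2 * C * (C / p.M1) * (1 - T / p.M2)
        - p.n1**e2 * T
        - p.gamma2**e2 * I * kill
        + p.p2**e2 * T * E / (p.a2 + T)
    )
    dH = (
        p.q**e3 * H * (1 - H / p.M3)
        - p.delta**e3 * H * T
        - p.p3**e3 * H * E / (p.a3 + H)
    )
    dI = (
        p.s**e4
        + p.rho**e4 * I * T / (p.omega + T)
        - p.gamma3**e4 * I * T
        - p.n2**e4 * I
        - p.u**e4 * I * E / (p.v + E)
    )
    dE = p.tau**e5 - (
        p.mu**e5
        + p.d1**e5 * C / (p.a1 + C)
        + p.d2**e5 * T / (p.a2 + T)
        + p.d3**e5 * H / (p.a3 + H)
    ) * E
    return np.array([dC, dT, dH, dI, dE]) if np.ndim(C) == 0 else np.stack(
        [dC, dT, dH, dI, dE]
    )


def classical_rhs(state, params: Optional[ModelParameters] = None,
                  immune_kill_target: str = "C"):
    """Integer-order right-hand sides (d/dt of C, T, H, I, E)."""
    params = params or default_parameters()
    return _rhs(state, params, (1, 1, 1, 1, 1), immune_kill_target)


def fractional_rhs(state, params: Optional[ModelParameters] = None,
                   orders: FractionalOrders = CLASSICAL_ORDERS,
                   immune_kill_target: str = "C"):
    """Dimension-corrected fractional right-hand sides.

    Every rate constant of dimension day^-1 in equation i is raised to the
    power eta_i; capacities, half-saturations and thresholds are untouched.
    The gamma2 immune-kill term in the T equation uses I*C as printed in the
    source model; pass ``immune_kill_target="T"`` for the I*T variant.
    """
    params = params or default_parameters()
    return _rhs(state, params, tuple(orders.as_array()), immune_kill_target)


def example_initial_conditions() -> StateVector:
    """Benchmark initial state: advanced tumor burden, intact healthy tissue,
    no immune activation and no excess estrogen yet."""
    return StateVector(C=7.3710e5, T=7.6167e6, H=2.5000e7, I=0.0, E=0.0)


@dataclass
class FractionalSystem:
    """A system of Caputo fractional ODEs D^eta_i y_i = rhs_i(t, y).

    ``rhs(t, state, orders)`` must be vectorized over a trailing node axis of
    ``state`` and accept complex arrays.  ``scales`` are per-component
    magnitudes used to nondimensionalize residuals (ones = no scaling).
    """

    dimension: int
    rhs: Callable
    initial_state: np.ndarray
    orders: FractionalOrders
    scales: np.ndarray = None
    name: str = "system"

    def __post_init__(self):
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.initial_state.shape != (self.dimension,):
            raise ValueError(
                f"initial state must have length {self.dimension}, "
                f"got {self.initial_state.shape}"
            )
        if self.scales is None:
            self.scales = np.ones(self.dimension)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.scales.shape != (self.dimension,) or np.any(self.scales <= 0):
            raise ValueError("scales must be positive, one per component")

    @property
    def order_array(self) -> np.ndarray:
        return np.atleast_1d(self.orders.as_array())[: self.dimension]


def fbccm_system(
    params: Optional[ModelParameters] = None,
    orders: FractionalOrders = CLASSICAL_ORDERS,
    initial_state=None,
    immune_kill_target: str = "C",
) -> FractionalSystem:
    """The fractional competition model packaged as a FractionalSystem.

    Residual scales are (M1, M2, M3, omega, v): the carrying capacities for
    the three cell populations, the immune threshold for I and the estrogen
    threshold for E.
    """
    params = params or default_parameters()
    if initial_state is None:
        initial_state = np.array(example_initial_conditions())

    def rhs(t, state, ords):
        return fractional_rhs(state, params, ords, immune_kill_target)

    return FractionalSystem(
        dimension=5,
        rhs=rhs,
        initial_state=np.asarray(initial_state, dtype=float),
        orders=orders,
        scales=np.array([params.M1, params.M2, params.M3, params.omega, params.v]),
        name="fbccm",
    )
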