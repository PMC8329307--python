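"""Reference Caputo-derivative implementations used as numerical oracles.

Two independent routes to the Caputo derivative of order eta in (0, 1]:

* :func:`caputo_monomial` — the closed-form rule for power functions,
  D^eta t^p = Gamma(p+1)/Gamma(p+1-eta) * t^(p-eta) (zero for p = 0),
  extended from integer to real powers p > 0.
* :func:`caputo_quadrature` — direct numerical evaluation of the defining
  convolution integral

      D^eta f(t) = 1/Gamma(1-eta) * int_0^t (t-xi)^(-eta) f'(xi) dxi,

  whose kernel is weakly singular at xi = t and whose integrand may be
  additionally singular at xi = 0 (e.g. f = t^p with p < 1).  A
  double-exponential (tanh-sinh) rule on the split interval [0, t/2, t]
  handles both algebraic endpoint singularities; plain Gauss rules do not.

The two routes agree to ~1e-6 relative on a grid of powers and orders, which
is the contract the basis and solver modules rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import mpmath as mp

__all__ = ["CaputoSpec", "caputo_monomial", "caputo_quadrature"]


@dataclass(frozen=True)
class CaputoSpec:
    """Order and quadrature resolution for the convolution integral."""

    eta: float
    quad_nodes: int = 64

    def __post_init__(self):
        if not 0 < self.eta <= 1:
            raise ValueError(f"order must lie in (0, 1], got {self.eta}")
        if self.quad_nodes < 8:
            raise ValueError(f"need at least 8 quadrature nodes, got {self.quad_nodes}")


def caputo_monomial(p: float, eta: float, t: float) -> float:
    """Caputo derivative of t^p (p >= 0 real) of order eta, at t > 0."""
    if p < 0:
        raise ValueError(f"power must be non-negative, got {p}")
    if not 0 < eta <= 1:
        raise ValueError(f"order must lie in (0, 1], got {eta}")
    if t <= 0:
        raise ValueError(f"abscissa must be positive, got {t}")
    if p == 0:
        return 0.0
    return math.gamma(p + 1) / math.gamma(p + 1 - eta) * t ** (p - eta)


def _fd_derivative(f: Callable[[float], float], x: float, t: float) -> float:
    """Fourth-order finite-difference f'(x) staying inside [0, t]."""
    h = 1e-6 * max(1.0, abs(t))
    if x - 2 * h >= 0 and x + 2 * h <= t:
        return (-f(x + 2 * h) + 8 * f(x + h) - 8 * f(x - h) + f(x - 2 * h)) / (12 * h)
    if x - 2 * h < 0:  # one-sided forward stencil near the origin
        return (
            -25 * f(x) + 48 * f(x + h) - 36 * f(x + 2 * h) + 16 * f(x + 3 * h) - 3 * f(x + 4 * h)
        ) / (12 * h)
    return (
        25 * f(x) - 48 * f(x - h) + 36 * f(x - 2 * h) - 16 * f(x - 3 * h) + 3 * f(x - 4 * h)
    ) / (12 * h)


def caputo_quadrature(
    f: Callable[[float], float],
    spec: CaputoSpec,
    t: float,
    fprime: Optional[Callable[[float], float]] = None,
) -> float:
    """Caputo derivative of a scalar function by direct quadrature.

    Parameters
    ----------
    f
        Scalar function on [0, t] with an integrable first derivative.
    spec
        Order and resolution; ``quad_nodes`` sets the tanh-sinh refinement
        depth (higher = more accurate).
    t
        Evaluation abscissa, t > 0.
    fprime
        Exact derivative if available (used for the basis monomials); when
        omitted, a high-order finite difference of ``f`` is used, which caps
        the attainable accuracy around 1e-8.
    """
    eta = spec.eta
    if t <= 0:
        raise ValueError(f"abscissa must be positive, got {t}")
    if eta == 1:
        df = fprime if fprime is not None else (lambda x: _fd_derivative(f, x, t))
        return float(df(t))
    df = fprime if fprime is not None else (lambda x: _fd_derivative(f, float(x), t))

    # Substituting u = (t - xi)^(1-eta) removes the kernel singularity at
    # xi = t analytically:
    #   int_0^t (t-xi)^-eta f'(xi) dxi = 1/(1-eta) int_0^T f'(t - u^s) du,
    # with s = 1/(1-eta), T = t^(1-eta).  The remaining integrand may still be
    # (weakly) singular at u = T when f' blows up at xi = 0 (e.g. f = t^p,
    # p < 1), which the double-exponential rule handles.
    maxdegree = max(8, int(math.log2(spec.quad_nodes)) + 4)
    with mp.workdps(30):
        # s, T must be formed at working precision: a low-precision upper
        # limit T can overshoot t^(1-eta), pushing nodes past the true
        # endpoint into the (clamped) singularity of f'.
        s = mp.mpf(1) / (1 - mp.mpf(eta))
        T = mp.mpf(t) ** (1 - mp.mpf(eta))

        def integrand(u):
            # u stays an mpf: tanh-sinh nodes approach the endpoints closer
            # than float can represent, and an exact fprime must see the true
            # tiny positive abscissa rather than a rounded 0.0.
            xi = t - u**s
            if xi <= 0:  # rounding guard; f' may be singular at exactly 0
                xi = mp.mpf(10) ** (-mp.mp.dps)
            return df(xi)

        val = mp.quad(integrand, [0, T / 2, T], maxdegree=maxdegree)
        val = val / ((1 - mp.mpf(eta)) * mp.gamma(1 - mp.mpf(eta)))
    return float(val)
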