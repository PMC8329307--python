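"""Shifted Legendre and generalized shifted Legendre (Müntz-type) bases.

The classical shifted Legendre polynomials (SLP) live on [0, 1],

    L_j(t) = sum_{k=0}^{j} (-1)^{j+k} (j+k)! / (j-k)! * t^k / (k!)^2,

with the endpoint identities ``L_j(0) = (-1)^j`` and ``L_j(1) = 1``.  The
generalized family (GSLP) keeps the same triangular coefficient table but
replaces each monomial ``t^j`` (j >= 1) by ``t^(j + alpha_j)``, where the
``alpha_j`` are free real "control parameters" subject only to
``j + alpha_j > 0``.  The GSLP are therefore a Müntz-type, non-orthogonal
family whose exponents can be tuned to match the algebraic boundary layers
(``t^eta`` behaviour near t = 0) typical of Caputo fractional dynamics.

The Caputo derivative of order ``eta`` acts diagonally on the GSLP monomial
vector ``Psi(t) = (1, t^(1+a1), ..., t^(m+am))``:

    D^eta t^p = Gamma(p+1) / Gamma(p+1-eta) * t^(p-eta),   D^eta 1 = 0,

which this module packages as an operational matrix (diagonal Gamma ratios
times a shared ``t^-eta`` factor).

All evaluation helpers accept real or complex ``alphas``/coefficients so that
complex-step differentiation can be driven straight through them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import gamma as _cgamma

__all__ = [
    "SLPBasis",
    "GSLPBasis",
    "OperationalMatrix",
    "slp_coefficient_matrix",
    "eval_slp",
    "gslp_q_matrix",
    "gslp_psi",
    "psi_matrix",
    "caputo_psi_matrix",
    "eval_gslp_expansion",
    "caputo_operational_matrix",
]


def _triangle_entry(i: int, j: int) -> int:
    """Exact integer coefficient (-1)^(i+j) (i+j)! / ((i-j)! (j!)^2)."""
    if j > i:
        return 0
    val = math.factorial(i + j) // (math.factorial(i - j) * math.factorial(j) ** 2)
    return -val if (i + j) % 2 else val


@lru_cache(maxsize=None)
def _coefficient_rows_cached(n: int) -> tuple:
    return tuple(
        tuple(_triangle_entry(i, j) for j in range(n + 1)) for i in range(n + 1)
    )


def _coefficient_rows(n: int) -> list[list[int]]:
    return [list(row) for row in _coefficient_rows_cached(n)]


@dataclass(frozen=True)
class SLPBasis:
    """Shifted Legendre basis up to degree ``n``.

    ``P`` is the lower-triangular (n+1)x(n+1) matrix mapping the monomial
    vector (1, t, ..., t^n) to (L_0, ..., L_n).
    """

    n: int
    P: np.ndarray

    @property
    def exact_rows(self) -> list[list[int]]:
        """The coefficient rows as exact Python integers."""
        return _coefficient_rows(self.n)


def slp_coefficient_matrix(n: int) -> SLPBasis:
    """Build the SLP coefficient matrix for degrees 0..n.

    Entries are computed in exact integer arithmetic and converted to float,
    so there is no cancellation for any representable degree.
    """
    if n < 0:
        raise ValueError(f"max degree must be non-negative, got {n}")
    P = np.array(_coefficient_rows(n), dtype=float)
    return SLPBasis(n=n, P=P)


def eval_slp(j: int, t: float) -> float:
    """Evaluate the shifted Legendre polynomial L_j at t in [0, 1]."""
    if j < 0:
        raise ValueError(f"degree must be non-negative, got {j}")
    tv = np.asarray(t, dtype=float)
    if np.any(tv < 0) or np.any(tv > 1):
        raise ValueError(f"abscissa must lie in [0, 1], got {t}")
    coeffs = [_triangle_entry(j, k) for k in range(j + 1)]
    # Horner with exact-integer coefficients, accumulated in extended
    # precision: the monomial form of L_j is badly conditioned (coefficients
    # ~ (2j)!/(j!)^2 with alternating signs), and 80-bit accumulation keeps
    # j <= ~15 accurate to well below 1e-9.
    tl = tv.astype(np.longdouble)
    acc = np.zeros_like(tl) + np.longdouble(coeffs[-1])
    for c in reversed(coeffs[:-1]):
        acc = acc * tl + np.longdouble(c)
    acc = acc.astype(float)
    return float(acc) if acc.ndim == 0 else acc


def gslp_q_matrix(m: int) -> np.ndarray:
    """Coefficient matrix Q of the generalized shifted Legendre family.

    (m+1)x(m+1), lower triangular; the first row is (1, 0, ..., 0) and rows
    k >= 1 carry the same factorial coefficients as the SLP matrix.
    """
    if m < 1:
        raise ValueError(f"basis size must be >= 1, got {m}")
    return np.array(_coefficient_rows(m), dtype=float)


@dataclass(frozen=True)
class GSLPBasis:
    """One compartment's generalized shifted Legendre basis.

    Parameters
    ----------
    m
        Basis size; the expansion uses m+1 functions (the constant plus m
        generalized polynomials).
    alphas
        Control-parameter exponent shifts (length m); exponent j of the
        monomial vector becomes ``j + alphas[j-1]`` and must stay positive.
    """

    m: int
    alphas: np.ndarray
    Q: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        alphas = np.atleast_1d(np.asarray(self.alphas))
        if alphas.shape != (self.m,):
            raise ValueError(
                f"need {self.m} control parameters, got shape {alphas.shape}"
            )
        expo = np.arange(1, self.m + 1) + alphas
        if np.any(np.real(expo) <= 0):
            raise ValueError(
                f"invalid basis: exponents j + alpha_j must be positive, got {expo}"
            )
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "Q", gslp_q_matrix(self.m))

    @property
    def exponents(self) -> np.ndarray:
        """Monomial exponents (0, 1 + a_1, ..., m + a_m), length m+1."""
        shifted = np.arange(1, self.m + 1) + self.alphas
        return np.concatenate((np.zeros(1, dtype=shifted.dtype), shifted))


def psi_matrix(basis: GSLPBasis, t) -> np.ndarray:
    """Monomial vector(s) Psi(t) = (1, t^(1+a1), ..., t^(m+am)).

    ``t`` may be a scalar or a 1-d array of non-negative abscissae; the result
    has shape (m+1,) or (m+1, len(t)).
    """
    tv = np.atleast_1d(np.asarray(t))
    if np.any(np.real(tv) < 0):
        raise ValueError("abscissae must be non-negative")
    expo = basis.exponents
    out_dtype = np.result_type(tv.dtype, expo.dtype, float)
    out = np.empty((basis.m + 1, tv.size), dtype=out_dtype)
    out[0] = 1.0
    pos = np.real(tv) > 0
    for row in range(1, basis.m + 1):
        out[row, pos] = tv[pos] ** expo[row]
        out[row, ~pos] = 0.0  # exponent > 0 by the basis invariant
    return out[:, 0] if np.isscalar(t) or np.ndim(t) == 0 else out


def gslp_psi(basis: GSLPBasis, t) -> np.ndarray:
    """Alias of :func:`psi_matrix` matching the field's Psi(t) notation."""
    return psi_matrix(basis, t)


def eval_gslp_expansion(coeffs, basis: GSLPBasis, t):
    """Evaluate the expansion coeffs^T Q Psi(t)."""
    coeffs = np.asarray(coeffs)
    if coeffs.shape != (basis.m + 1,):
        raise ValueError(
            f"coefficient vector must have length {basis.m + 1}, got {coeffs.shape}"
        )
    return (coeffs @ basis.Q) @ psi_matrix(basis, t)


def _gamma(z):
    """Gamma function valid for real and complex arguments."""
    z = np.asarray(z)
    if np.iscomplexobj(z):
        return _cgamma(z)
    return _cgamma(z.astype(float))


@dataclass(frozen=True)
class OperationalMatrix:
    """Diagonal Caputo operational matrix of order ``eta`` for a GSLP basis.

    Applying ``diag`` entrywise to Psi(t) and multiplying by ``t**time_exponent``
    reproduces the elementwise Caputo derivative of Psi(t).
    """

    order: float
    diag: np.ndarray
    time_exponent: float

    def matrix(self, t: float) -> np.ndarray:
        """Dense diagonal matrix t^(-eta) * diag at a single abscissa t > 0."""
        if t <= 0:
            raise ValueError("operational matrix carries t^-eta; need t > 0")
        return np.diag(self.diag) * t**self.time_exponent


def caputo_operational_matrix(basis: GSLPBasis, eta: float) -> OperationalMatrix:
    """Operational matrix of the Caputo derivative of order eta in (0, 1].

    diag[0] = 0 (the Caputo derivative of a constant vanishes) and
    diag[j] = Gamma(j+1+alpha_j) / Gamma(j+1-eta+alpha_j) for j >= 1.
    """
    if not 0 < eta <= 1:
        raise ValueError(f"order must lie in (0, 1], got {eta}")
    j = np.arange(1, basis.m + 1)
    diag = np.concatenate(
        ([0.0], _gamma(j + 1 + basis.alphas) / _gamma(j + 1 - eta + basis.alphas))
    )
    return OperationalMatrix(order=eta, diag=diag, time_exponent=-eta)


def caputo_psi_matrix(basis: GSLPBasis, eta: float, t) -> np.ndarray:
    """Elementwise Caputo derivative of Psi(t), shape (m+1, len(t)).

    The shared t^-eta factor is folded into the monomial exponents
    analytically, so t = 0 is handled without ever forming 0^-eta: an entry
    with combined exponent > 0 evaluates to 0 and an entry with combined
    exponent exactly 0 evaluates to its Gamma-ratio coefficient.
    """
    om = caputo_operational_matrix(basis, eta)
    tv = np.atleast_1d(np.asarray(t))
    if np.any(np.real(tv) < 0):
        raise ValueError("abscissae must be non-negative")
    expo = basis.exponents - eta  # combined exponents j + alpha_j - eta
    out_dtype = np.result_type(tv.dtype, expo.dtype, om.diag.dtype, float)
    out = np.zeros((basis.m + 1, tv.size), dtype=out_dtype)
    pos = np.real(tv) > 0
    for row in range(1, basis.m + 1):
        out[row, pos] = om.diag[row] * tv[pos] ** expo[row]
        if np.any(~pos):
            e = np.real(expo[row])
            if e == 0:
                out[row, ~pos] = om.diag[row]
            elif e < 0:
                raise ValueError(
                    "Caputo derivative of Psi is singular at t = 0 for exponent "
                    f"{expo[row]}"
                )
    return out[:, 0] if np.isscalar(t) or np.ndim(t) == 0 else out
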