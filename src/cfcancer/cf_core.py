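r"""Caputo-Fabrizio (CF) fractional operators with exponential kernel.

The CF derivative of order ``theta`` in (0, 1) of a function ``h`` with
``h in H^1(0, T)`` is

.. math::

    D^\vartheta h(t) = \frac{1}{1-\vartheta}
        \int_0^t h'(x)\, e^{-\vartheta (t-x)/(1-\vartheta)}\, dx,

a fractional derivative whose kernel is a decaying exponential rather than
the classical power law, so it is nonsingular at ``x = t``.  The associated
CF integral, with the normalization ``U(theta) = 2/(2 - theta)`` folded in,
reduces to the convex combination

.. math::

    I^\vartheta f(t) = (1-\vartheta)\, f(t) + \vartheta \int_0^t f(u)\, du,

which is the exact inverse of the derivative on functions vanishing at 0.
``theta = 1`` recovers ordinary calculus; smaller ``theta`` weights the past
more heavily ("index of memory").

All operators here act on functions sampled on a uniform grid starting at 0
and use composite trapezoid quadrature.  The exponential kernel admits an
exact one-step recurrence for the trapezoid sum, so the derivative is
evaluated at every grid node in O(N) total work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

__all__ = [
    "SampledFunction",
    "normalization_u",
    "cf_coefficients",
    "cf_derivative",
    "cf_integral",
]


def normalization_u(theta: float) -> float:
    """Normalization function ``U(theta) = 2 / (2 - theta)``.

    With this choice the two coefficients of the CF integral simplify to
    ``(1 - theta)`` and ``theta`` and sum exactly to 1.

    Parameters
    ----------
    theta : float
        Fractional order; must satisfy ``0 <= theta < 2``.
    """
    if not 0.0 <= theta < 2.0:
        raise ValueError(f"normalization U(theta) requires 0 <= theta < 2, got {theta}")
    return 2.0 / (2.0 - theta)


def cf_coefficients(theta: float) -> tuple[float, float]:
    """Unsimplified CF-integral coefficients ``(c1, c2)``.

    Returns ``c1 = 2(1-theta) / ((2-theta) U(theta))`` and
    ``c2 = 2 theta / ((2-theta) U(theta))``.  With ``U = 2/(2-theta)`` these
    are identically ``(1 - theta)`` and ``theta``; the unsimplified form is
    kept so the simplification can be proven rather than assumed.
    """
    u = normalization_u(theta)
    denom = (2.0 - theta) * u
    return 2.0 * (1.0 - theta) / denom, 2.0 * theta / denom


@dataclass(frozen=True)
class SampledFunction:
    """A real function sampled on a strictly increasing grid starting at 0."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or values.ndim != 1 or grid.size != values.size:
            raise ValueError("grid and values must be 1-d arrays of equal length")
        if grid.size < 2:
            raise ValueError("a sampled function needs at least 2 nodes")
        if grid[0] != 0.0:
            raise ValueError(f"grid must start at 0, got grid[0] = {grid[0]}")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)


def _as_grid_values(h, grid) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(h, SampledFunction):
        return h.grid, h.values
    if grid is None:
        raise ValueError("grid is required when values are passed as a plain array")
    return np.asarray(grid, dtype=float), np.asarray(h, dtype=float)


def _uniform_step(grid: np.ndarray) -> float:
    steps = np.diff(grid)
    h = steps[0]
    if h <= 0 or not np.allclose(steps, h, rtol=1e-9, atol=0.0):
        raise ValueError("cf operators require a uniform time grid")
    return float(h)


def cf_derivative(h, theta: float, grid=None) -> np.ndarray:
    """CF derivative of order ``theta`` at every grid node.

    ``h`` may be a :class:`SampledFunction` or an array of values (then
    ``grid`` must be supplied).  The derivative ``h'`` is formed by centered
    differences (second-order one-sided at the endpoints) and the kernel
    integral by composite trapezoid, accumulated through the exponential
    kernel's exact decay recurrence.  The value at ``t = 0`` is 0.

    ``theta = 1`` is a documented special case returning the plain first
    derivative; ``theta`` outside (0, 1] raises.
    """
    grid, values = _as_grid_values(h, grid)
    if values.size < 3:
        raise ValueError("cf_derivative needs at least 3 nodes for centered differences")
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"cf_derivative requires 0 < theta <= 1, got {theta}")
    step = _uniform_step(grid)
    dh = np.gradient(values, grid, edge_order=2)
    if theta == 1.0:
        return dh
    # decay rate of the exponential kernel exp(-a (t - x)), a = theta/(1-theta)
    a = theta / (1.0 - theta)
    r = np.exp(-a * step)
    # trapezoid contribution of each subinterval [t_j, t_{j+1}] to the
    # integral ending at t_{j+1}; the kernel then decays by r per step, so
    # I_{m+1} = r I_m + w_m, an exact restatement of the composite trapezoid
    # rule over [0, t_{m+1}] evaluated in O(N).
    w = 0.5 * step * (dh[:-1] * r + dh[1:])
    out = np.zeros_like(values)
    out[1:] = lfilter([1.0], [1.0, -r], w)
    out[1:] /= 1.0 - theta
    return out


def cf_integral(f, theta: float, t: float | None = None, grid=None):
    """CF integral ``(1-theta) f(t) + theta * int_0^t f`` (trapezoid).

    If ``t`` is given it must lie on the grid and a scalar is returned;
    otherwise the integral is returned at every grid node.  ``theta = 1``
    reduces to the plain integral and ``theta = 0`` returns ``f(t)`` itself;
    both follow from the same coefficient formula.
    """
    grid, values = _as_grid_values(f, grid)
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"cf_integral requires 0 <= theta <= 1, got {theta}")
    c1, c2 = cf_coefficients(theta)
    out = c1 * values + c2 * cumulative_trapezoid(values, grid, initial=0.0)
    if t is None:
        return out
    idx = np.flatnonzero(np.isclose(grid, t, rtol=1e-12, atol=1e-12))
    if idx.size == 0:
        raise ValueError(f"t = {t} is not a node of the supplied grid")
    return float(out[idx[0]])
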