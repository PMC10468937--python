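"""Neuronal-health density and its conservative transport.

Each parcel carries a probability density ``f(x_m, a, t)`` over the degree
of malfunctioning ``a in [0, 1]`` (0 = healthy neuron, 1 = dead).  The
density obeys a transport equation ``df/dt + d_a(v f) = 0`` whose drift
``v >= 0`` combines three effects, all vanishing at ``a = 1``:

* prion-like influence of already-malfunctioning neighbours within the
  parcel, ``C_G * int (b - a)^+ f(b) db``;
* amyloid-beta oligomer toxicity, ``C_S (1-a) (u_2+u_3+u_4 - U_bar_abeta)^+``;
* tau toxicity, ``C_T (1-a) (tau_1+...+tau_5 - U_bar_tau)^+`` (all tau
  compartments count here, as the model is written).

The malfunction axis is discretised into M uniform cells holding cell
averages.  Because ``v >= 0`` everywhere and ``v(1) = 0`` analytically, a
first-order upwind finite-volume step conserves each parcel's unit
probability mass to round-off and preserves nonnegativity under the CFL
condition — the properties that matter here, ahead of formal order of
accuracy.  All integrals over ``a`` (production, prion term, mean
malfunction) use midpoint quadrature on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams


class CFLError(RuntimeError):
    """Transport step too large: decrease dt."""


@dataclass(frozen=True)
class AGrid:
    """Uniform finite-volume grid on the malfunction axis [0, 1]."""

    n_cells: int
    delta: float = field(init=False)
    centers: np.ndarray = field(init=False)
    interfaces: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.n_cells < 8:
            raise ValueError(f"need at least 8 cells on [0,1], got {self.n_cells}")
        object.__setattr__(self, "delta", 1.0 / self.n_cells)
        object.__setattr__(
            self, "interfaces", np.linspace(0.0, 1.0, self.n_cells + 1)
        )
        object.__setattr__(
            self, "centers", 0.5 * (self.interfaces[:-1] + self.interfaces[1:])
        )

    def prion_kernel(self) -> np.ndarray:
        """Matrix K with ``K[i, k] = (a_k - a_{i-1/2})^+ * delta``.

        ``f @ K.T`` then evaluates ``int (b - a)^+ f(b) db`` at every cell
        interface by midpoint quadrature.
        """
        return np.maximum(self.centers[None, :] - self.interfaces[:, None], 0.0) * self.delta


@dataclass
class HealthDensity:
    """Per-node cell-averaged densities, shape (N, M); each row integrates to 1."""

    values: np.ndarray
    grid: AGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n_cells:
            raise ValueError(
                f"values must have shape (N, {self.grid.n_cells}), got {self.values.shape}"
            )
        if np.min(self.values, initial=0.0) < -1e-12:
            raise ValueError("densities must be nonnegative")
        np.maximum(self.values, 0.0, out=self.values)  # shave round-off negativity

    def mass(self) -> np.ndarray:
        """Per-node total probability mass (should be 1 up to round-off)."""
        return self.values.sum(axis=1) * self.grid.delta

    def copy(self) -> "HealthDensity":
        return HealthDensity(self.values.copy(), self.grid)


def initial_density(grid: AGrid, center: float = 0.01, width: float | None = None) -> np.ndarray:
    """Near-delta initial density for a healthy parcel: a triangular bump.

    A hat function of half-width ``width`` (default ``3 * delta``) centred at
    ``center``, truncated to [0, 1], cell-averaged and normalised.  The
    result is nonnegative, unimodal and has mean within one cell of
    ``center``.
    """
    if not 0.0 <= center < 0.1:
        raise ValueError(f"center must lie in [0, 0.1) (an almost-healthy brain), got {center}")
    if width is None:
        width = 3.0 * grid.delta
    if width < grid.delta:
        raise ValueError(f"width {width} is below one cell ({grid.delta}): unresolvable spike")
    f = np.maximum(1.0 - np.abs(grid.centers - center) / width, 0.0)
    total = f.sum() * grid.delta
    return f / total


def amyloid_production(
    f_node: np.ndarray, grid: AGrid, C_F: float, mu0: float
) -> np.ndarray:
    """Amyloid-beta monomer production by the parcel's neurons.

    Midpoint quadrature of ``C_F * int (mu0 + a)(1 - a) f(a) da``: a healthy
    neuron (a = 0) produces at the constant rate ``C_F * mu0``, a dead one
    (a = 1) produces nothing.  Accepts one row (M,) or a stack (N, M).
    """
    f = np.asarray(f_node, dtype=float)
    w = (mu0 + grid.centers) * (1.0 - grid.centers)
    return C_F * (f @ w) * grid.delta


def deterioration_rate(
    f_node: np.ndarray,
    grid: AGrid,
    oligomer_sum: np.ndarray,
    tau_sum: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Drift ``v(a) >= 0`` at every cell interface; shape (..., M+1).

    ``oligomer_sum`` is ``u_2 + u_3 + u_4`` and ``tau_sum`` is
    ``tau_1 + ... + tau_5`` at the node(s).  Every term carries a factor
    vanishing at ``a = 1``, so the outflow velocity at the right boundary is
    analytically zero and probability mass cannot leave [0, 1].
    """
    f = np.asarray(f_node, dtype=float)
    olig = np.asarray(oligomer_sum, dtype=float)
    tau = np.asarray(tau_sum, dtype=float)
    prion = params.C_G * (f @ grid.prion_kernel().T)
    tox = params.C_S * np.maximum(olig - params.U_bar_abeta, 0.0)
    tox = tox + params.C_T * np.maximum(tau - params.U_bar_tau, 0.0)
    v = prion + np.multiply.outer(tox, 1.0 - grid.interfaces)
    return v


def transport_step(
    f_node: np.ndarray, v: np.ndarray, dt: float, grid: AGrid
) -> np.ndarray:
    """One conservative first-order upwind step of ``df/dt + d_a(v f) = 0``.

    With ``v >= 0`` the upwind flux through interface k is ``v_k * f_{k-1}``
    (zero inflow at a = 0).  Under the CFL condition ``dt max(v) <= delta``
    the update preserves nonnegativity, and the zero flux at a = 1 makes the
    per-node mass exactly telescoping.  Accepts (M,)/(M+1,) rows or
    (N, M)/(N, M+1) stacks.
    """
    f = np.asarray(f_node, dtype=float)
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != grid.n_cells + 1:
        raise ValueError("v must be given at the M+1 cell interfaces")
    if np.min(v, initial=0.0) < 0:
        raise ValueError("upwind transport requires v >= 0")
    vmax = float(np.max(v, initial=0.0))
    if dt * vmax > grid.delta * (1.0 + 1e-12):
        raise CFLError(
            f"CFL violated: dt*max(v)/delta = {dt * vmax / grid.delta:.3f} > 1; reduce dt"
        )
    flux = v[..., 1:] * f                     # outflux of each cell (rightward)
    inflow = np.zeros_like(f)
    inflow[..., 1:] = flux[..., :-1]
    return f - (dt / grid.delta) * (flux - inflow)


def mean_malfunction(f_node: np.ndarray, grid: AGrid) -> np.ndarray:
    """Local average degree of malfunctioning ``A = int a f(a) da`` in [0, 1]."""
    f = np.asarray(f_node, dtype=float)
    return (f @ grid.centers) * grid.delta
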