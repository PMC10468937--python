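"""Aggregation-diffusion dynamics of amyloid-beta and misfolded tau.

Both proteins follow discrete Smoluchowski coagulation kinetics (binary
coalescence, no fragmentation, no nucleation) reduced to five compartments:
monomers, dimers, short proto-oligomers, long oligomers and the insoluble
aggregate (senile plaque for amyloid-beta, neurofibrillary tangle for tau).
Compartment 5 collects every coalescence product of total length >= 5; it
neither diffuses nor clears.

Amyloid-beta lives on the proximity graph and evolves on a fast time scale
(the whole right-hand side is divided by ``epsilon``); its monomers are
produced by neurons at a rate set by the health density (see
:mod:`adsim.health`) and cleared at rates ``sigma_i``.  Misfolded tau lives
on the connectivity graph, has no clearance, and gains monomers from two
sources: a Gamma-shaped seeding ``c * (t/lambda) exp(-t/lambda)`` on the
entorhinal vertices, and a production ``C_tau * (u_2+u_3+u_4 - U_bar)^+``
induced by amyloid-beta oligomers wherever they exceed the threshold.

Bookkeeping note: the soluble-species loss term sums over all five
compartments (plaques and tangles keep consuming soluble material) while
the compartment-5 gain only counts pairs of soluble species, exactly as the
model is written; total polymer mass is therefore not conserved by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import WeightedGraph
from .params import ModelParams

#: tolerated round-off negativity in concentrations
NEG_ATOL = 1e-12


class ContractError(ValueError):
    """Input violates an operation's contract (negative concentration, shape)."""


@dataclass
class ProteinField:
    """Per-node molar concentrations ``u`` (amyloid-beta) and ``tau``, shape (N, 5)."""

    u: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        for name, arr in (("u", self.u), ("tau", self.tau)):
            if arr.ndim != 2 or arr.shape[1] != 5:
                raise ContractError(f"{name} must have shape (N, 5), got {arr.shape}")
        if self.u.shape != self.tau.shape:
            raise ContractError("u and tau must share the same node set")

    @classmethod
    def zeros(cls, n_nodes: int) -> "ProteinField":
        return cls(np.zeros((n_nodes, 5)), np.zeros((n_nodes, 5)))

    @property
    def node_count(self) -> int:
        return self.u.shape[0]

    def copy(self) -> "ProteinField":
        return ProteinField(self.u.copy(), self.tau.copy())


def _checked(conc: np.ndarray, what: str) -> np.ndarray:
    """Validate nonnegativity up to round-off and clip the residue."""
    conc = np.asarray(conc, dtype=float)
    if conc.shape[-1] != 5:
        raise ContractError(f"{what} must have 5 compartments, got shape {conc.shape}")
    if np.min(conc, initial=0.0) < -NEG_ATOL:
        raise ContractError(f"{what} has negative entries (min {np.min(conc):.3e})")
    return np.maximum(conc, 0.0)


def coagulation_gain(conc: np.ndarray, rate: float) -> np.ndarray:
    """Smoluchowski gain terms for the 5-compartment reduction.

    ``gain_1 = 0``; ``gain_i = (rate/2) * sum_{j<i} c_j c_{i-j}`` for
    i = 2..4; ``gain_5`` sums every ordered soluble pair whose lengths add
    to at least 5 (j, k <= 4, j + k >= 5).  Works on a single 5-vector or on
    an (N, 5) stack.
    """
    if rate < 0:
        raise ContractError(f"coalescence rate must be >= 0, got {rate}")
    c = _checked(conc, "concentration")
    c1, c2, c3, c4 = c[..., 0], c[..., 1], c[..., 2], c[..., 3]
    gain = np.zeros_like(c)
    half = 0.5 * rate
    gain[..., 1] = half * c1 * c1
    gain[..., 2] = half * 2.0 * c1 * c2
    gain[..., 3] = half * (2.0 * c1 * c3 + c2 * c2)
    # ordered pairs (j,k), j,k in 1..4, j+k >= 5:
    # (1,4),(4,1),(2,3),(3,2),(2,4),(4,2),(3,4),(4,3),(3,3),(4,4)
    gain[..., 4] = half * (
        2.0 * c1 * c4 + 2.0 * c2 * c3 + 2.0 * c2 * c4 + 2.0 * c3 * c4 + c3 * c3 + c4 * c4
    )
    return gain


def coagulation_loss(conc: np.ndarray, rate: float) -> np.ndarray:
    """Smoluchowski loss terms: ``rate * c_i * sum_j c_j`` for i = 1..4.

    The sum runs over all five compartments (insoluble aggregates keep
    consuming soluble species), but compartment 5 itself has no loss term.
    """
    if rate < 0:
        raise ContractError(f"coalescence rate must be >= 0, got {rate}")
    c = _checked(conc, "concentration")
    total = c.sum(axis=-1, keepdims=True)
    loss = rate * c * total
    loss[..., 4] = 0.0
    return loss


def tau_seed_source(t: float, lambda_: float) -> float:
    """Gamma-shaped seeding profile ``(t/lambda) * exp(-t/lambda)``.

    Rises, peaks at ``t = lambda`` with value ``1/e``, then decays as the
    pool of cleavable physiological tau is exhausted.  The per-node source is
    this scalar times the amplitude ``c`` times the entorhinal indicator.
    """
    if t < 0:
        raise ContractError(f"time must be >= 0, got {t}")
    if lambda_ <= 0:
        raise ContractError(f"lambda must be > 0, got {lambda_}")
    x = t / lambda_
    return x * np.exp(-x)


def abeta_induced_production(u_node: np.ndarray, C_tau: float, U_bar: float) -> np.ndarray:
    """Misfolded-tau production induced by amyloid-beta oligomers.

    ``C_tau * (u_2 + u_3 + u_4 - U_bar)^+`` — only the genuinely oligomeric
    compartments (2..4) are toxic here; below the threshold ``U_bar`` the
    oligomers fail to be harmful.  Accepts a 5-vector or an (N, 5) stack and
    returns a scalar / per-node vector.
    """
    u = _checked(u_node, "u")
    olig = u[..., 1] + u[..., 2] + u[..., 3]
    return C_tau * np.maximum(olig - U_bar, 0.0)


def abeta_rhs(
    field: ProteinField,
    proximity: WeightedGraph,
    params: ModelParams,
    production: np.ndarray,
) -> np.ndarray:
    """Time derivatives of the amyloid-beta compartments, shape (N, 5).

    du_1/dt = (1/eps) [ -d_1 L u_1 - alpha u_1 U + F - sigma_1 u_1 ]
    du_i/dt = (1/eps) [ -d_i L u_i + gain_i - loss_i - sigma_i u_i ],  i = 2..4
    du_5/dt = (1/eps) gain_5

    where L is the proximity-graph Laplacian and U the total concentration.
    The ``1/epsilon`` division happens here, so the engine integrates plain
    derivatives for both species.
    """
    u = field.u
    if u.shape[0] != proximity.node_count:
        raise ContractError(
            f"field has {u.shape[0]} nodes, proximity graph has {proximity.node_count}"
        )
    production = np.asarray(production, dtype=float)
    if production.shape != (u.shape[0],):
        raise ContractError("production must be a per-node scalar field")
    if np.min(production, initial=0.0) < -NEG_ATOL:
        raise ContractError("production must be nonnegative")
    alpha = params.require_scenario().alpha
    gain = coagulation_gain(u, alpha)
    loss = coagulation_loss(u, alpha)
    d = np.asarray(params.d)
    du = gain - loss
    du[:, :4] -= d * proximity.apply_laplacian(u[:, :4])
    du[:, :4] -= np.asarray(params.sigma) * np.maximum(u[:, :4], 0.0)
    du[:, 0] += production
    du /= params.epsilon
    return du


def tau_rhs(
    field: ProteinField,
    connectivity: WeightedGraph,
    params: ModelParams,
    t: float,
    seed: np.ndarray,
) -> np.ndarray:
    """Time derivatives of the misfolded-tau compartments, shape (N, 5).

    dtau_1/dt = -d~_1 L tau_1 - loss_1 + c s_tau(t) chi_seed + C_tau (u_2+u_3+u_4 - U_bar)^+
    dtau_i/dt = -d~_i L tau_i + gain_i - loss_i,   i = 2..4   (no clearance)
    dtau_5/dt = gain_5

    with L the connectivity-graph Laplacian; no ``epsilon`` factor — tau
    evolves on the slow time scale.
    """
    tau = field.tau
    if tau.shape[0] != connectivity.node_count:
        raise ContractError(
            f"field has {tau.shape[0]} nodes, connectivity graph has {connectivity.node_count}"
        )
    seed = np.asarray(seed, dtype=float)
    if seed.shape != (tau.shape[0],):
        raise ContractError("seed indicator must be a per-node field")
    p = params.require_scenario()
    gain = coagulation_gain(tau, p.gamma)
    loss = coagulation_loss(tau, p.gamma)
    dtau = gain - loss
    dtau[:, :4] -= np.asarray(p.d_tilde) * connectivity.apply_laplacian(tau[:, :4])
    dtau[:, 0] += p.c * tau_seed_source(t, p.lambda_) * seed
    dtau[:, 0] += abeta_induced_production(field.u, p.C_tau, p.U_bar)
    return dtau
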