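"""Coupled time integration of proteins and health density.

The simulation starts from a healthy brain: a small uniform amyloid-beta
monomer level, no oligomers, no misfolded tau, and a near-delta health
density at ``a`` close to 0.  Each time step is operator-split:

1. freeze the health density; evaluate the amyloid production ``F(f)`` and
   the deterioration rate ``v`` per node;
2. advance both protein systems by one classical RK4 stage sequence;
3. advance the health density by one conservative upwind transport step
   with the frozen ``v``.

The step size adapts to the stiffness of the fast amyloid-beta system
(rates scale like ``alpha * total_concentration / epsilon``, which grows as
plaques accumulate) and to the transport CFL condition.  A step that
produces negativity beyond round-off, non-finite values, or a CFL violation
is rejected and retried at ``dt/2``; positivity is treated as a model
invariant, not a numerical suggestion, so negativity within ``-1e-12`` is
clamped to zero and anything larger rejects the step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .connectome import (
    Parcellation,
    WeightedGraph,
    load_graph,
    load_parcellation,
    seed_indicator,
    synthesize_connectome,
)
from .health import (
    AGrid,
    CFLError,
    HealthDensity,
    amyloid_production,
    deterioration_rate,
    initial_density,
    mean_malfunction,
    transport_step,
)
from .params import ModelParams, RunConfig
from .protein import NEG_ATOL, ContractError, ProteinField, abeta_rhs, tau_rhs


class StepRejected(RuntimeError):
    """A trial step violated a stability or positivity check."""


@dataclass
class SimState:
    """Full model state at one instant."""

    t: float
    proteins: ProteinField
    health: HealthDensity

    def copy(self) -> "SimState":
        return SimState(self.t, self.proteins.copy(), self.health.copy())


@dataclass
class Trajectory:
    """Sampled observables of one run, plus provenance metadata.

    Burdens are per-sample means over nodes (global) or over region members
    (regional); ``A_*`` series are the mean degree of malfunctioning.
    """

    times: np.ndarray                 # (S,)
    u_global: np.ndarray              # (S, 5)
    tau_global: np.ndarray            # (S, 5)
    u_regional: np.ndarray            # (S, n_regions, 5)
    tau_regional: np.ndarray          # (S, n_regions, 5)
    A_node: np.ndarray                # (S, N)
    A_regional: np.ndarray            # (S, n_regions)
    A_global: np.ndarray              # (S,)
    f_mass: np.ndarray                # (S, N)
    final_state: SimState
    parcellation: Parcellation
    metadata: dict
    snapshots: Optional[list] = field(default=None, repr=False)


def initialize(
    params: ModelParams,
    parcellation: Parcellation,
    connectivity: WeightedGraph,
    proximity: WeightedGraph,
    grid: AGrid,
    *,
    u01: float = 0.01,
    a0_center: float = 0.01,
    a0_width_cells: float = 3.0,
) -> SimState:
    """Healthy-brain initial state: ``u_1 = u01`` uniform, all else zero."""
    n = parcellation.node_count
    if connectivity.node_count != n or proximity.node_count != n:
        raise ValueError("parcellation and graphs must share the same node set")
    params.require_scenario()
    if params.c > 0 and parcellation.seed_nodes.size == 0:
        raise ValueError("tau seeding is active (c > 0) but V_seed is empty")
    proteins = ProteinField.zeros(n)
    proteins.u[:, 0] = u01
    f0 = initial_density(grid, a0_center, a0_width_cells * grid.delta)
    health = HealthDensity(np.tile(f0, (n, 1)), grid)
    return SimState(0.0, proteins, health)


def step(
    state: SimState,
    connectivity: WeightedGraph,
    proximity: WeightedGraph,
    params: ModelParams,
    grid: AGrid,
    seed_chi: np.ndarray,
    dt: float,
) -> SimState:
    """One operator-split step; raises :class:`StepRejected` on instability."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    u = state.proteins.u
    tau = state.proteins.tau
    f = state.health.values
    t = state.t

    # (1) frozen health functionals
    F = amyloid_production(f, grid, params.C_F, params.mu0)
    olig = u[:, 1:4].sum(axis=1)
    tausum = tau.sum(axis=1)
    v = deterioration_rate(f, grid, olig, tausum, params)

    # (2) RK4 on the two protein systems
    def rhs(tt: float, uu: np.ndarray, tt_arr: np.ndarray):
        fld = ProteinField(uu, tt_arr)
        return (
            abeta_rhs(fld, proximity, params, F),
            tau_rhs(fld, connectivity, params, tt, seed_chi),
        )

    try:
        ku1, kt1 = rhs(t, u, tau)
        ku2, kt2 = rhs(t + 0.5 * dt, u + 0.5 * dt * ku1, tau + 0.5 * dt * kt1)
        ku3, kt3 = rhs(t + 0.5 * dt, u + 0.5 * dt * ku2, tau + 0.5 * dt * kt2)
        ku4, kt4 = rhs(t + dt, u + dt * ku3, tau + dt * kt3)
    except ContractError as exc:
        raise StepRejected(f"stage state left the admissible set: {exc}") from exc
    u_new = u + (dt / 6.0) * (ku1 + 2.0 * ku2 + 2.0 * ku3 + ku4)
    tau_new = tau + (dt / 6.0) * (kt1 + 2.0 * kt2 + 2.0 * kt3 + kt4)

    for name, arr in (("u", u_new), ("tau", tau_new)):
        if not np.all(np.isfinite(arr)):
            raise StepRejected(f"non-finite values in {name}")
        if arr.min() < -NEG_ATOL:
            raise StepRejected(f"negativity beyond round-off in {name} (min {arr.min():.3e})")
    np.maximum(u_new, 0.0, out=u_new)
    np.maximum(tau_new, 0.0, out=tau_new)

    # (3) transport with the frozen drift
    try:
        f_new = transport_step(f, v, dt, grid)
    except CFLError as exc:
        raise StepRejected(str(exc)) from exc

    return SimState(t + dt, ProteinField(u_new, tau_new), HealthDensity(f_new, grid))


def _stable_dt(
    u: np.ndarray, tau: np.ndarray, params: ModelParams, grid: AGrid
) -> float:
    """Step bound from the fastest linearised reaction/diffusion rate and the CFL.

    The amyloid system carries the ``1/epsilon`` factor and its aggregation
    loss grows with the total concentration (plaques included), so the bound
    is recomputed every step.
    """
    u_tot = float(u.sum(axis=1).max(initial=0.0))
    tau_tot = float(tau.sum(axis=1).max(initial=0.0))
    rate_u = (2.0 * max(params.d) + max(params.sigma) + 2.0 * params.alpha * u_tot)
    rate_u /= params.epsilon
    rate_tau = 2.0 * max(params.d_tilde) + 2.0 * params.gamma * tau_tot
    dt_react = 1.0 / max(rate_u, rate_tau, 1e-9)
    olig = u[:, 1:4].sum(axis=1)
    v_bound = (
        params.C_G
        + params.C_S * max(float(olig.max(initial=0.0)) - params.U_bar_abeta, 0.0)
        + params.C_T * max(float(tau.sum(axis=1).max(initial=0.0)) - params.U_bar_tau, 0.0)
    )
    dt_cfl = 0.9 * grid.delta / max(v_bound, 1e-9)
    return min(dt_react, dt_cfl)


def simulate(
    params: ModelParams,
    parcellation: Parcellation,
    connectivity: WeightedGraph,
    proximity: WeightedGraph,
    *,
    t_end: float,
    a_cells: int = 101,
    u01: float = 0.01,
    a0_center: float = 0.01,
    a0_width_cells: float = 3.0,
    sample_dt: float = 0.25,
    dt_scale: float = 1.0,
    dt_max: Optional[float] = None,
    record_snapshots: bool = False,
    metadata: Optional[dict] = None,
) -> Trajectory:
    """Integrate the coupled system from 0 to ``t_end`` and record observables."""
    grid = AGrid(a_cells)
    state = initialize(
        params, parcellation, connectivity, proximity, grid,
        u01=u01, a0_center=a0_center, a0_width_cells=a0_width_cells,
    )
    chi = seed_indicator(parcellation)
    n_regions = parcellation.n_regions
    sizes = parcellation.region_sizes()
    region_mat = np.zeros((n_regions, parcellation.node_count))
    for j in range(n_regions):
        region_mat[j, parcellation.region_members(j)] = 1.0 / sizes[j]

    sample_times = list(np.arange(0.0, t_end, sample_dt))
    if not np.isclose(sample_times[-1], t_end):
        sample_times.append(t_end)
    else:
        sample_times[-1] = t_end

    rec: dict[str, list] = {k: [] for k in (
        "t", "u_g", "tau_g", "u_r", "tau_r", "A_node", "A_r", "A_g", "mass"
    )}
    snapshots: Optional[list] = [] if record_snapshots else None

    def record(s: SimState) -> None:
        u, tau, f = s.proteins.u, s.proteins.tau, s.health.values
        A = mean_malfunction(f, grid)
        rec["t"].append(s.t)
        rec["u_g"].append(u.mean(axis=0))
        rec["tau_g"].append(tau.mean(axis=0))
        rec["u_r"].append(region_mat @ u)
        rec["tau_r"].append(region_mat @ tau)
        rec["A_node"].append(A)
        rec["A_r"].append(region_mat @ A)
        rec["A_g"].append(A.mean())
        rec["mass"].append(f.sum(axis=1) * grid.delta)
        if snapshots is not None:
            snapshots.append(s.copy())

    record(state)
    next_idx = 1
    n_steps = n_rejected = 0
    dt_min_seen, dt_max_seen = np.inf, 0.0
    while state.t < t_end - 1e-12:
        dt = dt_scale * _stable_dt(state.proteins.u, state.proteins.tau, params, grid)
        if dt_max is not None:
            dt = min(dt, dt_max)
        dt = min(dt, sample_times[next_idx] - state.t)
        while True:
            try:
                new_state = step(state, connectivity, proximity, params, grid, chi, dt)
                break
            except StepRejected as exc:
                n_rejected += 1
                dt *= 0.5
                if dt < 1e-12:
                    raise RuntimeError(
                        "time step underflow after repeated halving at "
                        f"t={state.t:.6g}: {exc}; state summary: "
                        f"max u={state.proteins.u.max():.3e}, "
                        f"max tau={state.proteins.tau.max():.3e}"
                    ) from exc
        state = new_state
        n_steps += 1
        dt_min_seen = min(dt_min_seen, dt)
        dt_max_seen = max(dt_max_seen, dt)
        if state.t >= sample_times[next_idx] - 1e-12:
            record(state)
            next_idx += 1

    meta = dict(metadata or {})
    meta.update(
        {
            "n_steps": n_steps,
            "n_rejected": n_rejected,
            "dt_min": None if n_steps == 0 else dt_min_seen,
            "dt_max": None if n_steps == 0 else dt_max_seen,
            "a_cells": a_cells,
            "t_end": t_end,
            "u01": u01,
            "a0_center": a0_center,
            "sample_dt": sample_dt,
            "dt_scale": dt_scale,
            "connectivity_hash": connectivity.content_hash(),
            "proximity_hash": proximity.content_hash(),
            "params": {
                k: getattr(params, k)
                for k in ("epsilon", "alpha", "gamma", "c", "C_tau", "lambda_")
            },
        }
    )
    return Trajectory(
        times=np.array(rec["t"]),
        u_global=np.array(rec["u_g"]),
        tau_global=np.array(rec["tau_g"]),
        u_regional=np.array(rec["u_r"]),
        tau_regional=np.array(rec["tau_r"]),
        A_node=np.array(rec["A_node"]),
        A_regional=np.array(rec["A_r"]),
        A_global=np.array(rec["A_g"]),
        f_mass=np.array(rec["mass"]),
        final_state=state,
        parcellation=parcellation,
        metadata=meta,
        snapshots=snapshots,
    )


def build_connectome(config: RunConfig):
    """Materialise the (parcellation, connectivity, proximity) of a config."""
    if config.edges_path is not None:
        connectivity = load_graph(config.edges_path)
        parcellation = load_parcellation(config.parcels_path)
        if parcellation.coords is None:
            raise ValueError(
                "a real connectome needs parcel coordinates to build the proximity graph"
            )
        from .connectome import _proximity_graph

        proximity = _proximity_graph(parcellation.coords, k_neighbors=4)
        return parcellation, connectivity, proximity
    syn = config.synthetic
    return synthesize_connectome(
        syn.n_nodes, syn.n_regions, syn.rng_seed, k_neighbors=syn.k_neighbors
    )


def run(config: RunConfig) -> Trajectory:
    """Execute one configured run end to end; deterministic given the config."""
    parcellation, connectivity, proximity = build_connectome(config)
    params = config.params.require_scenario()
    meta = {"case": config.case, "config": config.to_dict()}
    return simulate(
        params,
        parcellation,
        connectivity,
        proximity,
        t_end=config.t_end,
        a_cells=config.a_cells,
        u01=config.u01,
        a0_center=config.a0_center,
        a0_width_cells=config.a0_width_cells,
        sample_dt=config.sample_dt,
        dt_scale=config.dt_scale,
        dt_max=config.dt_max,
        record_snapshots=config.record_snapshots,
        metadata=meta,
    )


def write_run_log(trajectory: Trajectory, path) -> None:
    """JSON run log: parameters, grids, step statistics, connectome hashes."""
    meta = dict(trajectory.metadata)
    meta["n_samples"] = int(trajectory.times.size)
    with open(Path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=float)
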