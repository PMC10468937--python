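"""Macroscopic disease read-outs: burdens and damage.

Global burdens average each compartment's concentration over all parcels
(all parcels are assumed to have the same volume); regional burdens average
over the members of one region of the partition.  Damage is the mean degree
of malfunctioning ``A``, per node, per region and globally.  Time series
export to tidy long-format CSV; a JSON summary collects peak times/values
and final damage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Parcellation
from .engine import SimState, Trajectory
from .health import mean_malfunction

_SPECIES = ("abeta", "tau")


def _species_values(state: SimState, species: str) -> np.ndarray:
    if species == "abeta":
        return state.proteins.u
    if species == "tau":
        return state.proteins.tau
    raise ValueError(f"unknown species {species!r}; use 'abeta' or 'tau'")


def global_burden(state: SimState, compartment: int, species: str) -> float:
    """Mean concentration of ``compartment`` (1..5) over all parcels."""
    if not 1 <= compartment <= 5:
        raise ValueError(f"compartment must be 1..5, got {compartment}")
    vals = _species_values(state, species)
    return float(vals[:, compartment - 1].mean())


def regional_burden(
    state: SimState,
    parcellation: Parcellation,
    region: int,
    compartment: int,
    species: str,
) -> float:
    """Mean concentration of ``compartment`` over the nodes of one region."""
    if not 1 <= compartment <= 5:
        raise ValueError(f"compartment must be 1..5, got {compartment}")
    members = parcellation.region_members(region)
    if members.size == 0:
        raise ValueError(f"region {region} is empty")
    vals = _species_values(state, species)
    return float(vals[members, compartment - 1].mean())


@dataclass(frozen=True)
class BurdenSeries:
    """Global and regional burden time series for both species."""

    times: np.ndarray
    u_global: np.ndarray        # (S, 5)
    tau_global: np.ndarray      # (S, 5)
    u_regional: np.ndarray      # (S, n_regions, 5)
    tau_regional: np.ndarray
    region_labels: tuple


@dataclass(frozen=True)
class DamageSeries:
    """Per-node, regional and global mean malfunction over time."""

    times: np.ndarray
    A_node: np.ndarray          # (S, N)
    A_regional: np.ndarray      # (S, n_regions)
    A_global: np.ndarray        # (S,)
    region_labels: tuple


def burden_series(trajectory: Trajectory) -> BurdenSeries:
    return BurdenSeries(
        times=trajectory.times,
        u_global=trajectory.u_global,
        tau_global=trajectory.tau_global,
        u_regional=trajectory.u_regional,
        tau_regional=trajectory.tau_regional,
        region_labels=trajectory.parcellation.region_labels,
    )


def damage_series(trajectory: Trajectory, parcellation: Parcellation | None = None) -> DamageSeries:
    """Damage read-outs of a trajectory (recomputed from snapshots if present)."""
    parc = parcellation or trajectory.parcellation
    if trajectory.snapshots:
        grid = trajectory.final_state.health.grid
        A_node = np.array(
            [mean_malfunction(s.health.values, grid) for s in trajectory.snapshots]
        )
        times = np.array([s.t for s in trajectory.snapshots])
    else:
        A_node = trajectory.A_node
        times = trajectory.times
    sizes = parc.region_sizes()
    region_mat = np.zeros((parc.n_regions, parc.node_count))
    for j in range(parc.n_regions):
        region_mat[j, parc.region_members(j)] = 1.0 / sizes[j]
    A_regional = A_node @ region_mat.T
    return DamageSeries(
        times=times,
        A_node=A_node,
        A_regional=A_regional,
        A_global=A_node.mean(axis=1),
        region_labels=parc.region_labels,
    )


def _tidy_frame(series) -> pd.DataFrame:
    """Long format: time, species, compartment, region, value."""
    rows: list[pd.DataFrame] = []
    if isinstance(series, BurdenSeries):
        for species, g, r in (
            ("abeta", series.u_global, series.u_regional),
            ("tau", series.tau_global, series.tau_regional),
        ):
            for i in range(5):
                rows.append(pd.DataFrame({
                    "time": series.times, "species": species,
                    "compartment": i + 1, "region": "global", "value": g[:, i],
                }))
                for j, label in enumerate(series.region_labels):
                    rows.append(pd.DataFrame({
                        "time": series.times, "species": species,
                        "compartment": i + 1, "region": label, "value": r[:, j, i],
                    }))
    elif isinstance(series, DamageSeries):
        rows.append(pd.DataFrame({
            "time": series.times, "species": "damage", "compartment": 0,
            "region": "global", "value": series.A_global,
        }))
        for j, label in enumerate(series.region_labels):
            rows.append(pd.DataFrame({
                "time": series.times, "species": "damage", "compartment": 0,
                "region": label, "value": series.A_regional[:, j],
            }))
    else:
        raise TypeError(f"cannot export object of type {type(series).__name__}")
    if not rows:
        return pd.DataFrame(columns=["time", "species", "compartment", "region", "value"])
    return pd.concat(rows, ignore_index=True)


def export_csv(series, path) -> Path:
    """Write a burden or damage series as tidy long-format CSV."""
    path = Path(path)
    frame = _tidy_frame(series)
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def read_series_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def peak(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """(argmax time, max value); ties resolve to the earliest sample."""
    k = int(np.argmax(values))
    return float(times[k]), float(values[k])


def summarize(trajectory: Trajectory) -> dict:
    """Peak time/value per species and compartment, plus final damage."""
    out: dict = {"case": trajectory.metadata.get("case"), "peaks": {}, "final": {}}
    for species, g in (("abeta", trajectory.u_global), ("tau", trajectory.tau_global)):
        out["peaks"][species] = {}
        for i in range(5):
            t_pk, v_pk = peak(trajectory.times, g[:, i])
            out["peaks"][species][f"compartment_{i + 1}"] = {"time": t_pk, "value": v_pk}
    out["final"]["A_global"] = float(trajectory.A_global[-1])
    out["final"]["A_regional"] = {
        label: float(trajectory.A_regional[-1, j])
        for j, label in enumerate(trajectory.parcellation.region_labels)
    }
    out["final"]["tangle_regional"] = {
        label: float(trajectory.tau_regional[-1, j, 4])
        for j, label in enumerate(trajectory.parcellation.region_labels)
    }
    out["final"]["plaque_global"] = float(trajectory.u_global[-1, 4])
    out["final"]["tangle_global"] = float(trajectory.tau_global[-1, 4])
    return out


def write_summary(trajectory: Trajectory, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(summarize(trajectory), fh, indent=2, sort_keys=True)
    return path
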