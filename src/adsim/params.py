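"""Model constants, scenario presets and run configuration.

All rates are dimensionless.  The fixed constants (clearance, diffusion,
thresholds, the time-scale ratio ``epsilon``) come from the published
parameter table; the three scenario constants are left unset until a case
is chosen, because the model's conclusions hinge on them:

* ``alpha``  — amyloid-beta coalescence probability,
* ``C_tau``  — production of misfolded tau induced by amyloid-beta oligomers,
* ``c``      — amplitude of the Gamma-shaped tau seeding at the entorhinal
  cortex.

The five scenario presets:

=====  =====  =====  ====
case   alpha  C_tau  c
=====  =====  =====  ====
A      10     0      0
B      10     0      0.05
C      10     10     0.05
D      10     10     0
E      0      10     0.05
=====  =====  =====  ====

Case A is a simplified amyloid-cascade hypothesis (no tau at all); B and D
switch off one tau source each; C includes everything; E emulates a drug
that blocks amyloid aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Invalid model parameter or run-configuration value."""


@dataclass(frozen=True)
class ModelParams:
    """All model constants.

    ``d``, ``d_tilde`` and ``sigma`` hold the coefficients for compartments
    1..4 only: compartment 5 (plaques/tangles) neither diffuses nor clears,
    so those coefficients are structurally absent rather than set to zero.
    """

    epsilon: float = 0.1        # fast/slow time-scale ratio of the Abeta system
    gamma: float = 4.0          # tau coalescence probability
    lambda_: float = 10.0       # time scale of the Gamma-shaped tau seeding
    U_bar: float = 0.001        # Abeta-oligomer threshold for induced tau production
    d: tuple = (1.0, 1 / 2, 1 / 3, 1 / 4)        # Abeta diffusion, compartments 1..4
    d_tilde: tuple = (1.0, 1 / 2, 1 / 3, 1 / 4)  # tau diffusion, compartments 1..4
    sigma: tuple = (1.0, 1 / 2, 1 / 3, 1 / 4)    # Abeta clearance, compartments 1..4
    C_G: float = 0.1            # prion-like propagation constant
    C_S: float = 0.01           # Abeta toxicity constant
    C_T: float = 0.01           # tau toxicity constant
    U_bar_abeta: float = 0.001  # Abeta toxicity threshold
    U_bar_tau: float = 0.001    # tau toxicity threshold
    C_F: float = 10.0           # Abeta production constant
    mu0: float = 0.01           # baseline (healthy-neuron) production level
    # scenario constants: no silent defaults
    alpha: Optional[float] = None
    C_tau: Optional[float] = None
    c: Optional[float] = None

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ConfigError(f"epsilon must be > 0, got {self.epsilon}")
        if not self.lambda_ > 0:
            raise ConfigError(f"lambda must be > 0, got {self.lambda_}")
        for name in ("gamma", "U_bar", "C_G", "C_S", "C_T", "U_bar_abeta",
                     "U_bar_tau", "C_F", "mu0"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative, got {getattr(self, name)}")
        for name in ("alpha", "C_tau", "c"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ConfigError(f"{name} must be nonnegative, got {val}")
        for name in ("d", "d_tilde", "sigma"):
            vec = tuple(float(v) for v in getattr(self, name))
            if len(vec) != 4:
                raise ConfigError(f"{name} must have 4 entries (compartments 1..4)")
            if any(v < 0 for v in vec):
                raise ConfigError(f"{name} entries must be nonnegative")
            object.__setattr__(self, name, vec)
        for name in ("d", "d_tilde"):
            vec = getattr(self, name)
            if any(vec[i + 1] > vec[i] for i in range(3)):
                raise ConfigError(f"{name} must be nonincreasing: larger oligomers diffuse slower")

    def require_scenario(self) -> "ModelParams":
        """Fail unless the scenario constants alpha, C_tau, c are all set."""
        missing = [n for n in ("alpha", "C_tau", "c") if getattr(self, n) is None]
        if missing:
            raise ConfigError(
                f"scenario constants {missing} are unset: name a case A-E or set them explicitly"
            )
        return self

    def with_scenario(self, alpha: float, C_tau: float, c: float) -> "ModelParams":
        return replace(self, alpha=float(alpha), C_tau=float(C_tau), c=float(c))


@dataclass(frozen=True)
class ScenarioCase:
    """One row of the scenario table: a label and its (alpha, C_tau, c)."""

    label: str
    alpha: float
    C_tau: float
    c: float


SCENARIOS: dict[str, ScenarioCase] = {
    "A": ScenarioCase("A", 10.0, 0.0, 0.0),
    "B": ScenarioCase("B", 10.0, 0.0, 0.05),
    "C": ScenarioCase("C", 10.0, 10.0, 0.05),
    "D": ScenarioCase("D", 10.0, 10.0, 0.0),
    "E": ScenarioCase("E", 0.0, 10.0, 0.05),
}


def default_params() -> ModelParams:
    """Fixed constants of the model; scenario constants left unset."""
    return ModelParams()


def scenario_params(case: str) -> ModelParams:
    """Fixed constants plus the (alpha, C_tau, c) preset of ``case`` A-E."""
    try:
        sc = SCENARIOS[case.upper()]
    except (KeyError, AttributeError):
        raise ConfigError(f"unknown scenario case {case!r}; choose one of A, B, C, D, E")
    return default_params().with_scenario(sc.alpha, sc.C_tau, sc.c)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_PARAM_KEYS = {f.name for f in fields(ModelParams)}
# config files may spell lambda without the trailing underscore
_PARAM_ALIASES = {"lambda": "lambda_"}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the built-in synthetic-connectome generator."""

    n_nodes: int = 64
    n_regions: int = 8
    rng_seed: int = 0
    k_neighbors: int = 4


@dataclass(frozen=True)
class RunConfig:
    """Complete, explicit description of one simulation run."""

    case: Optional[str] = "C"
    params: ModelParams = field(default_factory=lambda: scenario_params("C"))
    synthetic: Optional[SyntheticSpec] = field(default_factory=SyntheticSpec)
    edges_path: Optional[str] = None      # real connectome: edge-list CSV / GraphML
    parcels_path: Optional[str] = None    # real connectome: parcel table CSV
    t_end: float = 50.0
    a_cells: int = 101
    u01: float = 0.01                     # initial uniform Abeta monomer level (<< 1)
    a0_center: float = 0.01               # centre of the near-delta initial health density
    a0_width_cells: float = 3.0           # its half-width, in multiples of the cell size
    sample_dt: float = 0.25
    dt_scale: float = 1.0                 # multiplies the adaptive step bound (refinement studies)
    dt_max: Optional[float] = None
    record_snapshots: bool = False

    def __post_init__(self):
        if self.t_end <= 0:
            raise ConfigError(f"t_end must be > 0, got {self.t_end}")
        if self.a_cells < 8:
            raise ConfigError(f"a_cells must be >= 8, got {self.a_cells}")
        if not 0 <= self.u01 < 1:
            raise ConfigError(f"u01 must lie in [0, 1) (a healthy brain has u01 << 1)")
        if self.sample_dt <= 0:
            raise ConfigError("sample_dt must be > 0")
        if self.dt_scale <= 0:
            raise ConfigError("dt_scale must be > 0")
        if (self.edges_path is None) != (self.parcels_path is None):
            raise ConfigError("edges_path and parcels_path must be given together")
        if self.edges_path is None and self.synthetic is None:
            raise ConfigError("a run needs either a synthetic connectome spec or file paths")
        self.params.require_scenario()

    def to_dict(self) -> dict:
        p = {k: getattr(self.params, k) for k in sorted(_PARAM_KEYS)}
        p = {k: (list(v) if isinstance(v, tuple) else v) for k, v in p.items()}
        out = {
            "case": self.case,
            "params": p,
            "t_end": self.t_end,
            "a_cells": self.a_cells,
            "u01": self.u01,
            "a0_center": self.a0_center,
            "a0_width_cells": self.a0_width_cells,
            "sample_dt": self.sample_dt,
            "dt_scale": self.dt_scale,
            "dt_max": self.dt_max,
            "record_snapshots": self.record_snapshots,
        }
        if self.synthetic is not None:
            out["synthetic"] = {
                "n_nodes": self.synthetic.n_nodes,
                "n_regions": self.synthetic.n_regions,
                "rng_seed": self.synthetic.rng_seed,
                "k_neighbors": self.synthetic.k_neighbors,
            }
        if self.edges_path is not None:
            out["edges_path"] = self.edges_path
            out["parcels_path"] = self.parcels_path
        return out


_RUN_KEYS = {
    "case", "params", "synthetic", "edges_path", "parcels_path", "t_end", "a_cells",
    "u01", "a0_center", "a0_width_cells", "sample_dt", "dt_scale", "dt_max",
    "record_snapshots",
}


def config_from_dict(raw: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain mapping."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    case = raw.get("case", "C" if "params" not in raw or _scenario_unset(raw) else None)
    if case is not None:
        params = scenario_params(case)
    else:
        params = default_params()

    overrides = dict(raw.get("params") or {})
    unknown_p = set(_PARAM_ALIASES.get(k, k) for k in overrides) - _PARAM_KEYS
    if unknown_p:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown_p)}")
    kwargs = {}
    for key, val in overrides.items():
        key = _PARAM_ALIASES.get(key, key)
        if key in ("d", "d_tilde", "sigma"):
            val = tuple(float(v) for v in val)
        kwargs[key] = val
    if kwargs:
        try:
            params = replace(params, **kwargs)
        except ConfigError:
            raise
    syn_raw = raw.get("synthetic")
    synthetic = SyntheticSpec(**syn_raw) if isinstance(syn_raw, dict) else (
        None if raw.get("edges_path") else SyntheticSpec()
    )
    cfg_kwargs = {
        k: raw[k]
        for k in _RUN_KEYS - {"case", "params", "synthetic"}
        if k in raw
    }
    return RunConfig(case=case, params=params, synthetic=synthetic, **cfg_kwargs)


def _scenario_unset(raw: dict) -> bool:
    p = raw.get("params") or {}
    return not {"alpha", "C_tau", "c"}.issubset(p)


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    try:
        return config_from_dict(raw)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(config: RunConfig, path) -> None:
    """Write a configuration so that :func:`load_config` reproduces it."""
    path = Path(path)
    data = config.to_dict()
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(data, fh, sort_keys=True)
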