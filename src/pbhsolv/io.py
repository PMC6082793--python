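"""Configuration loading and result writers/readers.

Curves and maps are written as long-format CSV (one observation per row)
with ``#``-prefixed header comments embedding the resolved parameters and
package version; trajectories use HDF5 with the documented group layout;
reports are JSON.  Every written artifact can be read back into an equal
in-memory object.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .continuum import ContinuumCoefficients
from .dynamics import InitialWave, SimulationSettings, Trajectory
from .errors import ConfigError, UnknownFixtureError
from .mi import GainCurve, GainSurface, StabilityMap
from .model import MicroscopicParameters, PotentialProfile

__all__ = [
    "RunConfig", "load_config", "save_config", "resolve_parameters",
    "write_results", "write_trajectory", "read_trajectory",
    "write_profile", "read_profile", "write_gain_curve", "read_gain_curve",
    "write_gain_surface", "read_gain_surface",
    "write_stability_map", "read_stability_map",
    "write_report", "read_report",
]


@dataclass
class RunConfig:
    """Fully resolved run configuration.

    Exactly one of ``fixture`` (a registry name) or ``parameters`` (inline
    values) must be given in the source file.
    """

    parameters: MicroscopicParameters
    simulation: SimulationSettings
    wave: InitialWave
    fixture: str | None = None
    continuum: ContinuumCoefficients | None = None
    outputs: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        out = {
            "parameters": self.parameters.to_dict(),
            "simulation": dataclasses.asdict(self.simulation),
            "wave": dataclasses.asdict(self.wave),
            "outputs": dict(self.outputs),
            "log_level": self.log_level,
        }
        # parameters are always emitted inline (the fixture name is kept only
        # in memory) so the echoed config satisfies the exactly-one rule
        if self.continuum is not None:
            out["continuum"] = self.continuum.to_dict()
        return out


_VALID_TOP_KEYS = {"parameters", "fixture", "continuum", "simulation", "wave",
                   "outputs", "log_level"}


def _build(cls, data: dict, keypath: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{keypath}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{keypath}: {exc}") from exc


def resolve_parameters(raw: dict) -> RunConfig:
    """Validate a raw config mapping and resolve fixtures and defaults."""
    from .fixtures import figure_parameter_registry

    unknown = set(raw) - _VALID_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    has_inline = "parameters" in raw
    has_fixture = "fixture" in raw
    if has_inline == has_fixture:
        raise ConfigError(
            "exactly one of 'parameters' (inline) or 'fixture' (name) is required")
    wave = None
    if has_fixture:
        registry = figure_parameter_registry()
        name = raw["fixture"]
        if name not in registry:
            raise UnknownFixtureError(
                f"fixture: unknown fixture {name!r}; known: {sorted(registry)}")
        entry = registry[name]
        params = entry.micro
        wave = entry.wave
    else:
        params = _build(MicroscopicParameters, dict(raw["parameters"]), "parameters")
    if "wave" in raw:
        wave = _build(InitialWave, dict(raw["wave"]), "wave")
    if wave is None:
        wave = InitialWave()
    simulation = _build(SimulationSettings, dict(raw.get("simulation", {})), "simulation")
    continuum = None
    if "continuum" in raw:
        continuum = _build(ContinuumCoefficients, dict(raw["continuum"]), "continuum")
    return RunConfig(parameters=params, simulation=simulation, wave=wave,
                     fixture=raw.get("fixture"), continuum=continuum,
                     outputs=dict(raw.get("outputs", {})),
                     log_level=str(raw.get("log_level", "INFO")))


def load_config(path) -> RunConfig:
    """Parse and schema-validate a YAML/JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return resolve_parameters(raw)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# writers / readers

def _meta_comment(meta: dict) -> str:
    return f"# pbhsolv {__version__}\n# meta: {json.dumps(meta, sort_keys=True)}\n"


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# meta: "):
                meta = json.loads(line[len("# meta: "):])
    return meta


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_trajectory(traj: Trajectory, path, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fields = fh.create_group("fields")
        fields["lambda"] = traj.lambda_field
        fields["w"] = traj.w_field
        fields["theta"] = traj.theta_field
        fields["phi"] = traj.phi_field
        fields["B_real"] = traj.B_field.real
        fields["B_imag"] = traj.B_field.imag
        obs = fh.create_group("observables")
        obs["times"] = traj.times
        obs["energy"] = traj.energy_series
        obs["norm"] = traj.norm_series
        m = fh.create_group("meta")
        m.attrs["package_version"] = __version__
        for key, val in (meta or {}).items():
            m.attrs[key] = json.dumps(val) if isinstance(val, (dict, list)) else val


def read_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        return Trajectory(
            times=fh["observables/times"][:],
            lambda_field=fh["fields/lambda"][:],
            w_field=fh["fields/w"][:],
            theta_field=fh["fields/theta"][:],
            phi_field=fh["fields/phi"][:],
            B_field=fh["fields/B_real"][:] + 1j * fh["fields/B_imag"][:],
            energy_series=fh["observables/energy"][:],
            norm_series=fh["observables/norm"][:])


def write_profile(profile: PotentialProfile, path) -> None:
    """2-column CSV (lambda_angstrom, energy_eV) with the full parameter set
    recorded in the header comment."""
    meta = {
        "kind": "potential_profile",
        "params": profile.params.to_dict(),
        "phi_angle": profile.phi_angle,
        "theta": profile.theta,
        "solvent_orientation": profile.solvent_orientation,
    }
    df = pd.DataFrame({"lambda_angstrom": profile.lambda_grid,
                       "energy_eV": profile.energy})
    with open(path, "w") as fh:
        fh.write(_meta_comment(meta))
        df.to_csv(fh, index=False)


def read_profile(path) -> PotentialProfile:
    path = Path(path)
    meta = _read_meta(path)
    df = _read_csv(path)
    return PotentialProfile(
        lambda_grid=df["lambda_angstrom"].to_numpy(),
        energy=df["energy_eV"].to_numpy(),
        phi_angle=meta["phi_angle"], theta=meta["theta"],
        params=MicroscopicParameters.from_dict(meta["params"]),
        solvent_orientation=meta["solvent_orientation"])


def write_gain_curve(curve: GainCurve, path, meta: dict | None = None) -> None:
    cols = {"k1": curve.k1, "gain": curve.gain}
    for i in range(curve.roots.shape[1]):
        cols[f"root{i}_re"] = curve.roots[:, i].real
        cols[f"root{i}_im"] = curve.roots[:, i].imag
    header = {"kind": "gain_curve", "mode": curve.mode, **(meta or {})}
    with open(path, "w") as fh:
        fh.write(_meta_comment(header))
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_gain_curve(path) -> GainCurve:
    meta = _read_meta(Path(path))
    df = _read_csv(Path(path))
    n_roots = sum(1 for c in df.columns if c.endswith("_re"))
    roots = np.empty((len(df), n_roots), dtype=complex)
    for i in range(n_roots):
        roots[:, i] = df[f"root{i}_re"].to_numpy() + 1j * df[f"root{i}_im"].to_numpy()
    return GainCurve(k1=df["k1"].to_numpy(), gain=df["gain"].to_numpy(),
                     roots=roots, mode=meta.get("mode", "derived"))


def write_gain_surface(surface: GainSurface, path, meta: dict | None = None) -> None:
    """Long-format CSV: (omega, branch, k1_re, k1_im, gain)."""
    rows = []
    for i, omega in enumerate(surface.omega_grid):
        for j in range(surface.k1_branches.shape[1]):
            rows.append((omega, j, surface.k1_branches[i, j].real,
                         surface.k1_branches[i, j].imag, surface.gain[i, j]))
    df = pd.DataFrame(rows, columns=["omega", "branch", "k1_re", "k1_im", "gain"])
    header = {"kind": "gain_surface", "mode": surface.mode,
              "definition": surface.definition,
              "k1_window": list(surface.k1_window),
              "per_omega_max": [None if not math.isfinite(v) else v
                                for v in surface.per_omega_max],
              **(meta or {})}
    with open(path, "w") as fh:
        fh.write(_meta_comment(header))
        df.to_csv(fh, index=False)


def read_gain_surface(path) -> GainSurface:
    meta = _read_meta(Path(path))
    df = _read_csv(Path(path))
    omegas = np.array(sorted(df["omega"].unique()))
    n_branch = int(df["branch"].max()) + 1
    branches = np.full((omegas.size, n_branch), np.nan, dtype=complex)
    gain = np.full((omegas.size, n_branch), np.nan)
    idx = {o: i for i, o in enumerate(omegas)}
    for _, row in df.iterrows():
        i, j = idx[row["omega"]], int(row["branch"])
        branches[i, j] = row["k1_re"] + 1j * row["k1_im"]
        gain[i, j] = row["gain"]
    per_max = np.array([np.nan if v is None else v for v in meta["per_omega_max"]])
    return GainSurface(omega_grid=omegas, k1_window=tuple(meta["k1_window"]),
                       k1_branches=branches, gain=gain, per_omega_max=per_max,
                       definition=meta.get("definition", "spatial"),
                       mode=meta.get("mode", "derived"))


def write_stability_map(smap: StabilityMap, path, meta: dict | None = None) -> None:
    """Long-format CSV: (axis_value, k1, gain, unstable_flag)."""
    rows = []
    for i, val in enumerate(smap.axis_values):
        for j, k1 in enumerate(smap.k1):
            rows.append((val, k1, smap.gain[i, j], int(smap.unstable[i, j])))
    df = pd.DataFrame(rows, columns=["axis_value", "k1", "gain", "unstable_flag"])
    header = {"kind": "stability_map", "axis": smap.axis_name,
              "threshold": smap.threshold, "mode": smap.mode, **(meta or {})}
    with open(path, "w") as fh:
        fh.write(_meta_comment(header))
        df.to_csv(fh, index=False)


def read_stability_map(path) -> StabilityMap:
    meta = _read_meta(Path(path))
    df = _read_csv(Path(path))
    values = np.array(sorted(df["axis_value"].unique()))
    k1 = np.array(sorted(df["k1"].unique()))
    gain = np.full((values.size, k1.size), np.nan)
    unstable = np.zeros((values.size, k1.size), dtype=bool)
    vi = {v: i for i, v in enumerate(values)}
    ki = {k: i for i, k in enumerate(k1)}
    for _, row in df.iterrows():
        i, j = vi[row["axis_value"]], ki[row["k1"]]
        gain[i, j] = row["gain"]
        unstable[i, j] = bool(row["unstable_flag"])
    return StabilityMap(axis_name=meta["axis"], axis_values=values, k1=k1,
                        gain=gain, unstable=unstable,
                        threshold=float(meta["threshold"]),
                        unstable_fraction=np.mean(unstable, axis=1),
                        mode=meta.get("mode", "derived"))


def write_report(report: dict, path) -> None:
    payload = {"_meta": {"package_version": __version__}, **report}
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def read_report(path) -> dict:
    data = json.loads(Path(path).read_text())
    data.pop("_meta", None)
    return data


def write_results(artifact, path, fmt: str | None = None, meta: dict | None = None) -> None:
    """Dispatch writer: Trajectory -> HDF5, curves/maps/profiles -> CSV,
    reports (dict) -> JSON."""
    if isinstance(artifact, Trajectory):
        write_trajectory(artifact, path, meta)
    elif isinstance(artifact, PotentialProfile):
        write_profile(artifact, path)
    elif isinstance(artifact, GainCurve):
        write_gain_curve(artifact, path, meta)
    elif isinstance(artifact, GainSurface):
        write_gain_surface(artifact, path, meta)
    elif isinstance(artifact, StabilityMap):
        write_stability_map(artifact, path, meta)
    elif isinstance(artifact, dict):
        write_report(artifact, path)
    else:
        raise ConfigError(f"unsupported artifact type {type(artifact).__name__}")
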