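"""Configuration files and tabular output.

Run configurations are TOML files with one table per task (``[abm]``,
``[smol_fit]``, ``[calibrate]``).  Length-valued keys accept a bare
number (µm) or a string with a ``px`` or ``um`` suffix; pixel lengths
are converted through ``pixel_size``.  Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import AbmConfig, FluxSpec, PIXEL_SIZE_UM, Trajectory
from .space import BoxSpec

__all__ = [
    "ConfigError",
    "SmolFitRequest",
    "CalibrateRequest",
    "load_config",
    "parse_length",
    "trajectory_to_frame",
    "write_trajectory_csv",
    "read_trajectory_csv",
]


class ConfigError(ValueError):
    """A configuration file violates the schema."""


@dataclass(frozen=True)
class SmolFitRequest:
    series_path: str
    kernel: str  # constant | monomer_only | both
    n0: float | None
    field_area_um2: float | None


@dataclass(frozen=True)
class CalibrateRequest:
    reference_path: str
    base: AbmConfig
    step_lengths: tuple
    proliferation_rates: tuple
    flux_options: tuple
    n_replicates: int
    stride: int


def parse_length(value, pixel_size: float, key: str) -> float:
    """A length in µm from a number (µm) or a 'NN px' / 'NN um' string."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        try:
            num = float(parts[0])
        except (ValueError, IndexError):
            raise ConfigError(f"{key}: cannot parse length {value!r}") from None
        unit = parts[1] if len(parts) > 1 else "um"
        if unit in ("um", "µm"):
            return num
        if unit == "px":
            return num * pixel_size
        raise ConfigError(f"{key}: unknown length unit {unit!r} (use 'um' or 'px')")
    raise ConfigError(f"{key}: expected number or 'NN px'/'NN um' string")


_ABM_KEYS = {
    "n_initial", "cell_diameter", "step_length", "pixel_size",
    "proliferation_rate", "alpha_max", "compaction_enabled", "flux",
    "box_side", "n_iterations", "seed", "truncate_on_contact",
}
_FLUX_KEYS = {"enabled", "direction", "scope", "small_threshold"}


def _build_abm(table: dict) -> AbmConfig:
    unknown = set(table) - _ABM_KEYS
    if unknown:
        raise ConfigError(f"[abm]: unknown keys {sorted(unknown)}")
    if "n_initial" not in table:
        raise ConfigError("[abm]: n_initial is required")
    px = float(table.get("pixel_size", PIXEL_SIZE_UM))
    kw: dict = {"n_initial": int(table["n_initial"]), "pixel_size": px}
    for key in ("cell_diameter", "step_length"):
        if key in table:
            kw[key] = parse_length(table[key], px, key)
    for key in ("proliferation_rate", "alpha_max"):
        if key in table:
            kw[key] = float(table[key])
    for key in ("compaction_enabled", "truncate_on_contact"):
        if key in table:
            kw[key] = bool(table[key])
    for key in ("n_iterations", "seed"):
        if key in table:
            kw[key] = int(table[key])
    if "box_side" in table:
        kw["box"] = BoxSpec(side_length=parse_length(table["box_side"], px, "box_side"))
    if "flux" in table:
        ft = table["flux"]
        unknown = set(ft) - _FLUX_KEYS
        if unknown:
            raise ConfigError(f"[abm.flux]: unknown keys {sorted(unknown)}")
        kw["flux"] = FluxSpec(**ft)
    try:
        return AbmConfig(**kw)
    except ValueError as e:
        raise ConfigError(f"[abm]: {e}") from e


def load_config(path):
    """Parse and validate a TOML run configuration.

    Returns an :class:`AbmConfig`, :class:`SmolFitRequest` or
    :class:`CalibrateRequest` depending on which task table is present.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    tasks = [k for k in ("abm", "smol_fit", "calibrate") if k in data]
    unknown = set(data) - {"abm", "smol_fit", "calibrate"}
    if unknown:
        raise ConfigError(f"unknown top-level tables {sorted(unknown)}")
    if len(tasks) != 1 and not (tasks == ["abm", "calibrate"] or set(tasks) == {"abm", "calibrate"}):
        raise ConfigError("exactly one task table required ([abm], [smol_fit] or [abm]+[calibrate])")

    if tasks == ["smol_fit"]:
        t = data["smol_fit"]
        unknown = set(t) - {"series", "kernel", "n0", "field_area_um2"}
        if unknown:
            raise ConfigError(f"[smol_fit]: unknown keys {sorted(unknown)}")
        kernel = t.get("kernel", "both")
        if kernel not in ("constant", "monomer_only", "both"):
            raise ConfigError(f"[smol_fit].kernel: invalid value {kernel!r}")
        if "series" not in t:
            raise ConfigError("[smol_fit]: series (CSV path) is required")
        return SmolFitRequest(
            series_path=t["series"],
            kernel=kernel,
            n0=float(t["n0"]) if "n0" in t else None,
            field_area_um2=float(t["field_area_um2"]) if "field_area_um2" in t else None,
        )

    abm = _build_abm(data["abm"])
    if "calibrate" not in data:
        return abm
    t = data["calibrate"]
    allowed = {"reference", "step_lengths", "proliferation_rates", "flux_options",
               "n_replicates", "stride"}
    unknown = set(t) - allowed
    if unknown:
        raise ConfigError(f"[calibrate]: unknown keys {sorted(unknown)}")
    if "reference" not in t:
        raise ConfigError("[calibrate]: reference (CSV path) is required")
    steps = tuple(
        parse_length(v, abm.pixel_size, "step_lengths") for v in t.get("step_lengths", (abm.step_length,))
    )
    return CalibrateRequest(
        reference_path=t["reference"],
        base=abm,
        step_lengths=steps,
        proliferation_rates=tuple(float(v) for v in t.get("proliferation_rates", (abm.proliferation_rate,))),
        flux_options=tuple(t.get("flux_options", (None,))),
        n_replicates=int(t.get("n_replicates", 10)),
        stride=int(t.get("stride", 10)),
    )


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format table of a trajectory: time_min, cell_id, x_um, y_um."""
    chunks = []
    for snap in traj.snapshots:
        chunks.append(
            pd.DataFrame(
                dict(
                    time_min=np.full(len(snap.ids), snap.time),
                    cell_id=snap.ids,
                    x_um=snap.positions[:, 0],
                    y_um=snap.positions[:, 1],
                )
            )
        )
    return pd.concat(chunks, ignore_index=True)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False, float_format="%.9g")


def read_trajectory_csv(path, config: AbmConfig) -> Trajectory:
    """Rebuild a trajectory (snapshots only) from a saved CSV."""
    from .engine import Snapshot

    df = pd.read_csv(path)
    snaps = []
    for t, grp in df.groupby("time_min", sort=True):
        snaps.append(
            Snapshot(
                time=float(t),
                positions=grp[["x_um", "y_um"]].to_numpy(),
                ids=grp["cell_id"].to_numpy(dtype=np.intp),
            )
        )
    return Trajectory(config=config, snapshots=snaps)
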