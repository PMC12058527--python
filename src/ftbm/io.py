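"""Configuration and file formats.

Stacks are exchanged as a multi-page TIFF (one page per stage position) plus
a CSV positions table (``index, opl_nm``) and a JSON metadata sidecar that
embeds the full run configuration.  Results go out as 32-bit float TIFF maps
(GHz) plus an HDF5 archive holding maps, per-pixel diagnostics and the
embedded configuration; every artefact is regenerable from its own metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    BrillouinComponent,
    BrillouinSpectrum,
    OpticalConfig,
    PhotonBudget,
    SamplingSchedule,
)
from .simulate import NoiseModel, PhantomGeometry, SyntheticStack

__all__ = ["RunConfig", "write_stack", "read_stack", "write_results",
           "read_results"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _spectrum_to_dict(s: BrillouinSpectrum) -> dict:
    return {"components": [dataclasses.asdict(c) for c in s.components]}


def _spectrum_from_dict(d: dict) -> BrillouinSpectrum:
    return BrillouinSpectrum(
        [BrillouinComponent(**c) for c in d["components"]])


@dataclass
class RunConfig:
    """Complete, serializable description of a run (schema-versioned).

    Round-trips losslessly through YAML/JSON; embedded in every output so any
    result can be regenerated from its own metadata.
    """

    optics: OpticalConfig
    schedule: SamplingSchedule
    noise: NoiseModel
    spectrum: BrillouinSpectrum | None = None
    budget: PhotonBudget | None = None
    broadening_mode: str = "gaussian-approx"
    options: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "optics": dataclasses.asdict(self.optics),
            "schedule": dataclasses.asdict(self.schedule),
            "noise": dataclasses.asdict(self.noise),
            "spectrum": (None if self.spectrum is None
                         else _spectrum_to_dict(self.spectrum)),
            "budget": (None if self.budget is None
                       else dataclasses.asdict(self.budget)),
            "broadening_mode": self.broadening_mode,
            "options": dict(self.options),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            optics=OpticalConfig(**d["optics"]),
            schedule=SamplingSchedule(**d["schedule"]),
            noise=NoiseModel(**d["noise"]),
            spectrum=(None if d.get("spectrum") is None
                      else _spectrum_from_dict(d["spectrum"])),
            budget=(None if d.get("budget") is None
                    else PhotonBudget(**d["budget"])),
            broadening_mode=d.get("broadening_mode", "gaussian-approx"),
            options=d.get("options", {}),
            schema_version=d.get("schema_version", SCHEMA_VERSION),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Stacks
# ---------------------------------------------------------------------------


def write_stack(stack: SyntheticStack, outdir, stem: str = "stack") -> dict:
    """Write a stack as TIFF + positions CSV + JSON metadata (+ ground truth
    TIFF when present).  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "frames": outdir / f"{stem}.tif",
        "positions": outdir / f"{stem}_positions.csv",
        "metadata": outdir / f"{stem}_meta.json",
    }
    frames = stack.frames
    if stack.noise.shot_noise and stack.noise.read_noise_sd == 0:
        data = frames.astype(np.uint32)
    else:
        data = frames.astype(np.float32)
    tifffile.imwrite(paths["frames"], data, photometric="minisblack")
    pd.DataFrame({"index": np.arange(stack.positions_nm.size),
                  "opl_nm": stack.positions_nm}).to_csv(
        paths["positions"], index=False)
    config = RunConfig(optics=stack.optics, schedule=stack.schedule,
                       noise=stack.noise,
                       budget=stack.geometry.budget,
                       broadening_mode=stack.broadening_mode,
                       options={"seed": stack.seed,
                                "reference_region": stack.reference_region,
                                "reference_level": stack.reference_level})
    meta = {
        "config": config.to_dict(),
        "geometry": {
            "shape": list(stack.geometry.shape),
            "pixel_um": stack.geometry.pixel_um,
            "beads_um": [list(b) for b in stack.geometry.beads_um],
            "background": dataclasses.asdict(stack.geometry.background),
            "inclusion": dataclasses.asdict(stack.geometry.inclusion),
            "edge_blur_um": stack.geometry.edge_blur_um,
        },
        "units": {"positions": "nm OPL", "frames": "photoelectrons"},
    }
    if stack.truth:
        truth_path = outdir / f"{stem}_truth.tif"
        channels = sorted(stack.truth)
        tifffile.imwrite(truth_path,
                         np.stack([stack.truth[k].astype(np.float32)
                                   for k in channels]),
                         photometric="minisblack")
        meta["truth"] = {"file": truth_path.name, "channels": channels}
        paths["truth"] = truth_path
    paths["metadata"].write_text(json.dumps(meta, indent=2))
    return paths


def read_stack(outdir, stem: str = "stack"):
    """Read and validate a stack written by :func:`write_stack`.

    Returns ``(frames, positions_nm, config, meta)``.  Page/position count
    mismatches and missing metadata raise descriptive errors; a shuffled
    positions table is reordered by index with a warning.
    """
    outdir = Path(outdir)
    meta_path = outdir / f"{stem}_meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    config = RunConfig.from_dict(meta["config"])
    frames = tifffile.imread(outdir / f"{stem}.tif").astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    table = pd.read_csv(outdir / f"{stem}_positions.csv")
    if not np.array_equal(table["index"].to_numpy(),
                          np.arange(len(table))):
        logger.warning("positions table out of order; reordering by index")
        table = table.sort_values("index").reset_index(drop=True)
    positions = table["opl_nm"].to_numpy(dtype=float)
    n_expected = config.schedule.n_positions
    if frames.shape[0] != n_expected:
        raise ValueError(
            f"stack has {frames.shape[0]} pages but the schedule expects "
            f"{n_expected} (first missing index "
            f"{min(frames.shape[0], n_expected)})")
    if positions.size != n_expected:
        raise ValueError(
            f"positions table has {positions.size} rows, expected {n_expected}")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions are not strictly increasing")
    return frames, positions, config, meta


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

_MAP_UNITS = {"shift_ghz": "GHz", "linewidth_ghz": "GHz",
              "amplitude": "photoelectrons"}


def write_results(maps: dict, diagnostics: dict, config, outdir,
                  overwrite: bool = False) -> dict:
    """Write reconstruction maps + diagnostics + embedded config.

    32-bit float TIFF per map (units in the TIFF description), one HDF5
    archive with everything, and a CSV summary.  Refuses to write without a
    config (provenance is mandatory) and refuses to overwrite existing
    outputs unless asked.
    """
    if config is None:
        raise ValueError("refusing to write results without a run config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_dict = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    array_maps = {k: v for k, v in maps.items()
                  if isinstance(v, np.ndarray) and v.ndim == 2}
    paths = {}
    targets = [outdir / f"{k}.tif" for k in array_maps]
    targets += [outdir / "results.h5", outdir / "summary.csv"]
    existing = [p for p in targets if p.exists()]
    if existing and not overwrite:
        raise FileExistsError(f"output exists (pass overwrite=True): "
                              f"{existing[0]}")
    for name, arr in array_maps.items():
        p = outdir / f"{name}.tif"
        tifffile.imwrite(p, arr.astype(np.float32),
                         description=_MAP_UNITS.get(name, ""),
                         photometric="minisblack")
        paths[name] = p
    h5path = outdir / "results.h5"
    with h5py.File(h5path, "w") as h5:
        h5.attrs["config_json"] = json.dumps(config_dict)
        gm = h5.create_group("maps")
        for name, arr in array_maps.items():
            ds = gm.create_dataset(name, data=arr.astype(np.float32))
            ds.attrs["units"] = _MAP_UNITS.get(name, "")
        gd = h5.create_group("diagnostics")
        for name, value in (diagnostics or {}).items():
            if isinstance(value, np.ndarray):
                gd.create_dataset(name, data=value)
            else:
                gd.attrs[name] = value
    paths["archive"] = h5path
    summary = pd.DataFrame(
        [{"map": k, "mean": float(np.nanmean(v)), "sd": float(np.nanstd(v)),
          "units": _MAP_UNITS.get(k, "")} for k, v in array_maps.items()])
    summary.to_csv(outdir / "summary.csv", index=False)
    paths["summary"] = outdir / "summary.csv"
    return paths


def read_results(outdir):
    """Read back an archive written by :func:`write_results`.

    Returns ``(maps, diagnostics, config_dict)``.
    """
    outdir = Path(outdir)
    with h5py.File(outdir / "results.h5", "r") as h5:
        config = json.loads(h5.attrs["config_json"])
        maps = {k: h5["maps"][k][()] for k in h5["maps"]}
        diagnostics = {k: h5["diagnostics"][k][()] for k in h5["diagnostics"]}
        diagnostics.update(dict(h5["diagnostics"].attrs))
    return maps, diagnostics, config
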