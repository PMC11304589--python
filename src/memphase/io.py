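"""HDF5 checkpoints for fields and paths; CSV/JSON records for energies.

Field files carry the grid geometry, the elastic parameters and (when
present) the constraint multipliers, so a relaxation or string run can be
restarted exactly.  Energy tables are written with pandas so they load
back as plain data frames.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .energetics import ElasticParams, EnergyBreakdown
from .grid import AxisymGrid, ScalarField
from .relax import ConstraintSet
from .string_mep import StringPath

__all__ = [
    "save_field",
    "load_field",
    "save_path",
    "load_path",
    "energy_table",
    "write_energy_records",
]

_PARAM_KEYS = ("k", "kG", "m", "eps", "kBT_joules")
_GRID_KEYS = ("r_max", "z_min", "z_max", "nr", "nz")


def _write_grid(group: h5py.Group, grid: AxisymGrid) -> None:
    for key in _GRID_KEYS:
        group.attrs[key] = getattr(grid, key)


def _read_grid(group: h5py.Group) -> AxisymGrid:
    kw = {key: group.attrs[key] for key in _GRID_KEYS}
    return AxisymGrid(r_max=float(kw["r_max"]), z_min=float(kw["z_min"]),
                      z_max=float(kw["z_max"]), nr=int(kw["nr"]),
                      nz=int(kw["nz"]))


def save_field(path: str | Path, phi: ScalarField,
               params: ElasticParams | None = None,
               cons: ConstraintSet | None = None) -> None:
    """Write a phase field (plus optional parameters/constraints) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("phi", data=phi.values)
        _write_grid(f, phi.grid)
        if params is not None:
            g = f.create_group("params")
            for key in _PARAM_KEYS:
                g.attrs[key] = getattr(params, key)
        if cons is not None:
            g = f.create_group("constraints")
            for key, val in asdict(cons).items():
                g.attrs[key] = val


def load_field(path: str | Path) -> tuple[
        ScalarField, ElasticParams | None, ConstraintSet | None]:
    """Read a phase field back; parameters/constraints when stored."""
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        phi = ScalarField(grid, f["phi"][...])
        params = None
        if "params" in f:
            params = ElasticParams(**{k: float(f["params"].attrs[k])
                                      for k in _PARAM_KEYS})
        cons = None
        if "constraints" in f:
            cons = ConstraintSet(**{k: float(f["constraints"].attrs[k])
                                    for k in f["constraints"].attrs})
    return phi, params, cons


def save_path(path: str | Path, string: StringPath) -> None:
    """Write a string (all images + alphas + shared metadata) to HDF5."""
    with h5py.File(path, "w") as f:
        _write_grid(f, string.grid)
        f.create_dataset("alpha", data=string.alpha)
        g = f.create_group("params")
        for key in _PARAM_KEYS:
            g.attrs[key] = getattr(string.params, key)
        c = f.create_group("constraints")
        for key, val in asdict(string.cons).items():
            c.attrs[key] = val
        imgs = f.create_group("images")
        for i, im in enumerate(string.images):
            imgs.create_dataset(f"{i:04d}", data=im.values)
        f.attrs["converged"] = string.converged


def load_path(path: str | Path) -> StringPath:
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        params = ElasticParams(**{k: float(f["params"].attrs[k])
                                  for k in _PARAM_KEYS})
        cons = ConstraintSet(**{k: float(f["constraints"].attrs[k])
                                for k in f["constraints"].attrs})
        names = sorted(f["images"])
        images = [ScalarField(grid, f["images"][n][...]) for n in names]
        string = StringPath(images=images, alpha=f["alpha"][...],
                            params=params, cons=cons)
        string.converged = bool(f.attrs["converged"])
    return string


def energy_table(string: StringPath) -> pd.DataFrame:
    """Per-image energy table: alpha, E, EB, EG, A, V, v (+8πk-normalized)."""
    if not string.energies:
        raise ValueError("string has no energies attached")
    rows = []
    scale = 8.0 * np.pi * string.params.k
    for alpha, bd in zip(string.alpha, string.energies):
        rows.append(dict(alpha=alpha, E=bd.E, EB=bd.EB, EG=bd.EG,
                         A=bd.A, V=bd.V, v=bd.v,
                         E_over_8pik=bd.E / scale,
                         EB_over_8pik=bd.EB / scale,
                         EG_over_8pik=bd.EG / scale))
    return pd.DataFrame(rows)


def write_energy_records(path: str | Path, breakdown: EnergyBreakdown,
                         extra: dict | None = None) -> None:
    """JSON record of one energy breakdown (absolute and 8πk units)."""
    rec = breakdown.as_dict()
    if extra:
        rec.update(extra)
    Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
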