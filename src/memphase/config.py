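"""Run configuration: one YAML file describing a complete computation.

Lengths are expressed in units of the interface parameter ϵ (itself given
in nm), energies in kBT, spontaneous curvature in 1/nm.  Unknown keys are
rejected with a schema error listing the offending names, and every run
writes its resolved configuration next to the outputs so results are
reproducible from the artifact alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .energetics import KBT_JOULES_DEFAULT, ElasticParams

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    # elastic parameters
    k: float = 20.0                 # bending rigidity [kBT]
    kG_over_k: float = -1.0         # Gaussian modulus ratio
    m: float = 0.0                  # spontaneous curvature [1/nm]
    eps_nm: float = 5.0 / 6.0       # interface width [nm]; thickness = 6 eps
    kBT_joules: float = KBT_JOULES_DEFAULT

    # grid (units of eps)
    r_max: float = 60.0
    z_half: float = 30.0
    spacing: float = 2.0 / 3.0

    # fixture
    shape: str = "sphere"           # sphere|two_spheres|ellipsoid|clifford_torus
    Dve: float = 40.0               # vesicle scale [eps]
    reduced_volume: float | None = None
    gap: float = 4.0                # two-sphere surface gap [eps]

    # relaxation
    max_outer: int = 40
    inner_maxiter: int = 200
    tol_res: float = 1e-4
    tol_A: float = 1e-3
    tol_V: float = 1e-3
    penalty: float = 0.0            # 0 -> automatic

    # string
    n_images: int = 24
    max_cycles: int = 200
    inner_iters: int = 8
    n_first_segment: int = 0        # 0 -> uniform spacing

    # output
    outdir: str = "runs"

    def elastic_params(self, unit_eps: bool = True) -> ElasticParams:
        """ElasticParams with lengths in ϵ-units (default) or nm."""
        eps = 1.0 if unit_eps else self.eps_nm
        m = self.m * (self.eps_nm if unit_eps else 1.0)
        return ElasticParams(k=self.k, kG=self.kG_over_k * self.k, m=m,
                             eps=eps, kBT_joules=self.kBT_joules)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config, rejecting unknown keys by name."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    bad = sorted(set(data) - known)
    if bad:
        raise ValueError(f"unknown config keys: {', '.join(bad)}")
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
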