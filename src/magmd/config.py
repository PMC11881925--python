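"""Structured run configuration (YAML), with strict key checking.

Layout and key names::

    integrator:
      dt_ps: 0.001        # time step, ps
      n_steps: 1000
      ensemble: NVE       # or NVT
      temperature_K: 300.0
      tau_t_ps: 0.5
      constraint_tol_nm: 1.0e-8
      sample_stride: 10
      seed: 0
    field:
      B_tesla: 0.0
    nonbonded:
      cutoff_nm: 0.9
      epsilon_rf: 78.5
      lj_shift: true
    paths:
      structure: in.gro
      trajectory: out.xyz
      observables: obs.tsv

Unknown keys are rejected; a round trip through save/load is lossless.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field

import yaml

from .dynamics import IntegratorConfig
from .interactions import PairParams
from .model import FieldSpec, InvalidParameterError

_INTEGRATOR_KEYS = {
    "dt_ps",
    "n_steps",
    "ensemble",
    "temperature_K",
    "tau_t_ps",
    "constraint_tol_nm",
    "sample_stride",
    "seed",
    "remove_com",
    "com_stride",
}
_FIELD_KEYS = {"B_tesla"}
_NONBONDED_KEYS = {"cutoff_nm", "epsilon_rf", "lj_shift", "skin_nm"}
_PATH_KEYS = {"structure", "trajectory", "observables"}


@dataclass
class RunConfig:
    """Everything a reproducible run needs, in one serializable object."""

    integrator: IntegratorConfig = dc_field(default_factory=IntegratorConfig)
    field: FieldSpec = dc_field(default_factory=FieldSpec)
    nonbonded: PairParams = dc_field(default_factory=PairParams)
    paths: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "integrator": asdict(self.integrator),
            "field": {"B_tesla": self.field.B_tesla},
            "nonbonded": asdict(self.nonbonded),
            "paths": dict(self.paths),
        }

    def config_hash(self) -> str:
        """Short stable hash of the resolved configuration (provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _check_keys(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise InvalidParameterError(
            f"unknown key(s) in [{name}]: {', '.join(sorted(unknown))}"
        )


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    _check_keys(data, {"integrator", "field", "nonbonded", "paths"}, "top level")
    integ = dict(data.get("integrator") or {})
    fld = dict(data.get("field") or {})
    nb = dict(data.get("nonbonded") or {})
    paths = dict(data.get("paths") or {})
    _check_keys(integ, _INTEGRATOR_KEYS, "integrator")
    _check_keys(fld, _FIELD_KEYS, "field")
    _check_keys(nb, _NONBONDED_KEYS, "nonbonded")
    _check_keys(paths, _PATH_KEYS, "paths")
    return RunConfig(
        integrator=IntegratorConfig(**integ),
        field=FieldSpec(**fld),
        nonbonded=PairParams(**nb),
        paths=paths,
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidParameterError(f"{path}: config must be a YAML mapping")
    return config_from_dict(data)
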